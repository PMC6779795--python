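"""Day-resolved prediction-power profiles.

Once a model is trained, the total split gain of each feature day,
normalized by the summed gain, measures how much of the model's learned
structure each historical day carries (P_D).  Because the profile is a
within-model property, models here are fit on 90% of a panel's neurons
(80% training, 10% validation) with no test set.  Profiles from
different locations are compared by cosine similarity: shared-recency
dynamics give near-identical profiles across locations, while
location-specific history dependence gives profiles peaked at different
days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ActivityPanel, EnvironmentSchedule
from .engine import (
    EngineConfig,
    PowerProfile,
    assemble_xy,
    fit,
    prediction_power,
)


def run_power_profiles(
    panels: list[ActivityPanel],
    compartment: str,
    target_day: int,
    feature_days: list[int],
    config: EngineConfig | None = None,
    seed: int = 0,
    schedule: EnvironmentSchedule | None = None,
) -> list[PowerProfile]:
    """One normalized gain profile per location of a compartment.

    Per location, 90% of neurons are sampled and split 8:1 into training
    and validation (fractions of the whole panel); the fitted model's
    split gains are normalized into P_D.  When a schedule is given, each
    feature day is annotated with its environment label.
    """
    config = config or EngineConfig()
    pool = sorted(
        (p for p in panels if p.compartment == compartment),
        key=lambda p: p.location_id,
    )
    if not pool:
        raise ValueError(f"no panels in compartment {compartment!r}")
    rng = np.random.default_rng(seed)
    env_labels = (
        [schedule.environment_on(d) for d in feature_days] if schedule else None
    )
    profiles = []
    for p in pool:
        n_train = int(np.floor(0.8 * p.n_neurons))
        n_valid = int(np.floor(0.1 * p.n_neurons))
        rows = rng.choice(p.n_neurons, size=n_train + n_valid, replace=False)
        X, y = assemble_xy(p, target_day, feature_days, rows)
        model = fit(
            config,
            X[:n_train],
            y[:n_train],
            X[n_train:],
            y[n_train:],
            seed=int(rng.integers(2**31)),
            feature_days=feature_days,
        )
        prof = prediction_power(model, model_id=f"{p.location_id}:{compartment}")
        prof.environments = env_labels
        profiles.append(prof)
    return profiles


def profile_similarity(a: PowerProfile, b: PowerProfile) -> float:
    """Cosine similarity of two profiles over a common day axis."""
    if a.feature_days != b.feature_days:
        raise ValueError("profiles must share the same feature-day axis")
    na, nb = np.linalg.norm(a.powers), np.linalg.norm(b.powers)
    if na == 0 or nb == 0:
        raise ValueError("degenerate all-zero profile")
    return float(np.dot(a.powers, b.powers) / (na * nb))


@dataclass
class ProfileSimilaritySummary:
    """Pairwise cosine similarities within and between profile sets."""

    within_a: np.ndarray
    within_b: np.ndarray | None
    between: np.ndarray | None
    mean_within_a: float
    mean_within_b: float | None
    mean_between: float | None


def _pairwise(profiles: list[PowerProfile]) -> np.ndarray:
    n = len(profiles)
    sims = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims[i, j] = sims[j, i] = profile_similarity(profiles[i], profiles[j])
    return sims


def _mean_offdiag(sims: np.ndarray) -> float:
    n = sims.shape[0]
    if n < 2:
        return float("nan")
    return float(sims[~np.eye(n, dtype=bool)].mean())


def compare_profiles(
    profiles_a: list[PowerProfile],
    profiles_b: list[PowerProfile] | None = None,
) -> ProfileSimilaritySummary:
    """Within-set (and optionally between-set) cosine-similarity summary."""
    within_a = _pairwise(profiles_a)
    if profiles_b is None:
        return ProfileSimilaritySummary(
            within_a=within_a,
            within_b=None,
            between=None,
            mean_within_a=_mean_offdiag(within_a),
            mean_within_b=None,
            mean_between=None,
        )
    within_b = _pairwise(profiles_b)
    between = np.array(
        [[profile_similarity(a, b) for b in profiles_b] for a in profiles_a]
    )
    return ProfileSimilaritySummary(
        within_a=within_a,
        within_b=within_b,
        between=between,
        mean_within_a=_mean_offdiag(within_a),
        mean_within_b=_mean_offdiag(within_b),
        mean_between=float(between.mean()),
    )
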