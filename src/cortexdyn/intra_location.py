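"""Intra-location prediction: the same-population control.

Because train and test neurons come from one population here, the
protocol guards against overlap by first splitting each (location,
compartment) into 10 disjoint near-equal groups, then sampling 50
validation neurons from one group, 100 test neurons from two other
groups, and 350 training neurons from the remaining seven.  Locations
with fewer than 500 neurons in the compartment are excluded.  Target and
feature conventions match cross-location prediction (last scan day from
all previous days, Day 0 excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ActivityPanel
from .engine import (
    EngineConfig,
    PredictionOutcome,
    assemble_xy,
    default_feature_days,
    evaluate,
    fit,
)

MIN_NEURONS = 500
N_GROUPS = 10
SPLIT = (350, 50, 100)  # train, valid, test


@dataclass
class GroupPartition:
    """10 disjoint near-equal neuron groups of one (location, compartment)."""

    groups: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(g) for g in self.groups]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("group sizes must differ by at most 1")
        flat = np.concatenate(self.groups)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("groups must be disjoint")

    @property
    def n_neurons(self) -> int:
        return sum(len(g) for g in self.groups)


def make_partition(
    n_neurons: int, seed: int, n_groups: int = N_GROUPS
) -> GroupPartition:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_neurons)
    return GroupPartition(groups=list(np.array_split(order, n_groups)), seed=seed)


def sample_intra_split(
    partition: GroupPartition, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw disjoint (train, valid, test) neuron sets of sizes 350/50/100.

    One uniformly chosen group provides the 50 validation neurons, two
    other groups the 100 test neurons, and the remaining seven groups
    the 350 training neurons.
    """
    if partition.n_neurons < MIN_NEURONS:
        raise ValueError(
            f"location has {partition.n_neurons} < {MIN_NEURONS} neurons; excluded"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_train, n_valid, n_test = SPLIT
    picks = rng.choice(len(partition.groups), size=3, replace=False)
    valid_pool = partition.groups[picks[0]]
    test_pool = np.concatenate([partition.groups[picks[1]], partition.groups[picks[2]]])
    train_pool = np.concatenate(
        [g for k, g in enumerate(partition.groups) if k not in picks]
    )
    valid_ids = rng.choice(valid_pool, size=n_valid, replace=False)
    test_ids = rng.choice(test_pool, size=n_test, replace=False)
    train_ids = rng.choice(train_pool, size=n_train, replace=False)
    return train_ids, valid_ids, test_ids


def run_intra_location(
    panels: list[ActivityPanel],
    compartment: str,
    config: EngineConfig | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    n_shuffles: int = 20,
) -> dict[str, list[PredictionOutcome]]:
    """Per-location repeated fit+evaluate within one compartment.

    The 10-group partition is drawn once per location and reused across
    the repeats; each repeat redraws the train/valid/test sample.
    Under-sized locations are skipped with a warning.
    """
    config = config or EngineConfig()
    pool = sorted(
        (p for p in panels if p.compartment == compartment),
        key=lambda p: p.location_id,
    )
    rng = np.random.default_rng(seed)
    outcomes: dict[str, list[PredictionOutcome]] = {}
    for p in pool:
        if p.n_neurons < MIN_NEURONS:
            warnings.warn(
                f"{p.location_id} ({compartment}): {p.n_neurons} < {MIN_NEURONS} "
                "neurons, excluded from intra-location analysis",
                stacklevel=2,
            )
            continue
        target_day = int(p.scan_days[-1])
        feature_days = default_feature_days(p, target_day)
        partition = make_partition(p.n_neurons, seed=int(rng.integers(2**31)))
        runs = []
        for _ in range(n_repeats):
            train_ids, valid_ids, test_ids = sample_intra_split(partition, rng)
            X_tr, y_tr = assemble_xy(p, target_day, feature_days, train_ids)
            X_va, y_va = assemble_xy(p, target_day, feature_days, valid_ids)
            X_te, y_te = assemble_xy(p, target_day, feature_days, test_ids)
            model = fit(
                config,
                X_tr,
                y_tr,
                X_va,
                y_va,
                seed=int(rng.integers(2**31)),
                feature_days=feature_days,
            )
            runs.append(
                evaluate(
                    model,
                    X_te,
                    y_te,
                    config,
                    n_shuffles=n_shuffles,
                    seed=int(rng.integers(2**31)),
                    split_sizes=SPLIT,
                    target_day=target_day,
                )
            )
        outcomes[p.location_id] = runs
    return outcomes


@dataclass
class IntraContrast:
    """Per-location II/III-vs-V comparison of intra-location κ."""

    locations: list[str]
    mean_kappa_superficial: np.ndarray
    mean_kappa_deep: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float


def contrast_intra_locations(
    outcomes_superficial: dict[str, list[PredictionOutcome]],
    outcomes_deep: dict[str, list[PredictionOutcome]],
    alpha: float = 0.01,
) -> IntraContrast:
    """Paired t-test of repeat-matched intra-location κ per location,
    Bonferroni-corrected over the locations compared within the animal."""
    locs = sorted(set(outcomes_superficial) & set(outcomes_deep))
    if not locs:
        raise ValueError("no location present in both compartments")
    mean_sup, mean_deep, pvals = [], [], []
    for loc in locs:
        ks = np.array([o.kappa for o in outcomes_superficial[loc]])
        kd = np.array([o.kappa for o in outcomes_deep[loc]])
        if len(ks) != len(kd):
            raise ValueError("repeat counts differ between compartments")
        mean_sup.append(ks.mean())
        mean_deep.append(kd.mean())
        diffs = ks - kd
        pvals.append(
            1.0 if np.allclose(diffs.std(), 0.0) else stats.ttest_rel(ks, kd).pvalue
        )
    pvals = np.asarray(pvals)
    p_adj = np.minimum(pvals * len(locs), 1.0)
    return IntraContrast(
        locations=locs,
        mean_kappa_superficial=np.asarray(mean_sup),
        mean_kappa_deep=np.asarray(mean_deep),
        p_values=pvals,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        alpha=alpha,
    )
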