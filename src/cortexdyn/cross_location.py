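"""Cross-location transfer: train in one cortical location, test in
another within the same laminar compartment, and contrast the resulting
quality matrices between superficial (II/III) and deep (V) compartments.

For each ordered pair (i, j) of locations a model is trained on
location i's neurons and evaluated on location j's held-out neurons,
always predicting the last scan day from all previous days (Day 0
excluded).  κ(i, j) fills a location x location quality matrix with an
empty diagonal; the whole procedure is repeated 10 times with fresh
random neuron samples.  The layer contrast averages the repeats per
compartment (M̃), differences them (M_κ = M̃_II/III − M̃_V), symmetrizes
(M_s = (M_κ + M_κᵀ)/2), and runs a paired t-test per location pair over
the repeat-matched κ values with Bonferroni correction within the
animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import ActivityPanel
from .engine import (
    EngineConfig,
    PredictionOutcome,
    assemble_xy,
    cross_location_split_sizes,
    default_feature_days,
    evaluate,
    fit,
)


@dataclass
class QualityMatrix:
    """Location x location κ matrix for one compartment and repeat.

    Row = training location, column = test location; the diagonal is
    NaN ("empty").
    """

    compartment: str
    locations: list[str]
    kappa: np.ndarray
    repeat_index: int

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        n = len(self.locations)
        if self.kappa.shape != (n, n):
            raise ValueError("kappa matrix must be square over the location order")

    @property
    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.locations), dtype=bool)
        return self.kappa[mask]


@dataclass
class LayerContrast:
    """II/III-vs-V contrast of averaged quality matrices.

    ``m_s`` entries above zero mean superficial layers transferred
    better for that pair of locations; significance comes from paired
    t-tests over the repeat-matched κ values, Bonferroni-corrected over
    the pairs tested within the animal.
    """

    locations: list[str]
    m_tilde_superficial: np.ndarray
    m_tilde_deep: np.ndarray
    m_kappa: np.ndarray
    m_s: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float
    n_worse_in_deep: int
    n_worse_significant: int
    n_better_in_deep: int
    n_better_significant: int


def run_cross_location(
    panels: Sequence[ActivityPanel],
    compartment: str,
    config: EngineConfig | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    n_shuffles: int = 20,
    min_neurons: int | None = None,
) -> list[QualityMatrix]:
    """Train/test across all ordered location pairs of one compartment.

    Split sizes follow :func:`cross_location_split_sizes` on the minimum
    per-location neuron count.  Within a repeat, each training location
    gets one train+valid sample reused across all its test locations,
    and each test location one test sample reused across all models.
    Locations with fewer neurons than the test size are excluded with a
    warning.
    """
    config = config or EngineConfig()
    pool = sorted(
        (p for p in panels if p.compartment == compartment),
        key=lambda p: p.location_id,
    )
    if min_neurons is None:
        if len(pool) < 2:
            raise ValueError("need at least 2 locations in the compartment")
        min_neurons = min(p.n_neurons for p in pool)
    dropped = [p.location_id for p in pool if p.n_neurons < min_neurons]
    if dropped:
        warnings.warn(
            f"excluding locations with fewer than {min_neurons} neurons: {dropped}",
            stacklevel=2,
        )
        pool = [p for p in pool if p.n_neurons >= min_neurons]
    if len(pool) < 2:
        raise ValueError("need at least 2 eligible locations")

    days_ref = pool[0].scan_days
    for p in pool[1:]:
        if not np.array_equal(p.scan_days, days_ref):
            raise ValueError("all panels of a mouse must share the scan-day axis")

    target_day = int(days_ref[-1])
    feature_days = default_feature_days(pool[0], target_day)
    n_train, n_valid, n_test = cross_location_split_sizes(min_neurons)

    rng = np.random.default_rng(seed)
    locations = [p.location_id for p in pool]
    matrices: list[QualityMatrix] = []
    for r in range(n_repeats):
        # one sample per location per repeat: train+valid for its model,
        # test rows for when it is the target of a transfer
        fitted = {}
        test_sets = {}
        for p in pool:
            rows = rng.choice(p.n_neurons, size=n_train + n_valid, replace=False)
            X, y = assemble_xy(p, target_day, feature_days, rows)
            fitted[p.location_id] = fit(
                config,
                X[:n_train],
                y[:n_train],
                X[n_train:],
                y[n_train:],
                seed=int(rng.integers(2**31)),
                feature_days=feature_days,
            )
            test_rows = rng.choice(p.n_neurons, size=n_test, replace=False)
            test_sets[p.location_id] = assemble_xy(
                p, target_day, feature_days, test_rows
            )

        kappa = np.full((len(pool), len(pool)), np.nan)
        for i, pi in enumerate(pool):
            for j, pj in enumerate(pool):
                if i == j:
                    continue
                X_test, y_test = test_sets[pj.location_id]
                outcome = evaluate(
                    fitted[pi.location_id],
                    X_test,
                    y_test,
                    config,
                    n_shuffles=n_shuffles,
                    seed=int(rng.integers(2**31)),
                    split_sizes=(n_train, n_valid, n_test),
                    target_day=target_day,
                )
                kappa[i, j] = outcome.kappa
        matrices.append(
            QualityMatrix(
                compartment=compartment,
                locations=locations,
                kappa=kappa,
                repeat_index=r,
            )
        )
    return matrices


def _stack(matrices: Sequence[QualityMatrix]) -> np.ndarray:
    return np.stack([m.kappa for m in matrices])


def contrast_layers(
    matrices_superficial: Sequence[QualityMatrix],
    matrices_deep: Sequence[QualityMatrix],
    alpha: float = 0.01,
) -> LayerContrast:
    """Compare II/III and V quality matrices pair by pair.

    Both lists must hold the same number of repeats over an identical
    location order.  A pair with zero variance in the repeat-matched κ
    differences (e.g. literally identical inputs) is reported as
    p = 1 (no evidence of a difference).
    """
    if len(matrices_superficial) != len(matrices_deep):
        raise ValueError("both compartments need the same number of repeats")
    locs = matrices_superficial[0].locations
    for m in list(matrices_superficial) + list(matrices_deep):
        if m.locations != locs:
            raise ValueError("mismatched location sets between matrices")

    sup = _stack(matrices_superficial)  # (repeats, n, n)
    deep = _stack(matrices_deep)
    m_tilde_sup = sup.mean(axis=0)
    m_tilde_deep = deep.mean(axis=0)
    m_kappa = m_tilde_sup - m_tilde_deep
    m_s = (m_kappa + m_kappa.T) / 2.0

    n = len(locs)
    off = ~np.eye(n, dtype=bool)
    n_pairs = int(off.sum())

    p_values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = sup[:, i, j] - deep[:, i, j]
            if np.allclose(diffs.std(), 0.0):
                p_values[i, j] = 1.0
            else:
                p_values[i, j] = stats.ttest_rel(sup[:, i, j], deep[:, i, j]).pvalue
    p_adjusted = np.minimum(p_values * n_pairs, 1.0)
    significant = p_adjusted < alpha

    worse = (m_kappa > 0) & off  # deep layer transferred worse
    better = (m_kappa < 0) & off
    return LayerContrast(
        locations=list(locs),
        m_tilde_superficial=m_tilde_sup,
        m_tilde_deep=m_tilde_deep,
        m_kappa=m_kappa,
        m_s=m_s,
        p_values=p_values,
        p_adjusted=p_adjusted,
        significant=significant & off,
        alpha=alpha,
        n_worse_in_deep=int(worse.sum()),
        n_worse_significant=int((worse & significant).sum()),
        n_better_in_deep=int(better.sum()),
        n_better_significant=int((better & significant).sum()),
    )
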