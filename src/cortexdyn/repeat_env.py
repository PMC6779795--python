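"""Environment-repeat predictability and its decay with interval.

When an animal re-enters an environment it has seen before, how
reliably does the earlier exposure's activity pattern predict the later
one?  For each selected pair of same-environment scan days (S_a, S_b)
the model predicts activity on S_b from four features: activity on S_a
plus activity on scans S_1, S_2 and S_3 with neuron identities shuffled
(controls that carry each day's marginal distribution but no neuron-wise
information; Day 0 is always excluded).  The relative error
δ_r = δ/δ_s — with δ_s from re-shuffling the informative S_a column of
the test features — measures reactivation fidelity; averaging over 100
prediction repetitions and over locations yields δ̄_r and σ(δ_r), whose
linear dependence on the repeat interval Inv (days) is summarized by
OLS fits δ̄_r = ρ_m·Inv + α_m and σ(δ_r) = ρ_s·Inv + α_s.  Environment
comparisons are run twice, on raw values and on slope-modified values
(δ̄_r − ρ_m·Inv, σ(δ_r) − ρ_s·Inv) that remove the interval trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ActivityPanel, EnvironmentSchedule
from .engine import EngineConfig, evaluate, fit, shuffle_features

#: minimum analyzed pairs for a mouse to enter the interval analysis;
#: cohorts with very few environment repeats are excluded
MIN_PAIRS = 3

_SPLIT_GROUPS = (4, 1, 5)  # train/valid/test groups out of 10


@dataclass(frozen=True)
class RepeatPair:
    """Two same-environment scan days and the interval between them."""

    earlier_index: int
    later_index: int
    earlier_day: int
    later_day: int
    environment: str

    @property
    def interval(self) -> int:
        return self.later_day - self.earlier_day


def select_repeat_pairs(schedule: EnvironmentSchedule) -> list[RepeatPair]:
    """Deterministic selection of environment-repeat day pairs.

    Scanning forward from S_4, every scan whose environment occurred at
    an earlier scan (S_1 or later; Day 0 is excluded) is paired with that
    environment's most recent prior occurrence — unless, between the two
    days, the animal was put into the same physical box under a
    different label (e.g. a Training day between two Retrievals of the
    same letter), in which case the pair is excluded.
    """
    entries = schedule.entries
    pairs: list[RepeatPair] = []
    for b, later in enumerate(entries):
        if later.scan_index < 4:
            continue
        earlier = None
        for a in range(b - 1, 0, -1):  # never pair with S_0
            if entries[a].environment == later.environment:
                earlier = a
                break
        if earlier is None:
            continue
        box = later.box_id
        if any(e.box_id == box for e in entries[earlier + 1 : b]):
            continue
        pairs.append(
            RepeatPair(
                earlier_index=entries[earlier].scan_index,
                later_index=later.scan_index,
                earlier_day=entries[earlier].day,
                later_day=later.day,
                environment=later.environment,
            )
        )
    return pairs


@dataclass
class RepeatPredictionResult:
    """100-repetition summary of one (pair, location) prediction."""

    pair: RepeatPair
    location_id: str
    compartment: str
    delta_r: np.ndarray  # per-repetition δ_r
    mean_delta_r: float


def run_repeat_prediction(
    panel: ActivityPanel,
    pair: RepeatPair,
    schedule: EnvironmentSchedule,
    config: EngineConfig | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    n_shuffles: int = 20,
) -> RepeatPredictionResult:
    """Mean relative error ⟨δ_r⟩ of predicting S_b from S_a in one panel.

    Each repetition redraws the 10-group neuron partition (4 groups
    train, 1 valid, 5 test), freshly shuffles the three control days
    S_1-S_3, fits, and evaluates δ_r with the shuffle null applied to the
    S_a feature column only (the controls are already shuffled).
    """
    config = config or EngineConfig()
    day_a, day_b = pair.earlier_day, pair.later_day
    control_days = [schedule.entries[k].day for k in (1, 2, 3)]
    cols = [panel.day_index(day_a)] + [panel.day_index(d) for d in control_days]
    target_col = panel.day_index(day_b)  # raises KeyError if absent

    X_full = panel.activity[:, cols]
    y_full = panel.activity[:, target_col]
    n = panel.n_neurons
    rng = np.random.default_rng(seed)

    deltas = np.empty(n_repeats)
    for rep in range(n_repeats):
        # fresh control shuffles: destroy neuron pairing on S_1..S_3
        X = shuffle_features(X_full, which_days=[1, 2, 3], seed=rng)
        order = rng.permutation(n)
        groups = np.array_split(order, 10)
        tr_g, va_g, te_g = _SPLIT_GROUPS
        train = np.concatenate(groups[:tr_g])
        valid = np.concatenate(groups[tr_g : tr_g + va_g])
        test = np.concatenate(groups[tr_g + va_g :])
        model = fit(
            config,
            X[train],
            y_full[train],
            X[valid],
            y_full[valid],
            seed=int(rng.integers(2**31)),
            feature_days=[day_a] + control_days,
        )
        outcome = evaluate(
            model,
            X[test],
            y_full[test],
            config,
            n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31)),
            shuffle_columns=[0],
            target_day=day_b,
        )
        deltas[rep] = outcome.delta_r
    return RepeatPredictionResult(
        pair=pair,
        location_id=panel.location_id,
        compartment=panel.compartment,
        delta_r=deltas,
        mean_delta_r=float(deltas.mean()),
    )


@dataclass
class RepeatSummary:
    """Across-location repeat-prediction summary with interval fits."""

    pairs: list[RepeatPair]
    mean_delta_r: np.ndarray  # δ̄_r per pair (mean of ⟨δ_r⟩ over locations)
    sd_delta_r: np.ndarray  # σ(δ_r) per pair (SD over locations)
    rho_m: float
    alpha_m: float
    r2_m: float
    rho_s: float
    alpha_s: float
    r2_s: float

    @property
    def intervals(self) -> np.ndarray:
        return np.array([p.interval for p in self.pairs], dtype=float)

    @property
    def modified_mean(self) -> np.ndarray:
        """δ̄'_r = δ̄_r − ρ_m·Inv (interval trend removed)."""
        return self.mean_delta_r - self.rho_m * self.intervals

    @property
    def modified_sd(self) -> np.ndarray:
        """σ'(δ_r) = σ(δ_r) − ρ_s·Inv."""
        return self.sd_delta_r - self.rho_s * self.intervals


def summarize_across_locations(
    results_by_pair: dict[RepeatPair, list[RepeatPredictionResult]],
) -> tuple[list[RepeatPair], np.ndarray, np.ndarray]:
    """Collapse per-location ⟨δ_r⟩ into per-pair δ̄_r and σ(δ_r)."""
    pairs = sorted(results_by_pair, key=lambda p: (p.later_day, p.environment))
    means, sds = [], []
    for p in pairs:
        vals = np.array([r.mean_delta_r for r in results_by_pair[p]])
        means.append(vals.mean())
        sds.append(vals.std(ddof=0))
    return pairs, np.asarray(means), np.asarray(sds)


def fit_interval_dependence(
    pairs: list[RepeatPair],
    mean_delta_r: np.ndarray,
    sd_delta_r: np.ndarray,
) -> RepeatSummary:
    """OLS lines δ̄_r = ρ_m·Inv + α_m and σ(δ_r) = ρ_s·Inv + α_s."""
    intervals = np.array([p.interval for p in pairs], dtype=float)
    if len(np.unique(intervals)) < 2:
        raise ValueError("all intervals identical: slope is unidentifiable")
    if len(pairs) < MIN_PAIRS or len(np.unique(intervals)) < 3:
        raise ValueError(
            f"need at least {MIN_PAIRS} pairs over >=3 distinct intervals"
        )
    fit_m = stats.linregress(intervals, np.asarray(mean_delta_r, dtype=float))
    fit_s = stats.linregress(intervals, np.asarray(sd_delta_r, dtype=float))
    return RepeatSummary(
        pairs=list(pairs),
        mean_delta_r=np.asarray(mean_delta_r, dtype=float),
        sd_delta_r=np.asarray(sd_delta_r, dtype=float),
        rho_m=float(fit_m.slope),
        alpha_m=float(fit_m.intercept),
        r2_m=float(fit_m.rvalue**2),
        rho_s=float(fit_s.slope),
        alpha_s=float(fit_s.intercept),
        r2_s=float(fit_s.rvalue**2),
    )


@dataclass
class EnvironmentComparison:
    """Two-environment comparison of δ̄_r and σ(δ_r), raw or modified."""

    env_a: str
    env_b: str
    use_modified: bool
    comparable: bool
    n_pairs_a: int
    n_pairs_b: int
    p_mean: float | None = None
    p_sd: float | None = None
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None

    def flags(self, p: float | None) -> str:
        if p is None:
            return "n/a"
        if p < 0.05:
            return "*"
        if p < 0.1:
            return "+"
        return "ns"


def compare_environments(
    summary: RepeatSummary,
    env_a: str,
    env_b: str,
    use_modified: bool = False,
) -> EnvironmentComparison:
    """Welch t-test of per-pair δ̄_r and σ(δ_r) between two environments.

    With ``use_modified`` the slope-corrected values are compared, which
    removes the part of any difference explained by unequal repeat
    intervals.  Environments with fewer than 3 analyzed pairs are
    reported as not comparable.
    """
    envs = np.array([p.environment for p in summary.pairs])
    sel_a, sel_b = envs == env_a, envs == env_b
    n_a, n_b = int(sel_a.sum()), int(sel_b.sum())
    if n_a < 3 or n_b < 3:
        return EnvironmentComparison(
            env_a=env_a,
            env_b=env_b,
            use_modified=use_modified,
            comparable=False,
            n_pairs_a=n_a,
            n_pairs_b=n_b,
        )
    means = summary.modified_mean if use_modified else summary.mean_delta_r
    sds = summary.modified_sd if use_modified else summary.sd_delta_r
    p_mean = float(stats.ttest_ind(means[sel_a], means[sel_b], equal_var=False).pvalue)
    p_sd = float(stats.ttest_ind(sds[sel_a], sds[sel_b], equal_var=False).pvalue)
    return EnvironmentComparison(
        env_a=env_a,
        env_b=env_b,
        use_modified=use_modified,
        comparable=True,
        n_pairs_a=n_a,
        n_pairs_b=n_b,
        p_mean=p_mean,
        p_sd=p_sd,
        mean_a=float(means[sel_a].mean()),
        mean_b=float(means[sel_b].mean()),
        sd_a=float(sds[sel_a].mean()),
        sd_b=float(sds[sel_b].mean()),
    )


def most_repeated_environments(pairs: list[RepeatPair], k: int = 2) -> list[str]:
    """The k environments with the most analyzed repeat pairs."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.environment] = counts.get(p.environment, 0) + 1
    return sorted(counts, key=lambda e: (-counts[e], e))[:k]
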