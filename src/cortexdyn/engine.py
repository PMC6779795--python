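"""Boosted-tree prediction core: feature assembly, fitting, shuffle
controls, and the error/quality statistics δ, δ_s, δ_r and κ.

Day-resolved activity prediction is framed as tabular regression: rows
are neurons, columns are that neuron's activity on earlier scan days,
the label is its activity on the target day.  A gradient-boosted
decision-tree regressor is fit with a fixed reference configuration
(:class:`EngineConfig`) — 10 leaves, minimum 1 sample per leaf, learning
rate 0.05, 93% feature and bagging fractions with per-iteration
resampling, l2 objective — and evaluated against a shuffle null that
permutes neuron identities independently within each feature-day column
of the test set, destroying each neuron's pairing with its own history
while preserving every day's activity distribution.

Quality statistics: δ is the test mean square error of the model, δ_s
the MSE of the average of ``n_shuffles`` predictions on shuffled test
features, δ_r = δ/δ_s the relative error, and κ = exp(−δ_r) ∈ (0, 1]
the prediction quality (κ = e⁻¹ is shuffle-level performance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.ensemble import GradientBoostingRegressor

from .data_model import ActivityPanel

#: chunk of boosting rounds grown between validation checks
_ES_CHUNK = 25


@dataclass
class EngineConfig:
    """Reference regressor configuration (all defaults fixed).

    The named fields mirror the LightGBM-style parameter vocabulary the
    reference protocol is stated in; they are mapped onto scikit-learn's
    :class:`~sklearn.ensemble.GradientBoostingRegressor`
    (num_leaves -> max_leaf_nodes, min_data_in_leaf -> min_samples_leaf,
    feature_fraction -> max_features, bagging_fraction -> subsample with
    bagging_freq = 1 meaning per-iteration resampling, metric l2 ->
    squared-error loss).  ``num_threads`` is carried for config-file
    compatibility; the backing implementation is single-threaded, which
    makes every fit deterministic given the seed.
    """

    num_leaves: int = 10
    objective: str = "regression"
    min_data_in_leaf: int = 1
    learning_rate: float = 0.05
    feature_fraction: float = 0.93
    bagging_fraction: float = 0.93
    bagging_freq: int = 1
    metric: str = "l2"
    num_threads: int = 4
    num_boost_rounds: int = 500
    early_stopping_rounds: int = 50

    @classmethod
    def from_yaml(cls, path: Path | str) -> "EngineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k.lower(): v for k, v in raw.items()})

    def to_dict(self) -> dict:
        return {
            "num_leaves": self.num_leaves,
            "objective": self.objective,
            "min_data_in_leaf": self.min_data_in_leaf,
            "learning_rate": self.learning_rate,
            "feature_fraction": self.feature_fraction,
            "bagging_fraction": self.bagging_fraction,
            "bagging_freq": self.bagging_freq,
            "metric": self.metric,
            "num_threads": self.num_threads,
            "num_boost_rounds": self.num_boost_rounds,
            "early_stopping_rounds": self.early_stopping_rounds,
        }


@dataclass
class TrainedModel:
    """A fitted regressor plus its feature-day bookkeeping."""

    regressor: GradientBoostingRegressor
    feature_days: list[int]
    gains: np.ndarray  # total split gain per feature day, >= 0
    best_iteration: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(X)


@dataclass
class PredictionOutcome:
    """One trained-model evaluation against the shuffle null."""

    delta: float
    delta_s: float
    delta_r: float
    kappa: float
    r2: float
    split_sizes: tuple[int, int, int] | None = None
    feature_days: list[int] = field(default_factory=list)
    target_day: int | None = None
    seed: int | None = None


@dataclass
class PowerProfile:
    """Normalized per-feature-day prediction power P_D of one model.

    P_D is the total split gain of feature day D divided by the summed
    gain over all feature days, so the profile sums to one and reads as
    the share of the model's learned structure attributed to each day.
    """

    model_id: str
    feature_days: list[int]
    powers: np.ndarray
    environments: list[str] | None = None

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if len(self.powers) != len(self.feature_days):
            raise ValueError("one power per feature day required")

    @property
    def peak_day(self) -> int:
        return self.feature_days[int(np.argmax(self.powers))]


def assemble_xy(
    panel: ActivityPanel,
    target_day: int,
    feature_days: Sequence[int],
    neuron_subset: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (neurons x feature days) and target-day labels.

    Feature days must all precede the target day; Day 0 exclusion is the
    caller's protocol decision and is expressed simply by leaving day 0
    out of ``feature_days``.
    """
    feature_days = list(feature_days)
    if not feature_days:
        raise ValueError("empty feature-day set")
    if any(d >= target_day for d in feature_days):
        raise ValueError("feature days must all be strictly before the target day")
    t_col = panel.day_index(target_day)  # raises KeyError if absent
    cols = [panel.day_index(d) for d in feature_days]
    X = panel.activity[:, cols]
    y = panel.activity[:, t_col]
    if neuron_subset is not None:
        rows = np.asarray(neuron_subset, dtype=int)
        X, y = X[rows], y[rows]
    return np.ascontiguousarray(X, dtype=float), np.asarray(y, dtype=float)


def default_feature_days(panel: ActivityPanel, target_day: int) -> list[int]:
    """All scanned days before the target, excluding Day 0 (the
    cross-location / intra-location feature convention)."""
    return [int(d) for d in panel.scan_days if 0 < d < target_day]


def fit(
    config: EngineConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_valid: np.ndarray,
    y_valid: np.ndarray,
    seed: int,
    feature_days: Sequence[int] | None = None,
) -> TrainedModel:
    """Fit the boosted-tree regressor with validation early stopping.

    Rounds are grown in chunks; training stops once the validation l2
    has not improved for ``config.early_stopping_rounds`` rounds (or at
    ``config.num_boost_rounds``), and the ensemble is truncated to the
    best validation iteration.  Per-feature total split gains are summed
    over the kept trees.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(X_train) < config.min_data_in_leaf:
        raise ValueError("fewer training rows than min_data_in_leaf")
    if feature_days is None:
        feature_days = list(range(X_train.shape[1]))
    feature_days = [int(d) for d in feature_days]
    if len(feature_days) != X_train.shape[1]:
        raise ValueError("feature_days must match the design-matrix columns")

    reg = GradientBoostingRegressor(
        loss="squared_error",
        learning_rate=config.learning_rate,
        n_estimators=0,
        max_leaf_nodes=config.num_leaves,
        min_samples_leaf=config.min_data_in_leaf,
        subsample=config.bagging_fraction,
        max_features=config.feature_fraction,
        random_state=seed,
        warm_start=True,
    )
    best_l2, best_n, n_rounds = math.inf, 0, 0
    while n_rounds < config.num_boost_rounds:
        n_rounds = min(n_rounds + _ES_CHUNK, config.num_boost_rounds)
        reg.set_params(n_estimators=n_rounds)
        reg.fit(X_train, y_train)
        l2 = float(np.mean((reg.predict(X_valid) - y_valid) ** 2))
        if l2 < best_l2 - 1e-12:
            best_l2, best_n = l2, n_rounds
        if n_rounds - best_n >= config.early_stopping_rounds:
            break
    best_n = max(best_n, _ES_CHUNK)  # keep at least one chunk of trees
    reg.estimators_ = reg.estimators_[:best_n]
    reg.set_params(warm_start=False, n_estimators=best_n)

    gains = np.zeros(X_train.shape[1])
    for (tree,) in reg.estimators_:
        gains += tree.tree_.compute_feature_importances(normalize=False)
    return TrainedModel(
        regressor=reg,
        feature_days=feature_days,
        gains=gains,
        best_iteration=best_n,
    )


def shuffle_features(
    X_test: np.ndarray,
    which_days: Sequence[int] | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Independently permute neuron entries within each selected
    feature-day column (per-day marginals preserved, neuron-wise day
    pairing destroyed).  ``which_days`` are column indices; None means
    all columns."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = np.array(X_test, dtype=float, copy=True)
    cols = range(X.shape[1]) if which_days is None else which_days
    for c in cols:
        X[:, c] = X[rng.permutation(X.shape[0]), c]
    return X


def evaluate(
    model: TrainedModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: EngineConfig | None = None,
    n_shuffles: int = 20,
    seed: int = 0,
    shuffle_columns: Sequence[int] | None = None,
    split_sizes: tuple[int, int, int] | None = None,
    target_day: int | None = None,
) -> PredictionOutcome:
    """Score a model on held-out neurons against the shuffle null.

    δ is the test MSE; the control δ_s is the MSE of the *average* of
    ``n_shuffles`` predictions made on feature-shuffled copies of the
    test set; δ_r = δ/δ_s and κ = exp(−δ_r).  R² of the unshuffled
    prediction is reported alongside.
    """
    y_test = np.asarray(y_test, dtype=float)
    pred = model.predict(X_test)
    delta = float(np.mean((pred - y_test) ** 2))

    rng = np.random.default_rng(seed)
    acc = np.zeros_like(y_test)
    for _ in range(n_shuffles):
        acc += model.predict(shuffle_features(X_test, shuffle_columns, rng))
    delta_s = float(np.mean((acc / n_shuffles - y_test) ** 2))
    if delta_s == 0.0:
        raise ValueError("degenerate labels: shuffle-control error is zero")

    delta_r = delta / delta_s
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - y_test) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return PredictionOutcome(
        delta=delta,
        delta_s=delta_s,
        delta_r=delta_r,
        kappa=math.exp(-delta_r),
        r2=r2,
        split_sizes=split_sizes,
        feature_days=list(model.feature_days),
        target_day=target_day,
        seed=seed,
    )


def cross_location_split_sizes(min_neurons: int) -> tuple[int, int, int]:
    """Train/validation/test sizes for cross-location prediction.

    The test size equals the animal's minimum per-location neuron count;
    training and validation are 90% and 10% of that number (floored).
    """
    if min_neurons < 20:
        raise ValueError("need at least 20 neurons to form a split")
    return (
        int(math.floor(0.9 * min_neurons)),
        int(math.floor(0.1 * min_neurons)),
        int(min_neurons),
    )


def prediction_power(model: TrainedModel, model_id: str = "") -> PowerProfile:
    """Normalized split-gain profile P_D = G_D / Σ G_D of a fitted model."""
    total = float(model.gains.sum())
    if total <= 0:
        raise ValueError("all split gains are zero: the model learned nothing")
    return PowerProfile(
        model_id=model_id,
        feature_days=list(model.feature_days),
        powers=model.gains / total,
    )
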