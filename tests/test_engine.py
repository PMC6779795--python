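"""Prediction-core contracts: feature assembly, fitting, the shuffle
null, split-size arithmetic, the δ/δ_s/δ_r/κ statistics, and
prediction-power normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortexdyn as cd
from cortexdyn.engine import TrainedModel


@pytest.fixture(scope="module")
def config():
    return cd.EngineConfig()


def test_reference_config_defaults():
    cfg = cd.EngineConfig()
    assert (
        cfg.num_leaves,
        cfg.objective,
        cfg.min_data_in_leaf,
        cfg.learning_rate,
        cfg.feature_fraction,
        cfg.bagging_fraction,
        cfg.bagging_freq,
        cfg.metric,
        cfg.num_threads,
    ) == (10, "regression", 1, 0.05, 0.93, 0.93, 1, "l2", 4)


def test_config_yaml_round_trip(tmp_path):
    import yaml

    path = tmp_path / "engine.yaml"
    path.write_text(yaml.safe_dump(cd.EngineConfig(learning_rate=0.1).to_dict()))
    assert cd.EngineConfig.from_yaml(path).learning_rate == 0.1


class TestAssembleXY:
    def test_twelve_feature_days(self, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        target = int(p.scan_days[-1])
        days = [int(d) for d in p.scan_days[:-1][-12:] if d < target]
        X, y = cd.assemble_xy(p, target, days)
        assert X.shape == (p.n_neurons, len(days))
        np.testing.assert_array_equal(y, p.activity[:, -1])

    def test_single_feature_day(self, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        X, _ = cd.assemble_xy(p, int(p.scan_days[-1]), [int(p.scan_days[1])])
        assert X.shape[1] == 1

    def test_feature_on_or_after_target_rejected(self, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        target = int(p.scan_days[-1])
        with pytest.raises(ValueError, match="before the target"):
            cd.assemble_xy(p, target, [target])

    def test_missing_target_day_and_empty_features(self, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        with pytest.raises(KeyError):
            cd.assemble_xy(p, 9999, [0])
        with pytest.raises(ValueError, match="empty"):
            cd.assemble_xy(p, int(p.scan_days[-1]), [])

    def test_default_feature_days_exclude_day_zero_and_target(self, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        days = cd.default_feature_days(p, int(p.scan_days[-1]))
        assert 0 not in days
        assert int(p.scan_days[-1]) not in days
        assert days == sorted(days)


class TestFit:
    def test_constant_labels(self, config):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 5))
        y = np.full(300, 4.2)
        model = cd.fit(config, X[:250], y[:250], X[250:], y[250:], seed=1)
        np.testing.assert_allclose(model.predict(X), 4.2, atol=1e-9)

    def test_recovers_known_piecewise_function(self, config):
        """Tree ensemble should learn y = f(x0) for a deterministic
        piecewise generator (oracle = the generating function)."""
        rng = np.random.default_rng(1)
        X = rng.gamma(2.0, 1.0, size=(2000, 6))
        f = lambda x: np.where(x > 2.0, 2.0 * x, 0.5 * x)  # noqa: E731
        y = f(X[:, 0])
        model = cd.fit(config, X[:1600], y[:1600], X[1600:1800], y[1600:1800], seed=2)
        X_test, y_test = X[1800:], y[1800:]
        pred = model.predict(X_test)
        r2 = 1 - np.sum((pred - y_test) ** 2) / np.sum((y_test - y_test.mean()) ** 2)
        assert r2 > 0.9

    def test_pure_noise_r2_near_zero(self, config):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1200, 6))
        y = rng.normal(size=1200)
        model = cd.fit(config, X[:900], y[:900], X[900:1000], y[900:1000], seed=3)
        pred = model.predict(X[1000:])
        y_test = y[1000:]
        r2 = 1 - np.sum((pred - y_test) ** 2) / np.sum((y_test - y_test.mean()) ** 2)
        assert abs(r2) < 0.1

    def test_too_few_training_rows(self):
        cfg = cd.EngineConfig(min_data_in_leaf=10)
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="min_data_in_leaf"):
            cd.fit(cfg, X, np.ones(5), X, np.ones(5), seed=0)


class TestShuffleFeatures:
    def test_single_row_unchanged(self):
        X = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(cd.shuffle_features(X, seed=0), X)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(2, 40),
        p=st.integers(1, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_column_multisets_preserved(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        Xs = cd.shuffle_features(X, seed=seed)
        for c in range(p):
            np.testing.assert_array_equal(np.sort(Xs[:, c]), np.sort(X[:, c]))

    def test_only_selected_columns_shuffled(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        Xs = cd.shuffle_features(X, which_days=[1], seed=4)
        np.testing.assert_array_equal(Xs[:, 0], X[:, 0])
        np.testing.assert_array_equal(Xs[:, 2], X[:, 2])
        assert not np.array_equal(Xs[:, 1], X[:, 1])

    def test_shuffled_column_decorrelated_from_labels(self):
        """On recency-generated data the shuffled feature column loses
        its correlation with the labels (mean over 20 shuffles ~ 0)."""
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 1.0, 2000)
        y = x + rng.normal(0, 0.2, 2000)  # strongly correlated
        corrs = []
        for s in range(20):
            xs = cd.shuffle_features(x[:, None], seed=s)[:, 0]
            corrs.append(np.corrcoef(xs, y)[0, 1])
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.9
        assert abs(np.mean(corrs)) < 0.05


class _StubModel:
    """Duck-typed model with a fixed prediction rule, for evaluate()."""

    def __init__(self, fn, feature_days):
        self._fn = fn
        self.feature_days = feature_days

    def predict(self, X):
        return self._fn(X)


class TestEvaluate:
    def test_feature_blind_model_gives_delta_r_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 3))
        y = rng.normal(size=500)
        stub = _StubModel(lambda X: np.zeros(len(X)), [1, 2, 3])
        out = cd.evaluate(stub, X, y, n_shuffles=20, seed=7)
        assert out.delta_r == pytest.approx(1.0)
        assert out.kappa == pytest.approx(math.exp(-1.0))

    def test_perfect_prediction_gives_kappa_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(500, 2))
        y = X[:, 0].copy()
        stub = _StubModel(lambda X: X[:, 0], [1, 2])
        out = cd.evaluate(stub, X, y, n_shuffles=20, seed=9)
        assert out.delta == 0.0
        assert out.kappa == 1.0
        assert out.r2 == pytest.approx(1.0)

    def test_outcome_internal_consistency(self, config, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        target = int(p.scan_days[-1])
        days = cd.default_feature_days(p, target)
        X, y = cd.assemble_xy(p, target, days)
        model = cd.fit(config, X[:300], y[:300], X[300:340], y[300:340], seed=10)
        out = cd.evaluate(model, X[340:], y[340:], config, seed=11)
        assert out.delta_r == pytest.approx(out.delta / out.delta_s, rel=1e-12)
        assert out.kappa == pytest.approx(math.exp(-out.delta_r), rel=1e-12)
        assert 0 < out.kappa <= 1

    def test_degenerate_labels_error(self):
        X = np.ones((50, 2))
        y = np.ones(50)
        stub = _StubModel(lambda X: np.ones(len(X)), [1, 2])
        with pytest.raises(ValueError, match="degenerate"):
            cd.evaluate(stub, X, y, n_shuffles=5, seed=0)

    def test_determinism_bit_identical(self, config, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        target = int(p.scan_days[-1])
        days = cd.default_feature_days(p, target)
        X, y = cd.assemble_xy(p, target, days)

        def run():
            m = cd.fit(config, X[:300], y[:300], X[300:340], y[300:340], seed=12)
            return cd.evaluate(m, X[340:], y[340:], config, seed=13)

        a, b = run(), run()
        assert (a.delta, a.delta_s, a.delta_r, a.kappa, a.r2) == (
            b.delta,
            b.delta_s,
            b.delta_r,
            b.kappa,
            b.r2,
        )


class TestSplitSizes:
    @pytest.mark.parametrize(
        "min_neurons,expected",
        [(399, (359, 39, 399)), (116, (104, 11, 116)), (342, (307, 34, 342))],
    )
    def test_published_split_sizes(self, min_neurons, expected):
        assert cd.cross_location_split_sizes(min_neurons) == expected

    def test_minimum_size_guard(self):
        with pytest.raises(ValueError):
            cd.cross_location_split_sizes(19)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(m=st.integers(20, 10000))
    def test_rule_and_disjointness(self, m):
        n_train, n_valid, n_test = cd.cross_location_split_sizes(m)
        assert n_test == m
        assert n_train == int(0.9 * m) or n_train == math.floor(0.9 * m)
        assert n_valid == math.floor(0.1 * m)
        assert n_train + n_valid <= m  # train+valid sampled without overlap


class TestPredictionPower:
    def _model_with_gains(self, gains, days=None):
        gains = np.asarray(gains, dtype=float)
        days = days or list(range(len(gains)))
        return TrainedModel(
            regressor=None, feature_days=days, gains=gains, best_iteration=1
        )

    def test_normalization_oracle(self):
        prof = cd.prediction_power(self._model_with_gains([2.0, 2.0, 6.0]))
        np.testing.assert_allclose(prof.powers, [0.2, 0.2, 0.6])

    def test_single_feature_day(self):
        prof = cd.prediction_power(self._model_with_gains([5.0]))
        assert prof.powers[0] == 1.0

    def test_all_zero_gains_error(self):
        with pytest.raises(ValueError, match="learned nothing"):
            cd.prediction_power(self._model_with_gains([0.0, 0.0]))

    def test_fitted_profile_sums_to_one(self, config, mixed_cohort):
        panels, _ = mixed_cohort
        p = panels[0]
        target = int(p.scan_days[-1])
        days = cd.default_feature_days(p, target)
        X, y = cd.assemble_xy(p, target, days)
        model = cd.fit(
            config, X[:300], y[:300], X[300:340], y[300:340], seed=14,
            feature_days=days,
        )
        prof = cd.prediction_power(model)
        assert prof.powers.sum() == pytest.approx(1.0, abs=1e-12)
        assert (prof.powers >= 0).all()
        assert prof.feature_days == days
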