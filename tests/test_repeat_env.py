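"""Environment-repeat analysis: pair selection with box-identity
exclusion, the four-feature prediction with shuffled early-day controls,
interval regression against a normal-equations oracle, and environment
comparisons."""

import numpy as np
import pytest

import cortexdyn as cd
from cortexdyn.repeat_env import RepeatPair


def _schedule(envs, days=None):
    days = days or [2 * k for k in range(len(envs))]
    return cd.EnvironmentSchedule.from_environments("Syn", days, envs)


class TestSelectRepeatPairs:
    def test_home_cage_between_retrievals_included(self):
        #                 S0   S1    S2    S3    S4    S5   S6
        sch = _schedule(["H", "CB", "TU", "EE", "RA", "H", "RA"])
        pairs = cd.select_repeat_pairs(sch)
        ra = [p for p in pairs if p.environment == "RA"]
        assert len(ra) == 1
        assert (ra[0].earlier_day, ra[0].later_day) == (8, 12)
        assert ra[0].interval == 4

    def test_same_box_between_repeats_excluded(self):
        # Training A occupies box A between the two Retrieval A days
        sch = _schedule(["H", "CB", "TU", "EE", "RA", "TA", "RA"])
        pairs = cd.select_repeat_pairs(sch)
        assert all(p.environment != "RA" for p in pairs)

    def test_no_repeats_after_s3_gives_empty_list(self):
        sch = _schedule(["H", "RA", "RA", "RA", "CB", "TU", "EE"])
        assert cd.select_repeat_pairs(sch) == []

    def test_day_zero_never_a_pair_member(self):
        sch = _schedule(["H", "CB", "TU", "EE", "H", "RA"])
        pairs = cd.select_repeat_pairs(sch)
        assert all(p.earlier_day > 0 for p in pairs)

    def test_selection_is_deterministic(self, schedule12):
        assert cd.select_repeat_pairs(schedule12) == cd.select_repeat_pairs(schedule12)

    def test_pairs_use_most_recent_prior_occurrence(self, schedule12):
        for p in cd.select_repeat_pairs(schedule12):
            envs = schedule12.environments
            between = envs[p.earlier_index + 1 : p.later_index]
            assert p.environment not in between


@pytest.fixture(scope="module")
def env_cohort(schedule12):
    spec = cd.DynamicsSpec(
        "shared_recency", env_effect_scale=1.0, env_decay_rate=0.015, noise_sd=0.3
    )
    return cd.generate_cohort(2, 500, schedule12, {"II/III": spec}, seed=31)


class TestRunRepeatPrediction:
    def test_null_data_gives_delta_r_near_one(self, schedule12):
        panels, _ = cd.generate_cohort(
            2,
            500,
            schedule12,
            {"II/III": cd.DynamicsSpec("independent", env_effect_scale=0.0)},
            seed=32,
        )
        pair = cd.select_repeat_pairs(schedule12)[0]
        res = cd.run_repeat_prediction(panels[0], pair, schedule12, n_repeats=5, seed=33)
        assert abs(res.mean_delta_r - 1.0) < 0.15

    def test_signal_beats_null_and_controls_get_no_power(self, env_cohort, schedule12):
        panels, _ = env_cohort
        pair = cd.select_repeat_pairs(schedule12)[0]
        res = cd.run_repeat_prediction(panels[0], pair, schedule12, n_repeats=5, seed=34)
        assert res.mean_delta_r < 0.8

        # shuffled S_1-S_3 control columns should carry ~no prediction power
        day_a = schedule12.entries[pair.earlier_index].day
        controls = [schedule12.entries[k].day for k in (1, 2, 3)]
        cols = [panels[0].day_index(d) for d in [day_a] + controls]
        X = panels[0].activity[:, cols]
        X = cd.shuffle_features(X, which_days=[1, 2, 3], seed=35)
        y = panels[0].activity[:, panels[0].day_index(pair.later_day)]
        model = cd.fit(cd.EngineConfig(), X[:200], y[:200], X[200:250], y[200:250],
                       seed=36, feature_days=[day_a] + controls)
        prof = cd.prediction_power(model)
        assert prof.powers[1:].mean() < 0.1

    def test_pair_day_not_in_panel_errors(self, env_cohort, schedule12):
        panels, _ = env_cohort
        bad = RepeatPair(
            earlier_index=1, later_index=5, earlier_day=3, later_day=999,
            environment="RA",
        )
        with pytest.raises(KeyError):
            cd.run_repeat_prediction(panels[0], bad, schedule12, n_repeats=1, seed=0)


def _pair(inv, env="RA", start=10):
    return RepeatPair(
        earlier_index=4, later_index=5, earlier_day=start,
        later_day=start + inv, environment=env,
    )


class TestIntervalFits:
    def test_exact_line_recovered(self):
        pairs = [_pair(iv) for iv in (10, 20, 30, 40)]
        inv = np.array([10.0, 20.0, 30.0, 40.0])
        means = 0.01 * inv + 0.5
        sds = 0.002 * inv + 0.05
        summ = cd.fit_interval_dependence(pairs, means, sds)
        assert summ.rho_m == pytest.approx(0.01)
        assert summ.alpha_m == pytest.approx(0.5)
        assert summ.r2_m == pytest.approx(1.0)
        assert summ.rho_s == pytest.approx(0.002)

    def test_constant_values_give_zero_slope(self):
        pairs = [_pair(iv) for iv in (5, 15, 25)]
        summ = cd.fit_interval_dependence(pairs, np.full(3, 0.7), np.full(3, 0.1))
        assert summ.rho_m == pytest.approx(0.0, abs=1e-15)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(37)
        inv = np.array([5.0, 9.0, 16.0, 17.0, 37.0, 21.0])
        pairs = [_pair(int(iv)) for iv in inv]
        means = 0.012 * inv + 0.4 + rng.normal(0, 0.05, len(inv))
        sds = 0.001 * inv + 0.02 + rng.normal(0, 0.01, len(inv))
        summ = cd.fit_interval_dependence(pairs, means, sds)
        # closed-form normal equations for slope and intercept
        A = np.column_stack([inv, np.ones_like(inv)])
        slope_m, alpha_m = np.linalg.solve(A.T @ A, A.T @ means)
        slope_s, alpha_s = np.linalg.solve(A.T @ A, A.T @ sds)
        assert summ.rho_m == pytest.approx(slope_m, abs=1e-10)
        assert summ.alpha_m == pytest.approx(alpha_m, abs=1e-10)
        assert summ.rho_s == pytest.approx(slope_s, abs=1e-10)
        assert summ.alpha_s == pytest.approx(alpha_s, abs=1e-10)

    def test_identical_intervals_rejected(self):
        pairs = [_pair(10) for _ in range(4)]
        with pytest.raises(ValueError, match="identical|distinct"):
            cd.fit_interval_dependence(pairs, np.ones(4), np.ones(4))

    def test_modification_arithmetic(self):
        """δ̄'_r = δ̄_r − ρ_m·Inv: 0.8 − 0.002·50 = 0.7."""
        pairs = [_pair(50), _pair(30), _pair(10)]
        summ = cd.RepeatSummary(
            pairs=pairs,
            mean_delta_r=np.array([0.8, 0.76, 0.72]),
            sd_delta_r=np.array([0.1, 0.1, 0.1]),
            rho_m=0.002, alpha_m=0.7, r2_m=1.0,
            rho_s=0.0, alpha_s=0.1, r2_s=0.0,
        )
        assert summ.modified_mean[0] == pytest.approx(0.7)
        np.testing.assert_allclose(
            summ.modified_mean, summ.mean_delta_r - 0.002 * summ.intervals
        )


class TestCompareEnvironments:
    def _summary(self, rng, shift=0.0):
        pairs = [_pair(10 + 3 * k, env="RA") for k in range(4)] + [
            _pair(12 + 3 * k, env="EE") for k in range(4)
        ]
        means = np.concatenate(
            [0.5 + rng.normal(0, 0.02, 4), 0.5 + shift + rng.normal(0, 0.02, 4)]
        )
        sds = np.abs(rng.normal(0.08, 0.01, 8))
        return cd.fit_interval_dependence(pairs, means, sds)

    def test_insufficient_pairs_not_comparable(self):
        pairs = [_pair(10, "RA"), _pair(20, "RA"), _pair(15, "EE"), _pair(30, "RA")]
        summ = cd.fit_interval_dependence(
            pairs, np.array([0.5, 0.6, 0.55, 0.7]), np.array([0.1, 0.1, 0.1, 0.1])
        )
        rep = cd.compare_environments(summ, "RA", "EE")
        assert not rep.comparable
        assert rep.n_pairs_b == 1

    def test_identical_environments_not_significant(self):
        rng = np.random.default_rng(38)
        rep = cd.compare_environments(self._summary(rng), "RA", "EE")
        assert rep.comparable
        assert rep.p_mean > 0.1

    def test_shifted_environment_detected(self):
        rng = np.random.default_rng(39)
        rep = cd.compare_environments(self._summary(rng, shift=0.3), "RA", "EE")
        assert rep.p_mean < 0.05
        assert rep.flags(rep.p_mean) == "*"

    def test_most_repeated_environments(self, schedule12):
        pairs = cd.select_repeat_pairs(schedule12)
        top = cd.most_repeated_environments(pairs, k=2)
        assert top[0] == "RA"  # RA repeats most in the demo protocol
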