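"""Orthogonalization, regression fits, group tests, VIF pruning, confound demo."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gkrl import (
    TaskConfig,
    behavioral_choice_regression,
    confound_experiment,
    generate_cohort,
    logistic_fit,
    ols_betas,
    one_sample_ttest,
    serial_orthogonalize,
    vif_prune,
)
from gkrl.cohort import CohortSpec


class TestSerialOrthogonalize:
    def test_residuals_orthogonal_to_earlier_columns(self, rng):
        design = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        design["b"] += 0.8 * design["a"]  # induce shared variance
        design["c"] += 0.5 * design["a"] - 0.3 * design["b"]
        out = serial_orthogonalize(design, ["a", "b", "c"])
        assert abs(out["a"] @ out["b"]) < 1e-10
        assert abs(out["a"] @ out["c"]) < 1e-10
        assert abs(out["b"] @ out["c"]) < 1e-10

    def test_duplicate_column_residual_is_zero(self, rng):
        x = rng.normal(size=100)
        design = pd.DataFrame({"a": x, "b": x.copy()})
        out = serial_orthogonalize(design, ["a", "b"])
        assert np.allclose(out["b"], 0.0, atol=1e-10)

    def test_already_orthogonal_columns_unchanged(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal, mean-centred inputs
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)
        design = pd.DataFrame({"a": a, "b": b})
        out = serial_orthogonalize(design, ["a", "b"])
        assert np.allclose(out["b"], b, atol=1e-10)

    def test_rank_deficient_earlier_block_raises(self, rng):
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(ValueError):
            serial_orthogonalize(design, ["a", "b", "c"])


class TestOlsBetas:
    def test_noiseless_line(self):
        x = np.linspace(0, 10, 50)
        res = ols_betas(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.params[0] == pytest.approx(1.0, abs=1e-10)
        assert res.params[1] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(40, 3))
            y = rng.normal(size=40)
            res = ols_betas(y, pd.DataFrame(X))
            Xc = np.column_stack([np.ones(40), X])
            beta_oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            assert np.allclose(res.params, beta_oracle, atol=1e-8)

    def test_orthogonal_predictor_gets_zero_slope(self, rng):
        x = np.array([1.0, -1.0] * 25)
        y = np.ones(50)
        res = ols_betas(y, pd.DataFrame({"x": x}))
        assert res.params[1] == pytest.approx(0.0, abs=1e-12)


class TestLogisticFit:
    def test_independent_predictor_slope_near_zero(self, rng):
        y = rng.integers(0, 2, size=2000).astype(float)
        x = rng.normal(size=2000)
        coefs, separated = logistic_fit(y, pd.DataFrame({"x": x}))
        assert not separated
        assert abs(coefs[1]) < 0.15

    def test_matches_grid_search_oracle(self, rng):
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.4 + 1.2 * x)))
        y = (rng.random(300) < p).astype(float)
        coefs, _ = logistic_fit(y, pd.DataFrame({"x": x}))

        # brute-force likelihood maximization over a fine 2-d grid
        b0s = np.linspace(coefs[0] - 0.02, coefs[0] + 0.02, 41)
        b1s = np.linspace(coefs[1] - 0.02, coefs[1] + 0.02, 41)
        best, best_ll = None, -np.inf
        for b0 in b0s:
            for b1 in b1s:
                eta = b0 + b1 * x
                ll = float(y @ eta - np.logaddexp(0, eta).sum())
                if ll > best_ll:
                    best, best_ll = (b0, b1), ll
        assert coefs[0] == pytest.approx(best[0], abs=1e-3 + 1e-3)
        assert coefs[1] == pytest.approx(best[1], abs=2e-3)

    def test_separated_data_falls_back_to_ridge(self):
        x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
        y = (x > 0).astype(float)
        coefs, separated = logistic_fit(y, pd.DataFrame({"x": x}))
        assert separated
        assert np.all(np.isfinite(coefs))
        assert coefs[1] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestOneSampleTTest:
    def test_symmetric_values_give_t_zero(self):
        res = one_sample_ttest(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df == 4

    def test_matches_scipy_and_sign_flip_oracle(self, rng):
        values = rng.normal(0.4, 1.0, size=24)
        res = one_sample_ttest(values)
        t_ref, p_ref = sps.ttest_1samp(values, 0.0)
        assert res.t == pytest.approx(float(t_ref))
        assert res.p == pytest.approx(float(p_ref))
        # sign-flip permutation oracle
        flips = rng.choice([-1.0, 1.0], size=(20000, values.size))
        t_null = (flips * values).mean(axis=1) / (
            (flips * values).std(axis=1, ddof=1) / np.sqrt(values.size)
        )
        p_perm = float(np.mean(np.abs(t_null) >= abs(res.t)))
        assert res.p == pytest.approx(p_perm, abs=0.02)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            one_sample_ttest(np.full(5, 1.3))


class TestVifPrune:
    @staticmethod
    def _designs(rng, maker, n_subjects=4, n=128):
        return [maker(rng, n) for _ in range(n_subjects)]

    def test_orthogonal_design_untouched(self, rng):
        def maker(r, n):
            return pd.DataFrame(r.normal(size=(n, 4)), columns=list("abcd"))

        retained, history = vif_prune(self._designs(rng, maker), rng=rng)
        assert retained == list("abcd")
        assert all(v < 1.5 for v in history[0].values())

    def test_duplicated_column_removed_first(self, rng):
        def maker(r, n):
            x = r.normal(size=n)
            return pd.DataFrame({"a": x, "dup": x.copy(), "b": r.normal(size=n)})

        retained, history = vif_prune(self._designs(rng, maker), rng=rng)
        assert "b" in retained
        assert sorted(history[0], key=history[0].get)[-1] in ("a", "dup")
        assert len(retained) == 2

    def test_vif_closed_form_at_r2_08(self, rng):
        # x explains 80% of y's variance -> VIF(y) ~ 5
        n = 100_000
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        y = 2.0 * x + e  # R^2 = 4/5
        z = rng.normal(size=n)
        from gkrl.stats import _vifs

        vifs = _vifs(np.column_stack([x, y, z]))
        assert vifs[1] == pytest.approx(5.0, rel=0.05)

    def test_threshold_monotonicity(self, rng):
        def maker(r, n):
            x = r.normal(size=n)
            return pd.DataFrame(
                {
                    "a": x,
                    "b": x + 0.3 * r.normal(size=n),
                    "c": x + 0.3 * r.normal(size=n),
                    "d": r.normal(size=n),
                }
            )

        designs = self._designs(rng, maker)
        sizes = []
        for threshold in (1.5, 5.0, 50.0):
            retained, _ = vif_prune(designs, threshold=threshold, rng=np.random.default_rng(0))
            sizes.append(len(retained))
        assert sizes == sorted(sizes)


class TestConfoundExperiment:
    @pytest.fixture(scope="class")
    def results(self):
        config = TaskConfig(n_games=64)
        out = {}
        for ortho in (False, True):
            out[ortho] = confound_experiment(
                n_runs=63,
                config=config,
                rng=np.random.default_rng(2024),
                orthogonalize=ortho,
            )
        return out

    def test_confounded_cross_contrasts_spuriously_significant(self, results):
        confounded = results[False]
        # information contrast on the reward system (and vice versa) looks
        # significant even though the systems are independent by construction
        assert confounded[("reward", "information")].p < 0.05
        assert confounded[("information", "reward")].p < 0.05

    def test_own_contrasts_significant_in_both_modes(self, results):
        for ortho in (False, True):
            assert results[ortho][("reward", "reward")].p < 0.001
            assert results[ortho][("information", "information")].p < 0.001
            assert results[ortho][("reward", "reward")].mean_beta > 0
            assert results[ortho][("information", "information")].mean_beta > 0

    def test_orthogonalization_removes_cross_talk(self, results):
        orthogonalized = results[True]
        assert orthogonalized[("reward", "information")].p > 0.05
        assert orthogonalized[("information", "reward")].p > 0.05

    def test_cross_contrast_sign_matches_shared_variance(self, results):
        # with standardized regressors the cross beta IS the sample
        # correlation of the two signals, so both cross cells agree in sign
        confounded = results[False]
        b1 = confounded[("reward", "information")].mean_beta
        b2 = confounded[("information", "reward")].mean_beta
        assert np.sign(b1) == np.sign(b2)
        assert abs(b1 - b2) < 0.05


class TestBehavioralChoiceRegression:
    @staticmethod
    def _cohort(omega, beta, seed, n_subjects=8):
        from gkrl import AgentParams, make_session, simulate_agent

        rng = np.random.default_rng(seed)
        config = TaskConfig(n_games=96)
        tables = []
        for sid in range(n_subjects):
            params = AgentParams(
                alpha=float(rng.uniform(0.2, 0.7)),
                beta=beta,
                omega=omega,
                gamma=1.0 if omega == 0 else float(rng.uniform(0.5, 1.2)),
                model_tag="gkrl",
            )
            session = make_session(config, rng)
            tables.append(simulate_agent(params, session, config, rng, subject_id=sid))
        return tables

    def test_information_seekers_avoid_oversampled_targets(self):
        results = behavioral_choice_regression(self._cohort(omega=6.0, beta=0.15, seed=42))
        assert results["sample"].mean_beta < 0
        assert results["sample"].p < 0.05

    def test_reward_only_agents_track_reward_not_samples(self):
        results = behavioral_choice_regression(self._cohort(omega=0.0, beta=0.4, seed=43))
        assert results["highest_reward"].mean_beta > 0
        assert results["highest_reward"].p < 0.05
        assert abs(results["sample"].mean_beta) < abs(results["highest_reward"].mean_beta)

    def test_random_choosers_show_no_effects(self):
        results = behavioral_choice_regression(self._cohort(omega=0.0, beta=0.0, seed=44))
        assert results["highest_reward"].p > 0.05
        assert results["sample"].p > 0.05
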