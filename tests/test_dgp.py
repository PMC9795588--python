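"""Generative-model tests: covariance construction, exposure and outcome
models of both simulation scenarios, and the synthetic trial pool."""

import numpy as np
import pytest

from eca_bench import (ObservationalDataset, ScenarioConfig, generate_dataset,
                       generate_trial_pool, linear_sparse_f,
                       make_sparse_spd_covariance, sample_covariates,
                       sample_outcome_scenario1, sample_outcome_scenario2,
                       sample_treatment)
from eca_bench.estimators import estimate_unadjusted


class TestSparseSPDCovariance:
    def test_one_dimensional_is_positive(self, rng):
        cov = make_sparse_spd_covariance(1, 0.5, rng)
        assert cov.shape == (1, 1) and cov[0, 0] > 0

    def test_full_sparsity_gives_diagonal(self, rng):
        cov = make_sparse_spd_covariance(8, 1.0, rng)
        assert np.allclose(cov, np.diag(np.diag(cov)))

    def test_every_draw_is_symmetric_positive_definite(self, rng):
        for _ in range(200):
            cov = make_sparse_spd_covariance(20, 0.8, rng)
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov)[0] > 0

    def test_sparsity_parameter_controls_factor_zeros(self, rng):
        # alpha -> 0 gives dense covariances, alpha -> 1 near-diagonal ones
        off = lambda a: np.mean([
            np.mean(np.abs(make_sparse_spd_covariance(20, a, rng)
                           [np.tril_indices(20, -1)]) > 0)
            for _ in range(50)])
        assert off(0.0) > off(0.8) > off(1.0) == 0.0


class TestCovariates:
    def test_identity_covariance_recovered(self, rng):
        X = sample_covariates(10000, np.eye(4), rng)
        assert np.abs(np.cov(X.T) - np.eye(4)).max() < 0.1

    def test_single_row_shape(self, rng):
        assert sample_covariates(1, np.eye(3), rng).shape == (1, 3)

    def test_strong_correlation_reproduced(self, rng):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        X = sample_covariates(10000, cov, rng)
        assert abs(np.corrcoef(X.T)[0, 1] - 0.9) < 0.05


class TestTreatmentAssignment:
    def test_zero_coefficients_give_half_propensity(self, rng):
        X = rng.standard_normal((50, 20))
        _, prop = sample_treatment(X, np.zeros(5), rng)
        assert np.allclose(prop, 0.5)

    def test_zero_covariates_give_half_propensity(self, rng):
        X = np.zeros((10, 20))
        _, prop = sample_treatment(X, rng.uniform(-1, 1, 5), rng)
        assert np.allclose(prop, 0.5)

    def test_hand_computed_inverse_logit(self, rng):
        # beta = (sqrt(5),0,0,0,0), x1 = 1 -> logit 1 -> 1/(1+e^-1)
        X = np.zeros((1, 20))
        X[0, 0] = 1.0
        _, prop = sample_treatment(X, np.array([np.sqrt(5), 0, 0, 0, 0]), rng)
        assert prop[0] == pytest.approx(0.7310585786300049, abs=1e-12)

    def test_propensities_strictly_inside_unit_interval(self, rng):
        X = 10 * rng.standard_normal((200, 20))
        _, prop = sample_treatment(X, rng.uniform(-1, 1, 5), rng)
        assert np.all((prop > 0) & (prop < 1))


class TestScenario1Outcome:
    def test_noiseless_zero_covariates_reduce_to_effect(self, rng):
        X = np.zeros((6, 20))
        T = np.array([1, 0, 1, 0, 1, 0])
        Y = sample_outcome_scenario1(X, T, np.arange(20), 1.0, rng, noise_scale=0.0)
        assert np.allclose(Y, T)

    def test_noiseless_all_ones_give_sqrt_ten(self, rng):
        X = np.ones((4, 20))
        Y = sample_outcome_scenario1(X, np.zeros(4, int), np.arange(20), 0.0,
                                     rng, noise_scale=0.0)
        assert np.allclose(Y, np.sqrt(10.0))

    def test_effect_is_homogeneous(self, rng):
        # Y^1 - Y^0 = theta for every unit when noise is shared
        X = rng.standard_normal((50, 20))
        omega = rng.permutation(20)
        theta = 0.7
        y1 = linear_sparse_f(X, omega) + theta
        y0 = linear_sparse_f(X, omega)
        assert np.allclose(y1 - y0, theta)

    def test_confounding_biases_the_mean_difference(self, rng):
        # with a non-null exposure model the raw arm contrast misses theta
        cfg = ScenarioConfig(scenario=1, n=50000, seed=77)
        data, truth = generate_dataset(cfg)
        gap = estimate_unadjusted(data)
        mc_se = np.sqrt(np.var(data.Y) * (1 / data.n_treated + 1 / data.n_control))
        if np.abs(truth.beta).sum() > 0.5:
            assert abs(gap - truth.theta) > 2 * mc_se


class TestScenario2Outcome:
    def test_identical_permutations_cancel_heterogeneity(self, rng):
        X = rng.standard_normal((30, 20))
        T = (rng.random(30) < 0.5).astype(int)
        T[:2] = 1
        omega = rng.permutation(20)
        _, theta = sample_outcome_scenario2(X, T, omega, omega, 0.3, rng)
        assert theta == pytest.approx(0.3, abs=1e-12)

    def test_in_sample_att_matches_target_to_machine_precision(self, rng):
        X = rng.standard_normal((200, 20))
        T = (rng.random(200) < 0.4).astype(int)
        T[:2] = 1
        o0, o1 = rng.permutation(20), rng.permutation(20)
        target = -0.42
        _, theta = sample_outcome_scenario2(X, T, o0, o1, target, rng)
        tr = T == 1
        po_diff = linear_sparse_f(X, o1) + theta - linear_sparse_f(X, o0)
        assert np.mean(po_diff[tr]) == pytest.approx(target, abs=1e-12)

    def test_oracle_gcomp_recovers_null_target(self, rng):
        X = rng.standard_normal((300, 20))
        T = (rng.random(300) < 0.5).astype(int)
        o0, o1 = rng.permutation(20), rng.permutation(20)
        Y, theta = sample_outcome_scenario2(X, T, o0, o1, 0.0, rng, noise_scale=0.0)
        mu0 = linear_sparse_f(X, o0)            # oracle control-outcome model
        tr = T == 1
        assert np.mean(Y[tr] - mu0[tr]) == pytest.approx(0.0, abs=1e-10)

    def test_requires_treated_units(self, rng):
        X = rng.standard_normal((5, 20))
        with pytest.raises(ValueError):
            sample_outcome_scenario2(X, np.zeros(5, int), np.arange(20),
                                     np.arange(20), 0.0, rng)


class TestGenerateDataset:
    def test_fixed_seed_is_bitwise_deterministic(self):
        cfg = ScenarioConfig(scenario=2, n=300, seed=5)
        d1, t1 = generate_dataset(cfg)
        d2, t2 = generate_dataset(cfg)
        assert np.array_equal(d1.X, d2.X) and np.array_equal(d1.Y, d2.Y)
        assert t1.theta == t2.theta
        assert d1.to_csv_string() == d2.to_csv_string()

    @pytest.mark.parametrize("scenario", [1, 2])
    def test_null_hypothesis_forces_zero_att(self, scenario):
        cfg = ScenarioConfig(scenario=scenario, n=250, null_hypothesis=True, seed=9)
        _, truth = generate_dataset(cfg)
        assert truth.att == 0.0

    def test_effect_prior_variance(self):
        # chi-square interval for variance 0.4 at 300 draws
        thetas = [generate_dataset(ScenarioConfig(n=250, seed=s))[1].theta
                  for s in range(300)]
        assert 0.25 < np.var(thetas) < 0.55

    def test_csv_round_trip(self, tmp_path):
        data, _ = generate_dataset(ScenarioConfig(n=250, seed=1))
        path = tmp_path / "d.csv"
        data.to_csv(path)
        back = ObservationalDataset.from_csv(path)
        assert np.allclose(back.X, data.X) and np.array_equal(back.T, data.T)


class TestTrialPool:
    def test_minimal_pool_combinatorics(self):
        pool = generate_trial_pool(2, 2, 0.5, ScenarioConfig(n=100, seed=3), rng=3)
        from eca_bench.runner import _negative_control_comparisons
        comps = list(_negative_control_comparisons(pool))
        by_label = {}
        for c in comps:
            by_label.setdefault(c["label"], []).append(c)
        assert all(len(v) == 2 for v in by_label.values())

    def test_zero_shift_keeps_cross_trial_contrast_unbiased(self):
        # with no covariate shift the external control is effectively randomized
        diffs = []
        for s in range(40):
            pool = generate_trial_pool(2, 2, 0.0, ScenarioConfig(n=200, seed=s), rng=s)
            eca = pool.trials[0].two_arm("control", "control", pool.trials[1])
            diffs.append(estimate_unadjusted(eca))
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * mc_se

    def test_unadjusted_pseudo_bias_grows_with_shift(self):
        def mean_abs_bias(shift):
            vals = []
            for s in range(25):
                pool = generate_trial_pool(2, 2, shift,
                                           ScenarioConfig(n=200, seed=1000 + s),
                                           rng=1000 + s)
                eca = pool.trials[0].two_arm("control", "control", pool.trials[1])
                vals.append(abs(estimate_unadjusted(eca)))
            return np.mean(vals)

        levels = [mean_abs_bias(sh) for sh in (0.0, 1.0, 3.0)]
        assert levels[0] < levels[1] < levels[2]

    def test_pool_round_trip(self, tmp_path):
        from eca_bench import TrialPool
        pool = generate_trial_pool(3, 2, 1.0, ScenarioConfig(n=60, seed=4), rng=4)
        pool.save(tmp_path / "pool")
        back = TrialPool.load(tmp_path / "pool")
        assert back.n_trials == 3
        X0, Y0 = pool.trials[1].arms["control"]
        X1, Y1 = back.trials[1].arms["control"]
        assert np.allclose(X0, X1) and np.allclose(Y0, Y1)
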