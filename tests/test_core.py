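import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subgroupcox import (
    FitError,
    ModelSpec,
    SubgroupedSurvivalData,
    fit_model,
    fit_weighted_cox_lasso,
    fixed_weight_vector,
    select_lambda_cv,
    weighted_cox_loglik,
)
from subgroupcox.cox import _lambda_max, _prepare

from _oracles import loglik_double_loop
from conftest import make_random_data


# ---------------------------------------------------------------------------
# weighted partial log-likelihood


class TestWeightedLoglik:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_double_loop_transcription(self, seed):
        """Vectorized likelihood agrees with a literal nested-loop oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        p = int(rng.integers(1, 6))
        data = make_random_data(n, p, seed=seed + 1)
        # inject ties so the shared-risk-set convention is exercised
        if n > 6:
            t = data.times.copy()
            t[1] = t[0]
            t[3] = t[2]
            data = SubgroupedSurvivalData(t, data.events, data.subgroups, data.covariates)
        beta = rng.normal(scale=0.5, size=p)
        w = rng.uniform(0.0, 2.0, n)
        expected = loglik_double_loop(beta, data.times, data.events, data.covariates, w)
        assert weighted_cox_loglik(beta, data, w) == pytest.approx(expected, abs=1e-10)

    def test_unit_weights_reduce_to_breslow(self, small_data):
        """w=1 gives the standard unweighted Breslow partial log-likelihood."""
        beta = np.array([0.3, -0.2, 0.1])
        ones = np.ones(small_data.n)
        expected = loglik_double_loop(
            beta, small_data.times, small_data.events, small_data.covariates, ones
        )
        assert weighted_cox_loglik(beta, small_data, ones) == pytest.approx(
            expected, abs=1e-8
        )

    def test_zero_weighted_events_give_empty_sum(self, small_data):
        w = (1 - small_data.events).astype(float)  # weight 0 on every event
        assert weighted_cox_loglik(np.zeros(3), small_data, w) == 0.0

    def test_three_patient_frozen_example(self):
        # times (1,2,3), events (1,1,0), scalar covariate, weights (2,1,1)
        data = SubgroupedSurvivalData(
            [1.0, 2.0, 3.0], [1, 1, 0], [1, 1, 1], np.array([[0.5], [-1.0], [2.0]])
        )
        beta = np.array([0.7])
        w = np.array([2.0, 1.0, 1.0])
        expected = loglik_double_loop(beta, data.times, data.events, data.covariates, w)
        assert weighted_cox_loglik(beta, data, w) == pytest.approx(expected, abs=1e-12)

    def test_validation_errors(self, small_data):
        with pytest.raises(ValueError, match="length"):
            weighted_cox_loglik(np.zeros(3), small_data, np.ones(5))
        with pytest.raises(ValueError, match="nonnegative"):
            weighted_cox_loglik(np.zeros(3), small_data, -np.ones(small_data.n))
        with pytest.raises(ValueError, match="length p"):
            weighted_cox_loglik(np.zeros(7), small_data, np.ones(small_data.n))


# ---------------------------------------------------------------------------
# penalized fitting


class TestLassoFit:
    def test_large_lambda_shrinks_everything_to_zero(self, small_data):
        w = np.ones(small_data.n)
        prep = _prepare(
            small_data.times, small_data.events, small_data.covariates, w
        )
        lam_max = _lambda_max(prep)
        fit = fit_weighted_cox_lasso(small_data, w, lam_max * 1.001)
        assert np.all(fit.coefficients == 0.0)
        assert fit.n_nonzero == 0

    def test_unpenalized_fit_matches_newton_oracle(self):
        """lambda=0 agrees with an independent Breslow Newton solver."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        data = make_random_data(60, 3, seed=17)
        fit = fit_weighted_cox_lasso(data, np.ones(data.n), 0.0)
        y = np.array(
            [(bool(e), t) for e, t in zip(data.events, data.times)],
            dtype=[("event", "?"), ("time", "f8")],
        )
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow").fit(data.covariates, y)
        np.testing.assert_allclose(fit.coefficients, ref.coef_, atol=1e-4)

    def test_weight_scale_invariance(self, four_group_data):
        d = four_group_data
        w = fixed_weight_vector(d, 1, 0.3)
        a = fit_weighted_cox_lasso(d, w, 0.05)
        b = fit_weighted_cox_lasso(d, 7.0 * w, 0.05)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-12)
        assert a.weights_used.sum() == pytest.approx(d.n)
        assert b.weights_used.sum() == pytest.approx(d.n)

    @pytest.mark.parametrize("drop_event", [True, False])
    def test_zero_weight_equals_deletion(self, four_group_data, drop_event):
        """Setting a patient's weight to 0 equals removing their row."""
        d = four_group_data
        victims = np.flatnonzero(d.events == (1 if drop_event else 0))[:2]
        w = np.ones(d.n)
        w[victims] = 0.0
        keep = np.flatnonzero(w > 0)
        for lam in (0.2, 0.05, 0.01):
            fa = fit_weighted_cox_lasso(d, w, lam).coefficients
            fb = fit_weighted_cox_lasso(
                d.subset(keep), np.ones(keep.size), lam
            ).coefficients
            np.testing.assert_allclose(fa, fb, atol=1e-12)

    def test_no_usable_events_is_a_fit_error(self, small_data):
        w = (1 - small_data.events).astype(float)
        with pytest.raises(FitError):
            fit_weighted_cox_lasso(small_data, w, 0.1)

    def test_nonzero_count_monotone_along_lambda_grid(self):
        """Sparsity is non-increasing in lambda on random instances."""
        violations = 0
        for seed in range(20):
            data = make_random_data(50, 8, seed=100 + seed)
            w = np.ones(data.n)
            prep = _prepare(data.times, data.events, data.covariates, w)
            grid = np.geomspace(_lambda_max(prep), _lambda_max(prep) * 1e-2, 12)
            nnz = [
                fit_weighted_cox_lasso(data, w, lam).n_nonzero for lam in grid
            ]
            if any(b < a for a, b in zip(nnz, nnz[1:])):
                violations += 1
        assert violations == 0

    def test_kkt_conditions_at_solution(self):
        """Subgradient optimality holds at the returned coefficients."""
        data = make_random_data(80, 5, seed=7)
        w = np.ones(data.n)
        lam = 0.04
        fit = fit_weighted_cox_lasso(data, w, lam)
        prep = _prepare(data.times, data.events, data.covariates, w)
        beta_std = fit.coefficients * prep.sd

        def mean_loglik(b_std):
            coef = b_std / prep.sd
            return weighted_cox_loglik(coef, data, w) / data.n

        eps = 1e-6
        for j in range(data.p):
            bp = beta_std.copy()
            bm = beta_std.copy()
            bp[j] += eps
            bm[j] -= eps
            grad_j = (mean_loglik(bp) - mean_loglik(bm)) / (2 * eps)
            if fit.coefficients[j] == 0.0:
                assert abs(grad_j) <= lam + 1e-4
            else:
                assert grad_j == pytest.approx(
                    lam * np.sign(fit.coefficients[j]), abs=1e-4
                )


# ---------------------------------------------------------------------------
# cross-validated penalty selection


class TestSelectLambdaCV:
    def test_deterministic_given_seed(self, four_group_data):
        w = np.ones(four_group_data.n)
        a = select_lambda_cv(four_group_data, w, seed=5)
        b = select_lambda_cv(four_group_data, w, seed=5)
        assert a == b

    def test_null_model_selects_heavy_penalty(self):
        """Pure-noise covariates: CV keeps at most two spurious covariates."""
        sparse_enough = 0
        for seed in range(10):
            data = make_random_data(100, 12, seed=1000 + seed)
            w = np.ones(data.n)
            lam = select_lambda_cv(data, w, seed=seed)
            fit = fit_weighted_cox_lasso(data, w, lam)
            if fit.n_nonzero <= 2:
                sparse_enough += 1
        assert sparse_enough >= 9

    def test_two_folds_on_tiny_data(self):
        data = SubgroupedSurvivalData(
            [1.0, 2.0, 3.0, 4.0],
            [1, 0, 1, 0],
            [1, 1, 1, 1],
            np.array([[0.1], [0.4], [-0.3], [0.2]]),
        )
        lam = select_lambda_cv(data, np.ones(4), n_folds=2, seed=0)
        assert lam >= 0.0


# ---------------------------------------------------------------------------
# model constructions


class TestModelConstructions:
    def test_fixed_weight_vector_construction(self):
        data = make_random_data(40, 2, seed=2, n_subgroups=4)
        w = fixed_weight_vector(data, 2, 0.3)
        assert np.all(w[data.subgroups == 2] == 1.0)
        assert np.all(w[data.subgroups != 2] == 0.3)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fixed_weight_vector(data, 2, 1.5)
        with pytest.raises(ValueError, match="absent"):
            fixed_weight_vector(data, 9, 0.5)

    def test_w0_fixed_equals_subgroup_model(self, four_group_data):
        """w=0 for outsiders reproduces the subgroup-only fit exactly."""
        f_fixed = fit_model(
            ModelSpec("fixed_weights", 2, fixed_w=0.0), four_group_data, seed=11
        )
        f_sub = fit_model(ModelSpec("subgroup", 2), four_group_data, seed=11)
        assert f_fixed.lambda_ == f_sub.lambda_
        np.testing.assert_allclose(f_fixed.coefficients, f_sub.coefficients, atol=1e-12)

    def test_w1_fixed_equals_pooled_without_indicator(self, four_group_data):
        d = four_group_data
        w1 = fixed_weight_vector(d, 3, 1.0)
        np.testing.assert_array_equal(w1, np.ones(d.n))
        f_fixed = fit_model(ModelSpec("fixed_weights", 3, fixed_w=1.0), d, seed=4)
        lam = select_lambda_cv(d, np.ones(d.n), seed=4)
        pooled = fit_weighted_cox_lasso(d, np.ones(d.n), lam)
        np.testing.assert_array_equal(f_fixed.coefficients, pooled.coefficients)

    def test_subgroup_mode_uses_only_target_rows(self, four_group_data):
        d = four_group_data
        fit = fit_model(ModelSpec("subgroup", 4), d, seed=0)
        idx = np.flatnonzero(d.subgroups == 4)
        direct = fit_model(
            ModelSpec("subgroup", 1), d.subset(idx, relabel=True), seed=0
        )
        np.testing.assert_array_equal(fit.coefficients, direct.coefficients)

    def test_combined_mode_appends_s_minus_one_dummies(self, four_group_data):
        fit = fit_model(ModelSpec("combined", 1), four_group_data, seed=0)
        assert fit.coefficients.shape[0] == four_group_data.p + 3
        assert fit.dummy_levels == (2, 3, 4)
        assert fit.reference_level == 1

    def test_modelspec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec("fixed_weights", 1)  # fixed_w missing
        with pytest.raises(ValueError):
            ModelSpec("subgroup", 1, fixed_w=0.5)
        with pytest.raises(ValueError):
            ModelSpec("estimated_weights", 1)  # classifier missing
        with pytest.raises(ValueError):
            ModelSpec("subgroup", 1, classifier="rf")
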