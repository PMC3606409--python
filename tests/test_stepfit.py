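"""Step regression, Cochrane–Orcutt whitening, information criteria and
backward selection."""

import numpy as np
import pytest

from stepgls import (
    ARModel,
    RunConfig,
    backward_select,
    co_transform,
    design_matrix,
    detect_steps,
    fit_gls,
    fit_ols,
    information_criteria,
    pacf,
    simulate_ar,
)
from stepgls.stepfit import _fit_dense

AR7 = ARModel(
    order=7,
    coefficients=(0.222, 0.072, 0.035, 0.015, 0.016, 0.003, 0.013),
    innovation_sd=1.0,
)


def make_trace(n, steps, noise=None, seed=0):
    y = np.zeros(n)
    for idx, size in steps:
        y[idx:] += size
    if noise is not None:
        y = y + simulate_ar(noise, n, seed=seed)
    return y


class TestDesignMatrix:
    def test_no_steps_is_intercept_only(self):
        X = design_matrix(4, [])
        np.testing.assert_array_equal(X, np.ones((4, 1)))

    def test_indicator_column(self):
        X = design_matrix(5, [3])
        np.testing.assert_array_equal(X[:, 1], [0, 0, 0, 1, 1])

    def test_full_column_rank(self):
        X = design_matrix(50, [10, 20, 35])
        assert np.linalg.matrix_rank(X) == 4

    def test_duplicates_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            design_matrix(10, [3, 3])
        with pytest.raises(ValueError):
            design_matrix(10, [0])
        with pytest.raises(ValueError):
            design_matrix(10, [10])


class TestFitOLS:
    def test_noiseless_exact_interpolation(self):
        y = make_trace(100, [(30, 1.5), (60, -0.5)])
        fit = fit_ols(y, [30, 60])
        assert fit.model.baseline == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.model.step_sizes, [1.5, -0.5], atol=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_estimates_equal_segment_mean_differences(self, rng):
        # closed-form oracle for the saturated indicator basis
        y = rng.normal(size=200) + make_trace(200, [(50, 2.0), (120, 1.0)])
        fit = fit_ols(y, [50, 120])
        means = [y[:50].mean(), y[50:120].mean(), y[120:].mean()]
        assert fit.model.baseline == pytest.approx(means[0])
        assert fit.model.step_sizes[0] == pytest.approx(means[1] - means[0])
        assert fit.model.step_sizes[1] == pytest.approx(means[2] - means[1])

    def test_flat_trace_baseline_is_sample_mean(self, rng):
        y = rng.normal(1.7, 0.3, size=500)
        fit = fit_ols(y, [])
        assert fit.model.baseline == pytest.approx(y.mean())
        assert fit.sigma2 == pytest.approx(y.var(), rel=1e-9)


class TestCoTransform:
    def test_order_zero_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(co_transform(x, ARModel(0, (), 1.0)), x)

    def test_constant_column_under_ar1(self):
        z = co_transform(np.ones(10), ARModel(1, (0.3,), 1.0))
        assert z.size == 9
        np.testing.assert_allclose(z, 0.7)

    def test_whitens_its_own_process(self):
        x = simulate_ar(AR7, 100_000, seed=9)
        z = co_transform(x, AR7)
        res = pacf(z, 15)
        exceed = np.abs(res.values[1:]) > res.ci_bound
        assert exceed.sum() <= 3  # white-noise behavior


class TestFitGLS:
    def test_order_zero_identical_to_ols(self, rng):
        y = rng.normal(size=300) + make_trace(300, [(100, 1.0), (200, -2.0)])
        a = fit_ols(y, [100, 200])
        b = fit_gls(y, [100, 200], ARModel(0, (), 1.0))
        np.testing.assert_allclose(a.model.step_sizes, b.model.step_sizes,
                                   atol=1e-12)
        np.testing.assert_allclose(a.standard_errors, b.standard_errors,
                                   atol=1e-12)
        assert a.loglik == pytest.approx(b.loglik)

    def test_noiseless_exact_under_any_ar(self):
        y = make_trace(400, [(100, 1.0), (250, 2.0)])
        fit = fit_gls(y, [100, 250], AR7)
        np.testing.assert_allclose(fit.model.step_sizes, [1.0, 2.0], atol=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_generic_dense_solver(self, seed):
        rng = np.random.default_rng(seed)
        steps = [(70, 1.0), (73, -0.6), (160, 0.8)]  # incl. near-collision
        y = make_trace(260, steps, noise=AR7, seed=seed)
        idx = [s for s, _ in steps]
        fast = fit_gls(y, idx, AR7)
        dense = _fit_dense(y, idx, AR7)
        np.testing.assert_allclose(
            np.r_[fast.model.baseline, fast.model.step_sizes], dense, atol=1e-8
        )

    def test_gls_standard_errors_calibrated_under_ar_noise(self):
        # 95% CI coverage for the step size: GLS is calibrated, naive OLS
        # undercovers because it ignores the positive autocorrelation.
        ar1 = ARModel(1, (0.6,), 1.0)
        cover_gls = cover_ols = 0
        n_rep = 150
        for i in range(n_rep):
            y = make_trace(1200, [(600, 1.0)], noise=ar1, seed=1000 + i)
            g = fit_gls(y, [600], ar1)
            o = fit_ols(y, [600])
            cover_gls += abs(g.model.step_sizes[0] - 1.0) < 1.96 * g.standard_errors[1]
            cover_ols += abs(o.model.step_sizes[0] - 1.0) < 1.96 * o.standard_errors[1]
        assert 0.90 <= cover_gls / n_rep <= 0.99
        assert cover_ols < cover_gls

    def test_rank_deficiency_reported(self):
        y = np.zeros(20)
        with pytest.raises(ValueError):
            fit_gls(y, [5, 5], AR7)


class TestInformationCriteria:
    def test_worked_example(self):
        aic, bic = information_criteria(-100.0, 5, 1000)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200 + 5 * np.log(1000))

    def test_bic_aic_penalty_crossover_at_seven(self):
        # per-parameter penalty: ln(n) vs 2 -- equal footing ends at n = 7
        crossings = [n for n in range(1, 30) if np.log(n) <= 2.0]
        assert max(crossings) == 7
        aic7, bic7 = information_criteria(-10.0, 3, 7)
        aic8, bic8 = information_criteria(-10.0, 3, 8)
        assert bic7 <= aic7 and bic8 > aic8

    def test_single_parameter_gap(self):
        aic, bic = information_criteria(-5.0, 1, 100)
        assert bic - aic == pytest.approx(np.log(100) - 2)


class TestBackwardSelect:
    def test_noiseless_three_steps_recovered_exactly(self):
        y = make_trace(1500, [(400, 1.0), (800, -1.0), (1100, 2.0)])
        cand = [150, 400, 600, 800, 1100, 1300]
        fit = backward_select(y, cand, RunConfig())
        np.testing.assert_array_equal(fit.model.step_indices, [400, 800, 1100])
        np.testing.assert_allclose(fit.model.step_sizes, [1.0, -1.0, 2.0],
                                   atol=1e-9)

    def test_pure_noise_selects_baseline_only(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=3000)
        cand = [500, 1200, 1900, 2500]
        fit = backward_select(y, cand, RunConfig())
        assert fit.model.k == 0

    def test_empty_candidates_give_baseline_fit(self, rng):
        y = rng.normal(size=500)
        fit = backward_select(y, [], RunConfig())
        assert fit.model.k == 0
        assert fit.model.baseline == pytest.approx(y.mean())

    def test_likelihood_monotone_in_candidates(self, rng):
        # a nested larger model never has a smaller maximized likelihood
        y = rng.normal(size=800) + make_trace(800, [(300, 1.0)])
        sub = fit_ols(y, [300])
        sup = fit_ols(y, [300, 500])
        assert sup.loglik >= sub.loglik - 1e-9

    def test_path_recorded(self, rng):
        y = rng.normal(size=600) + make_trace(600, [(200, 1.5)])
        fit = backward_select(y, [200, 400], RunConfig())
        assert fit.path is not None
        assert [p["n_steps"] for p in fit.path] == [2, 1, 0]


class TestDetectSteps:
    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_steps(np.zeros(50), RunConfig())

    def test_constant_trace_baseline_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = detect_steps(np.full(500, 2.0), RunConfig())
        assert fit.model.k == 0
        assert fit.model.baseline == pytest.approx(2.0)

    def test_noiseless_pipeline_exact(self):
        y = make_trace(2000, [(400, 1.0), (1100, 2.0), (1600, -1.0)])
        fit = detect_steps(y, RunConfig())
        np.testing.assert_array_equal(fit.model.step_indices, [400, 1100, 1600])
        np.testing.assert_allclose(fit.model.step_sizes, [1.0, 2.0, -1.0],
                                   atol=1e-9)
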