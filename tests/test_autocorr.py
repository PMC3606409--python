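"""Correlogram estimators, AR order identification and the AR simulator."""

import numpy as np
import pytest
from scipy import linalg

from stepgls import ARModel, acf, fit_ar, pacf, simulate_ar
from stepgls.autocorr import (
    DegenerateSeriesError,
    durbin_levinson,
    stationary_sd,
)


class TestACF:
    def test_lag_zero_is_one_and_bounded(self, rng):
        x = rng.normal(size=500)
        res = acf(x, 20)
        assert res.values[0] == 1.0
        assert np.all(np.abs(res.values) <= 1.0)
        assert res.ci_bound == pytest.approx(1.96 / np.sqrt(500))

    def test_ar1_acf_decays_geometrically(self, ar1_long):
        # closed form for AR(1): rho(h) = a^h
        _, x = ar1_long
        res = acf(x, 6)
        expected = 0.5 ** np.arange(7)
        assert np.allclose(res.values, expected, atol=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            acf(np.ones(100), 5)


class TestPACF:
    def test_white_noise_within_null_bound(self, white_long):
        res = pacf(white_long, 20)
        exceed = np.abs(res.values[1:]) > res.ci_bound
        # ~5% exceedance expected under the null; allow up to 4 of 20
        assert exceed.sum() <= 4

    def test_ar1_cuts_off_after_lag_one(self, ar1_long):
        _, x = ar1_long
        res = pacf(x, 10)
        assert res.values[1] == pytest.approx(0.5, abs=0.02)
        assert np.all(np.abs(res.values[2:]) < 3 * res.ci_bound)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_durbin_levinson_matches_regression_oracle(self, seed):
        # PACF at lag h == last coefficient of regressing x_t on its h lags
        # (with biased Yule-Walker normalization, oracle = Toeplitz solve)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=2000).cumsum() * 0.01 + rng.normal(size=2000)
        res = pacf(x, 8)
        n = x.size
        xc = x - x.mean()
        gamma = np.array(
            [np.dot(xc[: n - h], xc[h:]) / n for h in range(9)]
        )
        rho = gamma / gamma[0]
        for h in range(1, 9):
            phi = linalg.solve_toeplitz(rho[:h], rho[1 : h + 1])
            assert res.values[h] == pytest.approx(phi[-1], abs=1e-8)

    def test_durbin_levinson_innovation_variances_decrease(self):
        rho = 0.6 ** np.arange(6)
        _, _, s2 = durbin_levinson(rho)
        assert np.all(np.diff(s2) <= 1e-12)


class TestFitAR:
    def test_white_noise_gives_order_zero(self, white_long):
        assert fit_ar(white_long, max_order=20).order == 0

    def test_ar2_recovery(self):
        model = ARModel(order=2, coefficients=(0.5, 0.3), innovation_sd=1.0)
        x = simulate_ar(model, 100_000, seed=5)
        fit = fit_ar(x, max_order=10)
        assert fit.order == 2
        assert np.allclose(fit.coefficients, (0.5, 0.3), atol=0.02)
        assert fit.innovation_sd == pytest.approx(1.0, abs=0.02)

    def test_order_recovery_frequency(self):
        # Above-the-bound lag-p coefficient => true order found in > 90% of
        # realizations.
        model = ARModel(order=2, coefficients=(0.5, 0.3), innovation_sd=1.0)
        hits = sum(
            fit_ar(simulate_ar(model, 20_000, seed=100 + i), max_order=10).order == 2
            for i in range(20)
        )
        assert hits >= 18

    def test_aic_method_agrees_on_strong_ar1(self, ar1_long):
        _, x = ar1_long
        assert fit_ar(x, max_order=10, method="aic").order >= 1


class TestSimulateAR:
    def test_order_zero_marginal_sd(self):
        model = ARModel(order=0, coefficients=(), innovation_sd=2.0)
        x = simulate_ar(model, 200_000, seed=3)
        assert np.std(x) == pytest.approx(2.0, rel=0.02)

    def test_ar1_stationary_variance_closed_form(self):
        # var = sigma^2 / (1 - a^2) = 1 / 0.19
        model = ARModel(order=1, coefficients=(0.9,), innovation_sd=1.0)
        x = simulate_ar(model, 1_000_000, seed=4)
        assert np.var(x) == pytest.approx(1 / 0.19, rel=0.05)
        assert stationary_sd(model) == pytest.approx(np.sqrt(1 / 0.19), rel=1e-9)

    def test_determinism(self):
        model = ARModel(order=2, coefficients=(0.4, 0.2), innovation_sd=1.0)
        a = simulate_ar(model, 1000, seed=42)
        b = simulate_ar(model, 1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_nonstationary_rejected(self):
        model = ARModel(order=1, coefficients=(1.05,), innovation_sd=1.0)
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_ar(model, 100, seed=0)

    def test_simulated_acf_matches_theory(self):
        # Yule-Walker autocorrelations of the simulated process match the
        # model's theoretical ACF within Monte-Carlo error.
        from statsmodels.tsa.arima_process import arma_acf

        model = ARModel(order=2, coefficients=(0.5, 0.3), innovation_sd=1.0)
        x = simulate_ar(model, 200_000, seed=6)
        emp = acf(x, 10).values
        theo = arma_acf(model.ar_poly, [1.0], lags=11)
        assert np.allclose(emp, theo, atol=0.02)


class TestARModel:
    def test_coefficient_length_enforced(self):
        with pytest.raises(ValueError):
            ARModel(order=2, coefficients=(0.5,), innovation_sd=1.0)

    def test_stationarity_check(self):
        assert ARModel(1, (0.99,), 1.0).is_stationary()
        assert not ARModel(1, (1.01,), 1.0).is_stationary()
        assert ARModel(0, (), 1.0).is_stationary()
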