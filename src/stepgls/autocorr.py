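"""Autocorrelation diagnostics, AR(p) estimation and AR noise simulation.

Single-molecule trajectories recorded with optical tweezers carry noise that
is correlated in time: the noise value at one sample is a linear function of
the previous few samples plus an i.i.d. Gaussian innovation.  This module
provides the tools to characterize that structure — the sample
autocorrelation function (ACF), the partial autocorrelation function (PACF),
Yule–Walker AR(p) estimation with PACF-based order identification — and a
reproducible simulator for stationary AR(p) noise.

The PACF of an AR(p) process cuts off after lag p, which is the property the
order-identification rule exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal, stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "ARModel",
    "CorrelogramResult",
    "acf",
    "pacf",
    "durbin_levinson",
    "fit_ar",
    "simulate_ar",
    "stationary_sd",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series is constant (zero variance) and correlation
    diagnostics are undefined."""


@dataclass(frozen=True)
class ARModel:
    """A zero-mean autoregressive noise model of order ``p``.

    x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t,  e_t ~ N(0, innovation_sd^2)

    ``order == 0`` means i.i.d. Gaussian noise.
    """

    order: int
    coefficients: tuple[float, ...]
    innovation_sd: float

    def __post_init__(self) -> None:
        coefs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coefs)
        if self.order < 0:
            raise ValueError("order must be non-negative")
        if len(coefs) != self.order:
            raise ValueError(
                f"expected {self.order} coefficients, got {len(coefs)}"
            )
        if not self.innovation_sd > 0:
            raise ValueError("innovation_sd must be positive")

    @property
    def ar_poly(self) -> np.ndarray:
        """Coefficients of 1 - a_1 B - ... - a_p B^p (for scipy filters)."""
        return np.r_[1.0, -np.asarray(self.coefficients)]

    def is_stationary(self) -> bool:
        """True when all roots of the AR polynomial lie outside the unit
        circle (second-order stationarity)."""
        if self.order == 0:
            return True
        roots = np.roots(self.ar_poly[::-1])
        return bool(np.all(np.abs(roots) > 1.0 + 1e-12))

    def require_stationary(self) -> None:
        if not self.is_stationary():
            raise ValueError(
                "AR coefficients are non-stationary (roots of the AR "
                "polynomial inside the unit circle)"
            )


@dataclass(frozen=True)
class CorrelogramResult:
    """ACF or PACF values at lags 0..L with the 95% no-correlation bound."""

    lags: np.ndarray
    values: np.ndarray
    ci_bound: float
    kind: str = "acf"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag": self.lags, "value": self.values, "ci_bound": self.ci_bound}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _validate_series(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if x.size <= max_lag:
        raise ValueError("series must be longer than max_lag")
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError(
            "series is constant; autocorrelation is undefined"
        )
    return x


def acf(x, max_lag: int) -> CorrelogramResult:
    """Sample autocorrelation at lags 0..max_lag.

    Uses the biased (divide-by-n) estimator, which guarantees a valid,
    positive semi-definite correlation sequence; value at lag 0 is exactly 1.
    """
    x = _validate_series(x, max_lag)
    vals = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        values=np.asarray(vals),
        ci_bound=1.96 / np.sqrt(x.size),
        kind="acf",
    )


def durbin_levinson(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Durbin–Levinson recursion on autocorrelations ``rho[0..L]``.

    Returns ``(pacf, phi, sigma2_scale)`` where ``pacf[h]`` is the partial
    autocorrelation at lag h (``pacf[0] = 1``), ``phi`` the final-order AR
    coefficients and ``sigma2_scale[h]`` the innovation variance of the
    order-h model relative to the process variance.
    """
    rho = np.asarray(rho, dtype=float)
    L = rho.size - 1
    pacf_vals = np.empty(L + 1)
    pacf_vals[0] = 1.0
    sigma2 = np.empty(L + 1)
    sigma2[0] = 1.0
    phi = np.zeros(L)
    phi_prev = np.zeros(L)
    for h in range(1, L + 1):
        num = rho[h] - np.dot(phi_prev[: h - 1], rho[h - 1 : 0 : -1])
        kappa = num / sigma2[h - 1]
        if h > 1:
            phi[: h - 1] = phi_prev[: h - 1] - kappa * phi_prev[h - 2 :: -1]
        phi[h - 1] = kappa
        sigma2[h] = sigma2[h - 1] * (1.0 - kappa**2)
        pacf_vals[h] = kappa
        phi_prev[:h] = phi[:h]
    return pacf_vals, phi, sigma2


def pacf(x, max_lag: int) -> CorrelogramResult:
    """Partial autocorrelation at lags 1..max_lag (lag 0 set to 1).

    Computed by the Durbin–Levinson recursion on the biased sample ACF
    (successive Yule–Walker solutions); equivalently the last coefficient of
    the regression of x_t on x_{t-1}..x_{t-h}.
    """
    x = _validate_series(x, max_lag)
    rho = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    vals, _, _ = durbin_levinson(rho)
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        values=vals,
        ci_bound=1.96 / np.sqrt(x.size),
        kind="pacf",
    )


def fit_ar(
    x,
    max_order: int = 20,
    method: str = "pacf",
    alpha: float = 0.05,
    simultaneous: bool = True,
) -> ARModel:
    """Estimate an AR model from a series.

    Order selection (``method="pacf"``, the default) takes the largest lag
    ``<= max_order`` whose PACF exceeds the no-correlation bound, scanning
    from ``max_order`` downward — the standard reading of a PACF correlogram.
    Because ``max_order`` lags are inspected at once, the bound is
    Bonferroni-corrected (``z_{1-alpha/2/max_order}/sqrt(n)``) so that a
    white-noise input yields order 0 with probability ~``1-alpha`` rather
    than ``0.95**max_order``; set ``simultaneous=False`` for the raw per-lag
    1.96/sqrt(n) bound.  ``method="aic"`` instead minimizes the Gaussian AIC
    over orders 0..max_order.

    Coefficients come from the Yule–Walker equations at the selected order,
    the innovation SD from the Durbin–Levinson residual variance.
    """
    x = _validate_series(x, max_order)
    n = x.size
    rho = _sm_acf(x, nlags=max_order, fft=True, adjusted=False)
    pacf_vals, _, sigma2_scale = durbin_levinson(rho)
    gamma0 = float(np.var(x))

    if method == "pacf":
        if simultaneous:
            z = stats.norm.ppf(1.0 - alpha / 2.0 / max_order)
        else:
            z = stats.norm.ppf(1.0 - alpha / 2.0)
        bound = z / np.sqrt(n)
        significant = np.flatnonzero(np.abs(pacf_vals[1:]) > bound) + 1
        order = int(significant.max()) if significant.size else 0
    elif method == "aic":
        # Gaussian AIC with the order-h innovation variance; +2 per AR coef.
        aics = n * np.log(gamma0 * sigma2_scale) + 2.0 * np.arange(max_order + 1)
        order = int(np.argmin(aics))
    else:
        raise ValueError(f"unknown order-selection method: {method!r}")

    if order == 0:
        return ARModel(order=0, coefficients=(), innovation_sd=float(np.std(x)))
    coefs = linalg.solve_toeplitz(rho[:order], rho[1 : order + 1])
    sigma2 = gamma0 * float(sigma2_scale[order])
    return ARModel(
        order=order,
        coefficients=tuple(coefs),
        innovation_sd=float(np.sqrt(max(sigma2, 1e-300))),
    )


def stationary_sd(model: ARModel) -> float:
    """Marginal (stationary) standard deviation of the AR process."""
    model.require_stationary()
    if model.order == 0:
        return model.innovation_sd
    from statsmodels.tsa.arima_process import arma_acf

    rho = arma_acf(model.ar_poly, np.array([1.0]), lags=model.order + 1)
    gamma0 = model.innovation_sd**2 / (
        1.0 - np.dot(model.coefficients, rho[1 : model.order + 1])
    )
    return float(np.sqrt(gamma0))


def simulate_ar(
    model: ARModel, n: int, seed, burn_in: int | None = None
) -> np.ndarray:
    """Simulate a zero-mean stationary AR(p) realization of length ``n``.

    ``burn_in`` samples (default ``max(500, 50*order)``) are generated and
    discarded to wash out the transient from the zero initial state.
    Reproducible for a fixed ``seed`` (an int or ``numpy`` Generator /
    SeedSequence).
    """
    if n < 1:
        raise ValueError("n must be positive")
    model.require_stationary()
    if burn_in is None:
        burn_in = max(500, 50 * model.order)
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, model.innovation_sd, size=n + burn_in)
    if model.order == 0:
        return e[burn_in:]
    x = signal.lfilter([1.0], model.ar_poly, e)
    return x[burn_in:]


def _replace(model: ARModel, **kw) -> ARModel:
    return dataclasses.replace(model, **kw)
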