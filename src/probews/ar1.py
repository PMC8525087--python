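"""Sliding-window AR(1) early-warning indicator with ARMA-surrogate testing.

The field-standard baseline detector: detrend with a Gaussian kernel, fit an
AR(1) process by ordinary least squares inside overlapping windows, quantify
the trend of the lag-1 autocorrelation trajectory with Kendall's tau, and
assess significance against surrogate series resimulated from the best-AIC
ARMA(p, q) fit to the original data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.arima_process import arma_generate_sample

from .timeseries import (
    TimeSeries,
    TrendTest,
    ZeroSpreadError,
    gaussian_smooth,
    kendall_tau,
    scott_bandwidth,
)

__all__ = [
    "AR1Fit",
    "EWSTrajectory",
    "fit_ar1_ols",
    "sliding_ar1",
    "fit_best_arma",
    "simulate_arma_surrogates",
    "surrogate_test",
    "ar1_indicator",
]


@dataclass(frozen=True)
class AR1Fit:
    """OLS fit of ``X[t+1] = mu + phi * (X[t] - mu) + eps``."""

    phi: float
    mu: float
    sigma: float

    @property
    def stationary(self) -> bool:
        """|phi| < 1; above 1 the mean level acts as a repeller."""
        return abs(self.phi) < 1.0


@dataclass(frozen=True)
class EWSTrajectory:
    """Per-time lag-1 autocorrelation estimates from one of the detectors."""

    times: np.ndarray
    phi: np.ndarray
    model: str  # "ar1" | "tvar" | "ptvar"
    window_frac: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.phi):
            raise ValueError("times and phi must be equally long")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")


def fit_ar1_ols(residuals: np.ndarray) -> AR1Fit:
    """Ordinary-least-squares AR(1) fit to (detrended) residuals.

    phi minimizes sum over t of (x~[t+1] - phi * x~[t])^2 with x~ the
    demeaned series, giving phi = sum(x~[t] x~[t+1]) / sum over the
    regression frame of x~[t]^2.
    """
    x = np.asarray(residuals, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for an AR(1) fit")
    mu = float(np.mean(x))
    x0, x1 = x[:-1], x[1:]
    # OLS of X[t+1] on (1, X[t]); the slope is the lag-1 autocorrelation
    # estimate and coincides with the uniform-weight limit of the kernel
    # TVAR regression.
    xc = x0 - np.mean(x0)
    denom = float(np.sum(xc**2))
    if denom <= 0:
        raise ZeroSpreadError("zero-variance input: AR(1) slope undefined")
    phi = float(np.sum(xc * (x1 - np.mean(x1))) / denom)
    resid = (x1 - np.mean(x1)) - phi * xc
    sigma = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    return AR1Fit(phi=phi, mu=mu, sigma=sigma)


def sliding_ar1(
    ts: TimeSeries,
    window_frac: float = 0.5,
    detrend_bandwidth: float | str = "auto",
) -> EWSTrajectory:
    """Sliding-window AR(1) indicator trajectory.

    The whole series is detrended once (Scott's-rule bandwidth when
    ``detrend_bandwidth="auto"``, converted to time units via the median
    sampling interval), then an AR(1) process is fitted by OLS inside each
    window of ``round(window_frac * n)`` samples, advanced one sample at a
    time.  Each phi estimate is anchored at the window's right edge so the
    indicator is causal.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must lie in (0, 1]")
    ts.warn_if_irregular()
    n = len(ts)
    w = int(round(window_frac * n))
    if w < 5:
        raise ValueError(f"window of {w} samples is too short (need >= 5)")
    if n < 2 * 5:
        raise ValueError("series too short for a sliding-window analysis")
    if detrend_bandwidth == "auto":
        # Scott's rule applied to the regressor (time), the kernel-regression
        # convention (cf. R bw.nrd); applying it to the data values would give
        # sub-sample bandwidths whenever the data sd is O(1).
        bw = scott_bandwidth(ts.times)
    else:
        bw = float(detrend_bandwidth)
    resid = gaussian_smooth(ts, bw).residuals
    phis = np.empty(n - w + 1)
    for i in range(n - w + 1):
        phis[i] = fit_ar1_ols(resid[i : i + w]).phi
    return EWSTrajectory(
        times=ts.times[w - 1 :], phi=phis, model="ar1", window_frac=window_frac
    )


def ar1_indicator(
    window_frac: float = 0.5, detrend_bandwidth: float | str = "auto"
) -> Callable[[TimeSeries], np.ndarray]:
    """Indicator closure for :func:`surrogate_test` (phi trajectory only)."""

    def indicator(ts: TimeSeries) -> np.ndarray:
        return sliding_ar1(ts, window_frac, detrend_bandwidth).phi

    return indicator


def fit_best_arma(values: np.ndarray, max_order: int = 5):
    """AIC-minimizing ARMA(p, q) fit over the grid p, q = 1..max_order.

    Ties are broken by smallest p + q, then smallest p.  Returns
    ``(p, q, fitted_model)`` where ``fitted_model`` is the statsmodels
    result used to resimulate surrogates.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 points to select an ARMA order")
    best = None
    attempted = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(1, max_order + 1):
            for q in range(1, max_order + 1):
                attempted.append((p, q))
                try:
                    res = ARIMA(x, order=(p, 0, q), trend="c").fit()
                    aic = res.aic
                except Exception:
                    continue
                if not np.isfinite(aic):
                    continue
                key = (aic, p + q, p)
                if best is None or key < best[0]:
                    best = (key, p, q, res)
    if best is None:
        raise RuntimeError(f"no ARMA fit converged; attempted orders {attempted}")
    _, p, q, res = best
    return p, q, res


def simulate_arma_surrogates(
    arma_result, n_surrogates: int, length: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Draw Gaussian-innovation surrogate series from a fitted ARMA model."""
    ar = np.r_[1.0, -arma_result.arparams]
    ma = np.r_[1.0, arma_result.maparams]
    scale = float(np.sqrt(arma_result.params[-1]))
    mean = float(arma_result.params[0])
    out = []
    for _ in range(n_surrogates):
        x = arma_generate_sample(
            ar, ma, nsample=length, scale=scale, distrvs=rng.standard_normal, burnin=200
        )
        out.append(x + mean)
    return out


def surrogate_test(
    ts: TimeSeries,
    indicator: Callable[[TimeSeries], np.ndarray],
    n_surrogates: int = 1000,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
    max_order: int = 5,
    arma_result=None,
    surrogates: Sequence[np.ndarray] | None = None,
    null_indicator: Callable[[TimeSeries], np.ndarray] | None = None,
    null_taus: np.ndarray | None = None,
) -> TrendTest:
    """One-tailed surrogate-data test of a positive indicator trend.

    Fits the best-AIC ARMA(p, q) null model to the original data, simulates
    ``n_surrogates`` series of equal length, estimates a phi trajectory on
    each with ``null_indicator`` (by default the same ``indicator``), and
    ranks the observed Kendall tau in the resulting null distribution of
    taus.  The p-value uses the add-one estimator
    ``(1 + #{tau_surr >= tau_obs}) / (n_surrogates + 1)`` so it can never be
    exactly zero.

    ``arma_result`` / ``surrogates`` / ``null_taus`` let callers that test
    several indicators on one series reuse the null model, its draws, and a
    shared null-tau distribution.
    """
    if surrogates is None and null_taus is None and n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a usable p-value")
    rng = np.random.default_rng() if rng is None else rng
    tau_obs = kendall_tau(indicator(ts))
    if null_taus is None:
        if surrogates is None:
            if arma_result is None:
                _, _, arma_result = fit_best_arma(ts.values, max_order=max_order)
            surrogates = simulate_arma_surrogates(arma_result, n_surrogates, len(ts), rng)
        null_indicator = indicator if null_indicator is None else null_indicator
        taus = []
        n_failed = 0
        for x in surrogates:
            try:
                taus.append(kendall_tau(null_indicator(TimeSeries(ts.times, x, ts.name))))
            except Exception:
                n_failed += 1
        if n_failed > 0.05 * len(surrogates):
            raise RuntimeError(
                f"indicator failed on {n_failed}/{len(surrogates)} surrogates"
            )
        null_taus = np.asarray(taus)
    taus = np.asarray(null_taus)
    p = (1.0 + np.sum(taus >= tau_obs)) / (len(taus) + 1.0)
    return TrendTest(
        tau=tau_obs,
        p_value=float(p),
        alpha=alpha,
        method="surrogate",
        null_or_posterior_taus=taus,
    )
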