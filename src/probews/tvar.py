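"""Nonprobabilistic time-varying AR(1) via Nadaraya-Watson kernel regression.

TVAR(1) lets both the mean level and the autoregressive coefficient drift:
``X[t+1] = mu_t + phi_t * (X[t] - mu_t) + eps_t``.  It is fitted once across
the whole raw series (no detrending, no sliding windows) by locally
constant, Gaussian-kernel-weighted least squares of X[t+1] on (1, X[t]).
The bandwidth is a fraction of the rescaled-to-[0, 1] time range and is
chosen by leave-one-out cross-validation unless fixed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ar1 import EWSTrajectory, fit_ar1_ols, surrogate_test
from .timeseries import TimeSeries, TrendTest

__all__ = ["TVARFit", "tvar_fit", "loocv_bandwidth", "tvar_trend_test", "tvar_indicator"]

DEFAULT_BANDWIDTH_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 4)


@dataclass(frozen=True)
class TVARFit:
    """Kernel-weighted least-squares fit of the time-varying AR(1)."""

    times: np.ndarray
    mu_t: np.ndarray
    phi_t: np.ndarray
    bandwidth: float  # fraction of the rescaled time range
    sigma: float  # one-step-ahead residual sd

    def trajectory(self) -> EWSTrajectory:
        return EWSTrajectory(times=self.times, phi=self.phi_t, model="tvar")


def _design_sums(u_eval, u_pairs, x0, x1, bandwidth):
    """Kernel-weighted moment sums for the regression of x1 on (1, x0).

    Rows index evaluation points, columns the (X[t], X[t+1]) pairs.
    Returns the weight matrix and the five moment-sum vectors.
    """
    z = (u_eval[:, None] - u_pairs[None, :]) / bandwidth
    w = np.exp(-0.5 * z * z)
    s0 = w.sum(axis=1)
    s1 = w @ x0
    s2 = w @ (x0 * x0)
    sy = w @ x1
    sxy = w @ (x0 * x1)
    return w, s0, s1, s2, sy, sxy


def _solve(s0, s1, s2, sy, sxy):
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (s0 * sxy - s1 * sy) / det
        a = (sy - b * s1) / s0
    return a, b, det


def tvar_fit(ts: TimeSeries, bandwidth: float) -> TVARFit:
    """Fit the TVAR(1) with a Gaussian kernel of the given bandwidth.

    For each observation time s the local regression
    ``X[t+1] ~ a_s + b_s X[t]`` is solved with weights
    ``K((u_s - u_t) / bandwidth)`` on time rescaled to [0, 1]; then
    ``phi_s = b_s`` and ``mu_s = a_s / (1 - b_s)`` (the stationary-mean
    reparameterization).  Where ``|1 - b_s|`` is numerically zero the mean
    is carried forward from the nearest solvable point.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(ts) < 10:
        raise ValueError("need at least 10 observations for a TVAR fit")
    ts.warn_if_irregular()
    t = ts.times
    u = (t - t[0]) / (t[-1] - t[0])
    x0, x1 = ts.values[:-1], ts.values[1:]
    u_pairs = u[:-1]
    w, s0, s1, s2, sy, sxy = _design_sums(u, u_pairs, x0, x1, bandwidth)
    # effective support: weights spread over < 3 pairs cannot identify (a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = (w.sum(axis=1) ** 2) / (w * w).sum(axis=1)
    a, b, det = _solve(s0, s1, s2, sy, sxy)
    bad = ~np.isfinite(b) | (np.abs(det) < 1e-12 * np.maximum(s0 * s2, 1e-300))
    if bad.all() or (n_eff < 3).all():
        raise ValueError(
            "weighted design is singular everywhere; increase the bandwidth"
        )
    if bad.any():
        good = np.flatnonzero(~bad)
        nearest = good[np.argmin(np.abs(np.arange(len(b))[:, None] - good[None, :]), axis=1)]
        b = np.where(bad, b[nearest], b)
        a = np.where(bad, a[nearest], a)
    phi_t = b
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_t = a / (1.0 - b)
    undef = np.abs(1.0 - b) <= 1e-8
    if undef.any():
        if undef.all():
            mu_t = np.full_like(b, np.mean(ts.values))
        else:
            ok = np.flatnonzero(~undef)
            nearest = ok[np.argmin(np.abs(np.arange(len(b))[:, None] - ok[None, :]), axis=1)]
            mu_t = np.where(undef, mu_t[nearest], mu_t)
    resid = x1 - (a[:-1] + b[:-1] * x0)
    sigma = float(np.std(resid, ddof=1))
    return TVARFit(times=t, mu_t=mu_t, phi_t=phi_t, bandwidth=float(bandwidth), sigma=sigma)


def loocv_bandwidth(
    ts: TimeSeries, grid: np.ndarray | None = None
) -> float:
    """Leave-one-out cross-validated bandwidth from a candidate grid.

    For each candidate the one-step-ahead prediction of ``X[s+1]`` at pair s
    is recomputed with that pair's own contribution removed from the moment
    sums; the candidate minimizing the summed squared errors wins, ties
    going to the larger (smoother) bandwidth.
    """
    grid = DEFAULT_BANDWIDTH_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("bandwidth grid values must lie in (0, 1]")
    if len(ts) < 20:
        raise ValueError("need at least 20 observations for LOOCV")
    t = ts.times
    u = (t - t[0]) / (t[-1] - t[0])
    x0, x1 = ts.values[:-1], ts.values[1:]
    u_pairs = u[:-1]
    best_bw, best_score = None, np.inf
    for bw in grid:
        w, s0, s1, s2, sy, sxy = _design_sums(u_pairs, u_pairs, x0, x1, bw)
        d = np.diag(w).copy()  # self-weight of each pair
        a, b, det = _solve(
            s0 - d, s1 - d * x0, s2 - d * x0 * x0, sy - d * x1, sxy - d * x0 * x1
        )
        pred = a + b * x0
        if not np.isfinite(pred).all():
            continue
        score = float(np.sum((x1 - pred) ** 2))
        if score < best_score - 1e-12 or (
            abs(score - best_score) <= 1e-12 and best_bw is not None and bw > best_bw
        ):
            best_score, best_bw = score, float(bw)
    if best_bw is None:
        raise ValueError("all candidate bandwidths gave singular designs")
    return best_bw


def tvar_indicator(bandwidth: float | str = "auto", grid=None):
    """Indicator closure for surrogate testing; re-selects the bandwidth by
    LOOCV on every series it is applied to when ``bandwidth="auto"``."""

    def indicator(ts: TimeSeries) -> np.ndarray:
        bw = loocv_bandwidth(ts, grid) if bandwidth == "auto" else float(bandwidth)
        return tvar_fit(ts, bw).phi_t

    return indicator


def tvar_trend_test(
    ts: TimeSeries,
    bandwidth: float | str = "auto",
    n_surrogates: int = 1000,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
    max_order: int = 5,
    arma_result=None,
    surrogates=None,
    null: str = "standard",
    null_taus=None,
) -> TrendTest:
    """Surrogate-data significance test of the TVAR(1) phi_t trend.

    The observed statistic is the Kendall tau of the TVAR phi_t trajectory
    (bandwidth chosen by LOOCV when "auto").  With ``null="standard"`` the
    null tau distribution is estimated on the ARMA surrogates with the
    standard sliding-AR(1) indicator — the sampling distribution of the
    trend statistic under stationary dynamics.  ``null="matched"`` instead
    re-runs the TVAR pipeline (bandwidth re-selected per surrogate when
    auto) on every surrogate; this variant is far more conservative because
    smooth TVAR trajectories saturate tau toward +-1 on the surrogates
    themselves.
    """
    if null not in ("standard", "matched"):
        raise ValueError("null must be 'standard' or 'matched'")
    from .ar1 import ar1_indicator

    null_indicator = ar1_indicator() if null == "standard" else None
    return surrogate_test(
        ts,
        tvar_indicator(bandwidth),
        n_surrogates=n_surrogates,
        alpha=alpha,
        rng=rng,
        max_order=max_order,
        arma_result=arma_result,
        surrogates=surrogates,
        null_indicator=null_indicator,
        null_taus=null_taus,
    )


def global_ar1_equivalent(ts: TimeSeries):
    """Global OLS AR(1) fit on the raw series (large-bandwidth limit)."""
    return fit_ar1_ols(ts.values)
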