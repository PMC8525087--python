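"""Univariate time-series container and the shared statistical primitives.

All early-warning-signal detectors in this package operate on a univariate,
(approximately) equidistant :class:`TimeSeries`.  This module provides the
container plus the operations every detector shares: Scott's-rule bandwidth
selection, Gaussian-kernel detrending, standardization, and the Kendall
rank-correlation trend statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeSeries",
    "DetrendResult",
    "TrendTest",
    "ZeroSpreadError",
    "scott_bandwidth",
    "gaussian_smooth",
    "standardize",
    "kendall_tau",
    "read_csv",
    "write_csv",
]

#: Relative deviation of sampling intervals above which a series is treated
#: as non-equidistant (models warn but proceed, using actual time distances).
EQUIDISTANCE_TOL = 0.05


class ZeroSpreadError(ValueError):
    """Raised when an operation requires non-constant data."""


@dataclass(frozen=True)
class TimeSeries:
    """Ordered (time, value) pairs.

    Parameters
    ----------
    times
        Strictly increasing observation times, arbitrary units.
    values
        Observed state variable, same length as ``times``.
    name
        Free-text label carried through the pipeline.
    """

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or x.ndim != 1 or len(t) != len(x):
            raise ValueError("times and values must be 1-D and equally long")
        if len(t) < 3:
            raise ValueError("a TimeSeries needs at least 3 observations")
        if not (np.isfinite(t).all() and np.isfinite(x).all()):
            raise ValueError("times and values must be finite (no NaN/inf)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", x)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt_median(self) -> float:
        """Median sampling interval."""
        return float(np.median(np.diff(self.times)))

    @property
    def equidistance_deviation(self) -> float:
        """max|dt - median dt| / median dt; > 0.05 means irregular sampling."""
        dt = np.diff(self.times)
        med = np.median(dt)
        return float(np.max(np.abs(dt - med)) / med)

    @property
    def is_equidistant(self) -> bool:
        return self.equidistance_deviation <= EQUIDISTANCE_TOL

    def warn_if_irregular(self) -> None:
        if not self.is_equidistant:
            warnings.warn(
                f"series {self.name!r}: sampling intervals deviate by "
                f"{self.equidistance_deviation:.1%} from the median; "
                "kernel weights use actual time distances",
                UserWarning,
                stacklevel=3,
            )

    def slice(self, start: int, stop: int) -> "TimeSeries":
        return TimeSeries(self.times[start:stop], self.values[start:stop], self.name)


@dataclass(frozen=True)
class DetrendResult:
    """Smoothed trend and the residuals the AR(1) indicator is fitted to."""

    trend: np.ndarray
    residuals: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class TrendTest:
    """Outcome of a trend-significance test for an indicator trajectory.

    ``method`` is ``"surrogate"`` for the frequentist detectors (null
    distribution of tau from resimulated ARMA surrogates) or ``"posterior"``
    for the Bayesian detector (posterior distribution of tau).  A warning
    signal is declared only for a positive trend: ``significant`` is true iff
    ``tau > 0`` and ``p_value <= alpha``.
    """

    tau: float
    p_value: float
    alpha: float
    method: str
    null_or_posterior_taus: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method not in ("surrogate", "posterior"):
            raise ValueError("method must be 'surrogate' or 'posterior'")

    @property
    def significant(self) -> bool:
        return bool(self.tau > 0 and self.p_value <= self.alpha)


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's-rule plug-in bandwidth, in sample-index units.

    bw = 1.06 * min(sd, IQR / 1.34) * n**(-1/5),

    with the sample standard deviation (ddof=1) and linear-interpolation
    ("type-7") quantiles for the IQR.  Callers convert to time units by
    multiplying with the median sampling interval.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.quantile(x, [0.75, 0.25])  # type-7 linear interpolation
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ZeroSpreadError("constant series has no spread to set a bandwidth")
    return 1.06 * spread * len(x) ** (-1 / 5)


def gaussian_smooth(
    ts: TimeSeries,
    bandwidth: float,
    *,
    ksmooth_compat: bool = False,
) -> DetrendResult:
    """Gaussian-kernel (Nadaraya-Watson) smoother used for detrending.

    ``bandwidth`` is the standard deviation of the Gaussian kernel in time
    units.  Weights are renormalized at the boundaries (no padding).  With
    ``ksmooth_compat`` the bandwidth is rescaled by 0.3706 to reproduce the
    R ``stats::ksmooth`` convention, which places the kernel quartiles at
    +/- 0.25 * bandwidth.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    h = bandwidth * 0.3706506 if ksmooth_compat else bandwidth
    t = ts.times
    # n x n kernel matrix; series are short (<= a few hundred) so dense is fine
    u = (t[:, None] - t[None, :]) / h
    w = np.exp(-0.5 * u * u)
    trend = (w @ ts.values) / w.sum(axis=1)
    return DetrendResult(trend=trend, residuals=ts.values - trend, bandwidth=h)


def standardize(ts: TimeSeries) -> tuple[TimeSeries, float, float]:
    """Center and scale to sample mean 0, sample sd 1 (ddof=1).

    Returns the standardized series plus the (mean, sd) needed to map
    results back to the original units.
    """
    mean = float(np.mean(ts.values))
    sd = float(np.std(ts.values, ddof=1))
    if sd <= 0:
        raise ZeroSpreadError("cannot standardize a constant series")
    return TimeSeries(ts.times, (ts.values - mean) / sd, ts.name), mean, sd


def kendall_tau(x: np.ndarray) -> float:
    """Kendall rank correlation of a trajectory against its time index.

    Uses the tau-b (tie-corrected) convention, which coincides with the
    plain concordant-minus-discordant ratio when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values for Kendall tau")
    if np.all(x == x[0]):
        return 0.0
    tau = stats.kendalltau(np.arange(len(x)), x).statistic
    return float(tau)


def read_csv(path) -> TimeSeries:
    """Read a two-column ``time,value`` CSV (header required, '.' decimal)."""
    df = pd.read_csv(path, encoding="utf-8")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns 'time,value'")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(x).any():
        raise ValueError(f"{path}: NaN entries are not allowed")
    if len(np.unique(t)) != len(t):
        raise ValueError(f"{path}: duplicated time points")
    order = np.argsort(t)
    return TimeSeries(t[order], x[order], name=str(path))


def write_csv(ts: TimeSeries, path) -> None:
    pd.DataFrame({"time": ts.times, "value": ts.values}).to_csv(path, index=False)
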