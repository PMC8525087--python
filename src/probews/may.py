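"""May (1977) harvesting model: the benchmark generator for regime shifts.

The stochastic differential equation

    dX = [ r X (1 - X/K) - c X^2 / (X^2 + h^2) ] dt + sigma X dW_t

combines logistic growth (rate r, carrying capacity K) with a saturating
harvest term (rate c, half-saturation h) and multiplicative environmental
noise.  For a window of harvest rates (c1, c2) the deterministic skeleton
is bistable; pushing c slowly through the upper fold forces a catastrophic
collapse to the low-biomass branch, which is the regime shift the
early-warning detectors try to anticipate from the pre-shift segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gp import se_cov, gp_draw
from .timeseries import TimeSeries

__all__ = [
    "SimParams",
    "SimReplicate",
    "critical_points",
    "equilibria",
    "sample_sim_params",
    "sample_harvest_trajectory",
    "euler_maruyama",
    "detect_shift",
    "add_observation_error",
    "generate_benchmark_suite",
]

DT = 0.01  # Euler-Maruyama step, 100 substeps per unit-time observation
PARAM_FLOOR = 1e-3
MIN_PRESHIFT = 15


@dataclass(frozen=True)
class SimParams:
    """One replicate's model parameters and harvest trajectory."""

    T: int
    r: float
    K: float
    h: float
    sigma: float
    c_traj: np.ndarray
    regime: str  # "shifting" | "stationary"
    obs_error_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("shifting", "stationary"):
            raise ValueError("regime must be 'shifting' or 'stationary'")
        if min(self.r, self.K, self.h, self.sigma) <= 0:
            raise ValueError("rate parameters must be positive")
        c = np.asarray(self.c_traj, dtype=float)
        if len(c) != self.T:
            raise ValueError("c_traj must have one value per observation time")
        object.__setattr__(self, "c_traj", c)


@dataclass(frozen=True)
class SimReplicate:
    """A simulated path plus the ground truth the benchmark scores against."""

    params: SimParams
    series: TimeSeries
    truncated: TimeSeries
    label: bool  # True = a state shift occurred
    shift_index: int | None = None  # 1-based observation index of the shift
    noisy_series: TimeSeries | None = None


def _turning_points(r: float, K: float, h: float) -> np.ndarray:
    """Positive roots of d c(X)/dX = 0 on the nontrivial equilibrium branch.

    c(X) = r (1 - X/K)(X^2 + h^2) / X, so dc/dX = 0 reduces to the cubic
    2 X^3 - K X^2 + K h^2 = 0.
    """
    roots = np.roots([2.0, -K, 0.0, K * h * h])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real[real > 0])


def _c_of_x(x: np.ndarray, r: float, K: float, h: float) -> np.ndarray:
    return r * (1.0 - x / K) * (x * x + h * h) / x


def critical_points(r: float, K: float, h: float) -> tuple[float, float] | None:
    """Fold-bifurcation harvest rates (c1, c2) of the deterministic skeleton.

    Returns ``None`` when no bistable window exists (e.g. K close to h, where
    logistic growth dominates and the equilibrium branch is monotone).
    With r=1, K=10, h=1 the window is approximately (1.791, 2.604).
    """
    if min(r, K, h) <= 0:
        raise ValueError("r, K, h must be positive")
    xs = _turning_points(r, K, h)
    if len(xs) < 2:
        return None
    cs = _c_of_x(xs, r, K, h)
    c1, c2 = float(np.min(cs)), float(np.max(cs))
    if not np.isfinite(c1) or c1 <= 0 or np.isclose(c1, c2):
        return None
    return c1, c2


def equilibria(c: float, r: float, K: float, h: float) -> np.ndarray:
    """Positive equilibria of the skeleton at harvest rate c, ascending.

    Nontrivial equilibria solve X^3 - K X^2 + (h^2 + c K / r) X - K h^2 = 0.
    One root = single stable state; three = lower stable / unstable / upper
    stable.
    """
    roots = np.roots([1.0, -K, h * h + c * K / r, -K * h * h])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real[real > 1e-12])


def sample_harvest_trajectory(
    rng: np.random.Generator, T: int, regime: str
) -> np.ndarray:
    """Draw a harvest-rate trajectory c(t), t = 1..T, from its GP.

    Shifting regime: squared-exponential GP fluctuations (amplitude
    alpha_c ~ Unif(0.05, 0.25), length scale rho_c ~ Unif(10, 50)) around a
    mean ramp rising linearly from 1 to 3.5 across the simulation — well
    past the upper fold.  Stationary regime: same GP around a constant
    mean of 1.
    """
    if T < 2:
        raise ValueError("need T >= 2")
    alpha_c = rng.uniform(0.05, 0.25)
    rho_c = rng.uniform(10.0, 50.0)
    t = np.arange(1, T + 1, dtype=float)
    if regime == "shifting":
        delta = 1.0 + (3.5 - 1.0) * (t - 1.0) / (T - 1.0)
    elif regime == "stationary":
        delta = np.ones(T)
    else:
        raise ValueError("regime must be 'shifting' or 'stationary'")
    return gp_draw(delta, se_cov(t, alpha_c, rho_c), rng)


def sample_sim_params(rng: np.random.Generator, regime: str) -> SimParams:
    """Draw one replicate's parameters from the benchmark distributions.

    T ~ Unif(50, 200), r ~ N(1, 0.1), K ~ N(10, 1), h ~ N(1, 0.1),
    sigma ~ N(0.1, 0.01); Gaussian draws are floored at 1e-3 to preserve
    positivity.
    """
    T = int(rng.integers(50, 201))
    r = max(rng.normal(1.0, 0.1), PARAM_FLOOR)
    K = max(rng.normal(10.0, 1.0), PARAM_FLOOR)
    h = max(rng.normal(1.0, 0.1), PARAM_FLOOR)
    sigma = max(rng.normal(0.1, 0.01), PARAM_FLOOR)
    c_traj = sample_harvest_trajectory(rng, T, regime)
    return SimParams(T=T, r=r, K=K, h=h, sigma=sigma, c_traj=c_traj, regime=regime)


def euler_maruyama(
    params: SimParams,
    rng: np.random.Generator,
    dt: float = DT,
    x0: float | None = None,
) -> TimeSeries:
    """Integrate the SDE and record the state at integer times t = 1..T.

    The harvest rate is linearly interpolated between its observation-time
    values on the fine grid; the state is clamped at 1e-8 from below (the
    clamp is a numerical guard and essentially never activates for the
    benchmark parameter ranges).  X(0) ~ N(K, sigma) unless ``x0`` given.
    """
    p = params
    n_sub = int(round(1.0 / dt))
    fine_t = np.arange(0, p.T * n_sub + 1) * dt
    c_fine = np.interp(fine_t, np.arange(1, p.T + 1, dtype=float), p.c_traj)
    x = float(rng.normal(p.K, p.sigma)) if x0 is None else float(x0)
    x = max(x, 1e-8)
    out = np.empty(p.T)
    sqrt_dt = np.sqrt(dt)
    z = rng.standard_normal(len(fine_t) - 1) if p.sigma > 0 else None
    for i in range(len(fine_t) - 1):
        c = c_fine[i]
        drift = p.r * x * (1.0 - x / p.K) - c * x * x / (x * x + p.h * p.h)
        x = x + drift * dt
        if z is not None:
            x += p.sigma * x * sqrt_dt * z[i]
        if not np.isfinite(x):
            raise FloatingPointError(f"non-finite state at step {i} (t={fine_t[i+1]:.2f})")
        if x < 1e-8:
            x = 1e-8
        step = i + 1
        if step % n_sub == 0:
            out[step // n_sub - 1] = x
    return TimeSeries(np.arange(1, p.T + 1, dtype=float), out, name=f"may-{p.regime}")


def _shift_thresholds(params: SimParams) -> np.ndarray:
    """Per-observation collapse threshold: the unstable branch inside the
    bistable window, K/2 past the upper fold, NaN (no threshold) below it."""
    cp = critical_points(params.r, params.K, params.h)
    thr = np.full(params.T, np.nan)
    for i, c in enumerate(params.c_traj):
        if cp is not None and c >= cp[1]:
            thr[i] = params.K / 2.0
        elif cp is not None and c > cp[0]:
            eq = equilibria(c, params.r, params.K, params.h)
            if len(eq) == 3:
                thr[i] = eq[1]
            elif c > 0.5 * (cp[0] + cp[1]):
                thr[i] = params.K / 2.0
    return thr


def detect_shift(series: TimeSeries, params: SimParams, persistence: int = 3) -> int | None:
    """Automated change-point proxy: first 1-based observation index where
    the state falls below the unstable equilibrium branch (or K/2 once the
    harvest rate has passed the upper fold) and stays below for at least
    ``persistence`` consecutive observations."""
    thr = _shift_thresholds(params)
    below = series.values < thr  # NaN threshold compares False
    run = 0
    for i in range(len(below) - 1, -1, -1):
        run = run + 1 if below[i] else 0
        below[i] = run >= persistence
    idx = np.flatnonzero(below)
    return int(idx[0]) + 1 if len(idx) else None


def add_observation_error(
    series: TimeSeries, sd: float, rng: np.random.Generator
) -> TimeSeries:
    """Add i.i.d. N(0, sd^2) measurement noise; sd = 0 returns the input."""
    if sd < 0:
        raise ValueError("observation-error sd must be >= 0")
    if sd == 0:
        return series
    return TimeSeries(
        series.times, series.values + sd * rng.standard_normal(len(series)), series.name
    )


def _make_replicate(params: SimParams, rng: np.random.Generator) -> SimReplicate:
    series = euler_maruyama(params, rng)
    shift = detect_shift(series, params)
    if params.regime == "shifting":
        label = shift is not None
        truncated = series.slice(0, shift - 1) if (shift and shift > 3) else series
    else:
        label = False
        truncated = series
        shift = None
    return SimReplicate(
        params=params, series=series, truncated=truncated, label=label, shift_index=shift
    )


def generate_benchmark_suite(
    n_reps: int, seed: int = 0, max_reject_frac: float = 0.5
) -> list[SimReplicate]:
    """Generate the paired benchmark collection: ``n_reps`` shifting
    replicates followed by ``n_reps`` stationary ones.

    Shifting replicates must actually shift and keep at least 15 pre-shift
    observations; failures are rejected and redrawn.  Each stationary
    replicate reuses the matched shifting replicate's parameters with its
    length set to that replicate's pre-shift length, so the two groups are
    length-matched pairwise.  Deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shifting: list[SimReplicate] = []
    n_rejected = 0
    while len(shifting) < n_reps:
        rep = _make_replicate(sample_sim_params(rng, "shifting"), rng)
        ok = (
            rep.label
            and rep.shift_index is not None
            and len(rep.truncated) >= MIN_PRESHIFT
        )
        if ok:
            shifting.append(rep)
        else:
            n_rejected += 1
            if n_rejected > max_reject_frac * (n_rejected + len(shifting)) and (
                n_rejected + len(shifting)
            ) >= 20:
                raise RuntimeError(
                    f"rejected {n_rejected} of {n_rejected + len(shifting)} shifting "
                    "replicates; parameter configuration looks wrong"
                )
    stationary = []
    for rep in shifting:
        T = len(rep.truncated)
        params = sample_sim_params(rng, "stationary")
        params = replace(
            params, T=T, c_traj=sample_harvest_trajectory(rng, T, "stationary")
        )
        stationary.append(_make_replicate(params, rng))
    return shifting + stationary
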