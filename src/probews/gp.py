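"""Gaussian-process covariance functions used by the priors and the simulator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GPConfig", "matern32_cov", "se_cov", "gp_draw"]

JITTER = 1e-6


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameters of a GP prior on a latent trajectory.

    ``amplitude`` is alpha (so alpha^2 is the process variance),
    ``length_scale`` is rho in time-index units, and ``nu`` selects the
    Matern smoothness (3/2 gives once-differentiable trajectories, 5/2
    twice-differentiable).
    """

    mean: float = 0.0
    amplitude: float = 1.0
    length_scale: float = 1.0
    nu: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.length_scale <= 0:
            raise ValueError("amplitude and length_scale must be positive")
        if self.nu not in (1.5, 2.5):
            raise ValueError("nu must be 3/2 or 5/2")


def matern32_cov(times: np.ndarray, cfg: GPConfig) -> np.ndarray:
    """Matern covariance matrix on a set of (increasing) input locations.

    For nu = 3/2: k(r) = alpha^2 (1 + sqrt(3) r / rho) exp(-sqrt(3) r / rho);
    for nu = 5/2 the corresponding twice-differentiable form.  A diagonal
    jitter of 1e-6 * alpha^2 keeps the Cholesky factorization stable.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-D vector")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    r = np.abs(t[:, None] - t[None, :]) / cfg.length_scale
    a2 = cfg.amplitude**2
    if cfg.nu == 1.5:
        s = np.sqrt(3.0) * r
        k = a2 * (1.0 + s) * np.exp(-s)
    else:
        s = np.sqrt(5.0) * r
        k = a2 * (1.0 + s + s * s / 3.0) * np.exp(-s)
    k[np.diag_indices_from(k)] += JITTER * a2
    return k


def se_cov(times: np.ndarray, amplitude: float, length_scale: float) -> np.ndarray:
    """Squared-exponential covariance alpha^2 exp(-r^2 / (2 rho^2)) with 1e-9 jitter."""
    t = np.asarray(times, dtype=float)
    r = t[:, None] - t[None, :]
    k = amplitude**2 * np.exp(-0.5 * (r / length_scale) ** 2)
    k[np.diag_indices_from(k)] += 1e-9
    return k


def gp_draw(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One multivariate-normal draw via Cholesky (deterministic under rng)."""
    chol = np.linalg.cholesky(cov)
    return np.asarray(mean, dtype=float) + chol @ rng.standard_normal(len(cov))
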