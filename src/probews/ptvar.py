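"""Probabilistic time-varying AR(1) — pTVAR(1).

The generative model, on the standardized series x (mean 0, sd 1):

    phi_t ~ GP(M_phi, Matern-3/2(rho_phi, alpha_phi))
    mu_t  ~ GP(M_mu,  Matern-3/2(rho_mu,  alpha_mu))
    sigma ~ half-Normal(0, s^2)
    x[t+1] = mu_t + phi_t * (x[t] - mu_t) + eps_t,   eps_t ~ N(0, sigma^2)

Standardization lets the hyperparameters default to M = 0, alpha = 1 for
both trajectories, with the length scales set to the series length — a
deliberately smooth prior that highlights the long-term trends relevant
for early warnings.  phi_t is left unconstrained: excursions toward (and
past) 1 are exactly the signal of interest near a transition.

The posterior is sampled by Hamiltonian Monte Carlo in a whitened
(non-centered) parameterization: standard-normal innovation vectors are
mapped through the Cholesky factors of the prior covariances.  Every
posterior draw of phi_t yields a Kendall tau against time, so trend
significance is read directly off the tau posterior — no surrogate data
are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gp import GPConfig, matern32_cov
from .hmc import hmc_sample
from .timeseries import TimeSeries, TrendTest, kendall_tau, standardize

__all__ = [
    "GPConfig",
    "PTVARConfig",
    "PosteriorSamples",
    "loglik_tvar",
    "fit_ptvar",
    "posterior_trend_test",
    "ptvar_trend_test",
]

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class PTVARConfig:
    """Sampler and prior configuration for :func:`fit_ptvar`.

    ``gp_phi`` / ``gp_mu`` default to mean 0, amplitude 1, and length scale
    equal to the series length (filled in at fit time when ``None``).
    """

    gp_phi: GPConfig | None = None
    gp_mu: GPConfig | None = None
    sigma_prior_scale: float = 1.0
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    n_leapfrog: int = 24

    def resolved(self, n: int) -> "PTVARConfig":
        """Fill in the data-dependent length-scale defaults for series length n."""
        gp_phi = self.gp_phi if self.gp_phi is not None else GPConfig(0.0, 1.0, float(n))
        gp_mu = self.gp_mu if self.gp_mu is not None else GPConfig(0.0, 1.0, float(n))
        return replace(self, gp_phi=gp_phi, gp_mu=gp_mu)


@dataclass
class PosteriorSamples:
    """Posterior draws of the pTVAR(1) parameters.

    ``phi_t_draws`` and ``mu_t_draws`` have one row per draw and one column
    per transition time t = 1..n-1 (the likelihood constrains only those);
    ``mu_t_draws`` is back-transformed to the original data units while
    ``sigma_draws`` stays on the standardized scale (multiply by
    ``data_sd`` for original units).  ``tau_draws[k]`` is the Kendall tau
    of ``phi_t_draws[k]`` against time.
    """

    times: np.ndarray
    phi_t_draws: np.ndarray
    mu_t_draws: np.ndarray
    sigma_draws: np.ndarray
    tau_draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    data_mean: float = 0.0
    data_sd: float = 1.0

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("ok", False))


def loglik_tvar(
    x_std: np.ndarray, mu_t: np.ndarray, phi_t: np.ndarray, sigma: float
) -> float:
    """Log-likelihood of a TVAR(1) parameterization given standardized data.

    Sum over t of log N(x[t+1] | mu_t + phi_t (x[t] - mu_t), sigma^2),
    with mu_t, phi_t indexed by the n-1 transitions.
    """
    x = np.asarray(x_std, dtype=float)
    mu = np.asarray(mu_t, dtype=float)
    phi = np.asarray(phi_t, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = len(x) - 1
    if len(mu) != m or len(phi) != m:
        raise ValueError("mu_t and phi_t must have length len(x) - 1")
    r = x[1:] - (mu + phi * (x[:-1] - mu))
    return float(
        -m * (0.5 * np.log(2.0 * np.pi) + np.log(sigma)) - np.sum(r * r) / (2.0 * sigma**2)
    )


def _make_logp(x_std, chol_phi, chol_mu, m_phi, m_mu, sigma_scale, likelihood_weight):
    """Log-joint and gradient in the whitened parameterization.

    theta = [z_phi (m), z_mu (m), eta = log sigma]; phi = M + L z, etc.
    """
    x0 = x_std[:-1]
    x1 = x_std[1:]
    m = len(x0)
    lt_phi = chol_phi.T
    lt_mu = chol_mu.T

    def logp_and_grad(theta):
        z_phi = theta[:m]
        z_mu = theta[m : 2 * m]
        eta = theta[-1]
        if not np.isfinite(eta) or abs(eta) > 40.0:
            # leapfrog excursion far outside the posterior's support
            return -np.inf, np.zeros_like(theta)
        sigma = np.exp(eta)
        phi = m_phi + chol_phi @ z_phi
        mu = m_mu + chol_mu @ z_mu
        d = x0 - mu
        r = x1 - (mu + phi * d)
        inv_s2 = np.exp(-2.0 * eta)
        ll = -m * eta - 0.5 * inv_s2 * np.dot(r, r)
        # priors: z ~ N(0, I); sigma ~ half-N(0, s^2) with log-Jacobian eta
        lp = (
            likelihood_weight * ll
            - 0.5 * np.dot(z_phi, z_phi)
            - 0.5 * np.dot(z_mu, z_mu)
            - 0.5 * (sigma / sigma_scale) ** 2
            + eta
        )
        g_pred = likelihood_weight * inv_s2 * r
        grad = np.empty_like(theta)
        grad[:m] = lt_phi @ (g_pred * d) - z_phi
        grad[m : 2 * m] = lt_mu @ (g_pred * (1.0 - phi)) - z_mu
        grad[-1] = (
            likelihood_weight * (-m + inv_s2 * np.dot(r, r))
            - (sigma / sigma_scale) ** 2
            + 1.0
        )
        return lp, grad

    return logp_and_grad


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split-R̂ (rank-normalization omitted) for an array of shape (chain, draw)."""
    c, d = chains_draws.shape
    half = d // 2
    if half < 2:
        return np.nan
    seq = chains_draws[:, : 2 * half].reshape(2 * c, half)
    means = seq.mean(axis=1)
    variances = seq.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return np.nan
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def fit_ptvar(
    ts: TimeSeries,
    cfg: PTVARConfig | None = None,
    *,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Sample the pTVAR(1) posterior for a time series.

    The series is standardized internally; ``mu_t`` draws are mapped back
    to the original units.  Sampling is deterministic under ``cfg.seed``.
    With ``prior_only`` the likelihood is switched off, which turns the
    sampler into a prior-predictive check of the GP machinery.

    Convergence problems (split-R̂ above 1.01 or divergent transitions) are
    reported in ``diagnostics`` and via a warning — never silently.
    """
    cfg = (cfg or PTVARConfig()).resolved(len(ts))
    if len(ts) < 10:
        raise ValueError("need at least 10 observations to fit pTVAR(1)")
    ts.warn_if_irregular()
    std, mean, sd = standardize(ts)
    # GP inputs on the index scale (length scales are quoted in index units)
    g = (ts.times - ts.times[0]) / ts.dt_median
    g_param = g[:-1]
    m = len(ts) - 1
    chol_phi = np.linalg.cholesky(matern32_cov(g_param, cfg.gp_phi))
    chol_mu = np.linalg.cholesky(matern32_cov(g_param, cfg.gp_mu))
    logp = _make_logp(
        std.values,
        chol_phi,
        chol_mu,
        cfg.gp_phi.mean,
        cfg.gp_mu.mean,
        cfg.sigma_prior_scale,
        0.0 if prior_only else 1.0,
    )

    seed_seq = np.random.SeedSequence(cfg.seed)
    chain_draws = []
    accept_rates = []
    divergences = 0
    step_sizes = []
    for child in seed_seq.spawn(cfg.chains):
        rng = np.random.default_rng(child)
        x0 = np.concatenate([0.1 * rng.standard_normal(2 * m), [np.log(0.5)]])
        res = hmc_sample(
            logp,
            x0,
            n_warmup=cfg.warmup,
            n_draws=cfg.draws,
            rng=rng,
            target_accept=cfg.target_accept,
            n_leapfrog=cfg.n_leapfrog,
        )
        chain_draws.append(res.draws)
        accept_rates.append(res.accept_rate)
        divergences += res.divergences
        step_sizes.append(res.step_size)

    theta = np.vstack(chain_draws)
    z_phi = theta[:, :m]
    z_mu = theta[:, m : 2 * m]
    sigma = np.exp(theta[:, -1])
    phi_draws = cfg.gp_phi.mean + z_phi @ chol_phi.T
    mu_std = cfg.gp_mu.mean + z_mu @ chol_mu.T
    mu_draws = mean + sd * mu_std
    tau_draws = np.array([kendall_tau(row) for row in phi_draws])

    # split-R̂ on scalar summaries that exercise every parameter block
    per_chain = lambda v: v.reshape(cfg.chains, cfg.draws)
    rhats = {
        "sigma": _split_rhat(per_chain(sigma)),
        "tau": _split_rhat(per_chain(tau_draws)),
        "phi_first": _split_rhat(per_chain(phi_draws[:, 0])),
        "phi_mid": _split_rhat(per_chain(phi_draws[:, m // 2])),
        "phi_last": _split_rhat(per_chain(phi_draws[:, -1])),
    }
    max_rhat = float(np.nanmax(list(rhats.values())))
    ok = bool(max_rhat <= RHAT_LIMIT and divergences == 0)
    diagnostics = {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "divergences": int(divergences),
        "accept_rate": float(np.mean(accept_rates)),
        "step_size": float(np.mean(step_sizes)),
        "ok": ok,
    }
    if not ok:
        import warnings

        warnings.warn(
            f"pTVAR sampler diagnostics flagged: max split-R-hat {max_rhat:.3f}, "
            f"{divergences} divergent transitions",
            UserWarning,
            stacklevel=2,
        )
    return PosteriorSamples(
        times=ts.times[:-1],
        phi_t_draws=phi_draws,
        mu_t_draws=mu_draws,
        sigma_draws=sigma,
        tau_draws=tau_draws,
        diagnostics=diagnostics,
        data_mean=mean,
        data_sd=sd,
    )


def posterior_trend_test(post: PosteriorSamples, alpha: float = 0.1) -> TrendTest:
    """Trend test from the tau posterior.

    The probabilistic p-value is the plain fraction of the tau posterior
    that is not positive; a warning signal requires 100(1 - alpha)% of the
    posterior mass above zero.
    """
    taus = post.tau_draws
    if len(taus) < 500:
        raise ValueError("need at least 500 posterior tau draws")
    p = float(np.mean(taus <= 0.0))
    return TrendTest(
        tau=float(np.mean(taus)),
        p_value=p,
        alpha=alpha,
        method="posterior",
        null_or_posterior_taus=taus,
    )


def ptvar_trend_test(
    ts: TimeSeries, cfg: PTVARConfig | None = None, alpha: float = 0.1
) -> TrendTest:
    """Convenience wrapper: fit pTVAR(1) and test the phi_t trend."""
    return posterior_trend_test(fit_ptvar(ts, cfg), alpha=alpha)
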