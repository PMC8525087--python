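import numpy as np
import pytest

from probews import (
    GPConfig,
    PTVARConfig,
    TimeSeries,
    fit_ptvar,
    kendall_tau,
    loglik_tvar,
    matern32_cov,
    posterior_trend_test,
)
from probews.ptvar import PosteriorSamples

from conftest import make_ar1_series

FAST = PTVARConfig(chains=2, warmup=400, draws=400, seed=0)


class TestMaternCov:
    def test_zero_distance_is_variance_plus_jitter(self):
        k = matern32_cov(np.array([0.0, 2.0]), GPConfig(0, 2.0, 1.0))
        assert k[0, 0] == pytest.approx(4.0 * (1 + 1e-6))

    def test_hand_value_at_unit_distance(self):
        k = matern32_cov(np.array([0.0, 1.0]), GPConfig(0, 1.0, 1.0))
        s = np.sqrt(3.0)
        assert k[0, 1] == pytest.approx((1 + s) * np.exp(-s), abs=1e-12)

    def test_positive_semidefinite_large_grid(self):
        for rho in (1.0, 25.0, 500.0):
            k = matern32_cov(np.arange(500.0), GPConfig(0, 1.0, rho))
            assert np.linalg.eigvalsh(k).min() >= -1e-9

    def test_matern52_and_validation(self):
        k = matern32_cov(np.array([0.0, 1.0]), GPConfig(0, 1.0, 1.0, nu=2.5))
        s = np.sqrt(5.0)
        assert k[0, 1] == pytest.approx((1 + s + s * s / 3) * np.exp(-s))
        with pytest.raises(ValueError):
            GPConfig(0, 1.0, 1.0, nu=0.5)
        with pytest.raises(ValueError):
            matern32_cov(np.array([1.0, 0.5]), GPConfig())


class TestLoglik:
    def test_single_transition_standard_normal(self):
        ll = loglik_tvar(np.zeros(2), np.zeros(1), np.zeros(1), 1.0)
        assert ll == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)))

    def test_perfect_prediction_is_maximal(self):
        rng = np.random.default_rng(40)
        x = rng.standard_normal(20)
        phi = np.full(19, 0.5)
        mu_star = (x[1:] - phi * x[:-1]) / (1 - phi)  # exact-prediction means
        best = loglik_tvar(x, mu_star, phi, 0.7)
        for _ in range(20):
            worse = loglik_tvar(x, mu_star + 0.1 * rng.standard_normal(19), phi, 0.7)
            assert worse <= best

    def test_doubling_sigma_with_zero_residuals(self):
        x = np.zeros(10)
        base = loglik_tvar(x, np.zeros(9), np.zeros(9), 0.5)
        assert loglik_tvar(x, np.zeros(9), np.zeros(9), 1.0) == pytest.approx(
            base - 9 * np.log(2.0)
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            loglik_tvar(np.zeros(5), np.zeros(4), np.zeros(4), 0.0)


class TestPriorPredictive:
    def test_sampled_prior_matches_gp_moments(self):
        # likelihood off: the HMC chain must reproduce the Matern GP prior
        ts = TimeSeries(np.arange(1.0, 41), np.random.default_rng(0).standard_normal(40))
        post = fit_ptvar(ts, PTVARConfig(chains=2, warmup=400, draws=400, seed=3),
                         prior_only=True)
        ph = post.phi_t_draws
        assert abs(ph.std(axis=0).mean() - 1.0) < 0.15  # marginal sd ~ alpha
        s = np.sqrt(3.0) * 38 / 40
        theory = (1 + s) * np.exp(-s)
        emp = np.corrcoef(ph[:, 0], ph[:, -1])[0, 1]
        assert emp == pytest.approx(theory, abs=0.15)


class TestFitPtvar:
    def test_deterministic_under_seed(self):
        s = make_ar1_series(40, 0.5, seed=41)
        a = fit_ptvar(s, FAST)
        b = fit_ptvar(s, FAST)
        assert np.array_equal(a.phi_t_draws, b.phi_t_draws)
        assert np.array_equal(a.sigma_draws, b.sigma_draws)

    def test_tau_identity_per_draw(self):
        s = make_ar1_series(40, 0.5, seed=42)
        post = fit_ptvar(s, FAST)
        for k in range(0, len(post.tau_draws), 100):
            assert post.tau_draws[k] == kendall_tau(post.phi_t_draws[k])

    def test_white_noise_phi_near_zero(self):
        # no-signal case: the phi posterior mean stays small at every time
        worst = []
        for seed in range(5):
            s = TimeSeries(
                np.arange(1.0, 101),
                np.random.default_rng(700 + seed).standard_normal(100),
            )
            cfg = PTVARConfig(chains=2, warmup=400, draws=400, seed=seed)
            m = fit_ptvar(s, cfg).phi_t_draws.mean(axis=0)
            worst.append(np.max(np.abs(m)))
            assert np.mean(np.abs(m)) < 0.25
        assert max(worst) < 0.5

    def test_sigma_recovery(self):
        s = make_ar1_series(120, np.linspace(0.3, 0.7, 119), sigma=0.5, seed=600)
        post = fit_ptvar(s, PTVARConfig(chains=2, warmup=500, draws=500, seed=0))
        assert np.median(post.sigma_draws) * post.data_sd == pytest.approx(0.5, rel=0.3)

    def test_constant_shift_equivariance(self):
        # standardization makes the posterior shift-equivariant; comparison
        # is statistical because MCMC trajectories are chaotic in the last
        # floating-point digits of the standardized data
        s = make_ar1_series(60, 0.5, seed=43)
        shifted = TimeSeries(s.times, s.values + 100.0)
        a, b = fit_ptvar(s, FAST), fit_ptvar(shifted, FAST)
        assert b.data_mean == pytest.approx(a.data_mean + 100.0)
        assert b.data_sd == pytest.approx(a.data_sd)
        assert np.allclose(
            a.phi_t_draws.mean(axis=0), b.phi_t_draws.mean(axis=0), atol=0.1
        )
        assert np.allclose(
            a.mu_t_draws.mean(axis=0) + 100.0, b.mu_t_draws.mean(axis=0), atol=0.1
        )

    def test_length_scale_robustness_of_trend_fit(self, bench_suite):
        # the trend fit stays accurate across a 4x range of mu length scales
        from dataclasses import replace as dc_replace

        from probews.may import euler_maruyama

        rep = bench_suite[0]
        tr = rep.truncated
        det = euler_maruyama(
            dc_replace(rep.params, sigma=1e-12), np.random.default_rng(0),
            x0=rep.params.K,
        )
        trend = det.values[: len(tr) - 1]
        n = len(tr)
        mses = []
        for frac in (0.25, 0.5, 1.0):
            cfg = PTVARConfig(
                gp_mu=GPConfig(0, 1.0, frac * n), gp_phi=GPConfig(0, 1.0, float(n)),
                chains=2, warmup=500, draws=500, seed=9,
            )
            mu = fit_ptvar(tr, cfg).mu_t_draws.mean(axis=0)
            mses.append(np.mean((mu - trend) ** 2))
        assert max(mses) / min(mses) < 2.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            fit_ptvar(make_ar1_series(8, 0.5), FAST)


def _fake_posterior(taus):
    taus = np.asarray(taus, dtype=float)
    k = len(taus)
    return PosteriorSamples(
        times=np.arange(3.0),
        phi_t_draws=np.zeros((k, 3)),
        mu_t_draws=np.zeros((k, 3)),
        sigma_draws=np.ones(k),
        tau_draws=taus,
    )


class TestPosteriorTrendTest:
    def test_unanimously_positive_posterior(self):
        test = posterior_trend_test(_fake_posterior(np.linspace(0.1, 0.9, 1000)))
        assert test.p_value == 0.0
        assert test.significant

    def test_null_centred_posterior(self):
        rng = np.random.default_rng(44)
        taus = rng.uniform(-0.5, 0.5, 2000)
        test = posterior_trend_test(_fake_posterior(taus))
        assert test.p_value == pytest.approx(0.5, abs=0.05)
        assert not test.significant

    def test_small_negative_fraction(self):
        taus = np.concatenate([np.full(9995, 0.4), np.full(5, -0.1)])
        test = posterior_trend_test(_fake_posterior(taus))
        assert test.p_value == pytest.approx(0.0005)

    def test_needs_enough_draws(self):
        with pytest.raises(ValueError):
            posterior_trend_test(_fake_posterior(np.ones(100)))
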