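import numpy as np
import pytest

from probews import (
    SimParams,
    TimeSeries,
    add_observation_error,
    critical_points,
    detect_shift,
    equilibria,
    euler_maruyama,
    generate_benchmark_suite,
    sample_harvest_trajectory,
    sample_sim_params,
)


class TestCriticalPoints:
    def test_reference_parameterization(self):
        # turning points of c(X) solve 2X^3 - KX^2 + Kh^2 = 0, here
        # X^3 - 5X^2 + 5 = 0; the resulting fold values bracket bistability
        c1, c2 = critical_points(1.0, 10.0, 1.0)
        roots = np.roots([1.0, -5.0, 0.0, 5.0])
        xs = np.sort(roots[np.abs(roots.imag) < 1e-12].real)
        xs = xs[xs > 0]
        c_oracle = sorted((1 - x / 10) * (x * x + 1) / x for x in xs)
        assert c1 == pytest.approx(c_oracle[0], abs=1e-9)
        assert c2 == pytest.approx(c_oracle[1], abs=1e-9)
        assert c2 == pytest.approx(2.604, abs=1e-3)
        assert c1 == pytest.approx(1.791, rel=3e-3)  # published value is rounded

    def test_bistability_brackets_equilibrium_count(self):
        c1, c2 = critical_points(1.0, 10.0, 1.0)
        assert len(equilibria(0.5 * (c1 + c2), 1, 10, 1)) == 3
        assert len(equilibria(c1 - 0.05, 1, 10, 1)) == 1
        assert len(equilibria(c2 + 0.05, 1, 10, 1)) == 1

    def test_no_bistability_when_logistic_dominates(self):
        assert critical_points(1.0, 3.0, 1.0) is None

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            critical_points(0.0, 10.0, 1.0)


class TestParameterSampling:
    def test_distribution_means_and_bounds(self):
        rng = np.random.default_rng(50)
        draws = [sample_sim_params(rng, "shifting") for _ in range(3000)]
        assert np.mean([p.r for p in draws]) == pytest.approx(1.0, abs=0.01)
        assert np.mean([p.K for p in draws]) == pytest.approx(10.0, abs=0.1)
        assert np.mean([p.h for p in draws]) == pytest.approx(1.0, abs=0.01)
        assert np.mean([p.sigma for p in draws]) == pytest.approx(0.1, abs=0.002)
        assert all(min(p.r, p.K, p.h, p.sigma) > 0 for p in draws)
        assert all(50 <= p.T <= 200 for p in draws)


class TestHarvestTrajectory:
    def test_shifting_mean_ramp_endpoints(self):
        rng = np.random.default_rng(51)
        draws = np.array([sample_harvest_trajectory(rng, 100, "shifting") for _ in range(400)])
        assert draws[:, 0].mean() == pytest.approx(1.0, abs=0.05)
        assert draws[:, -1].mean() == pytest.approx(3.5, abs=0.05)

    def test_stationary_mean_constant(self):
        rng = np.random.default_rng(52)
        draws = np.array([sample_harvest_trajectory(rng, 80, "stationary") for _ in range(400)])
        assert np.allclose(draws.mean(axis=0), 1.0, atol=0.06)

    def test_paths_are_smooth(self):
        # SE-kernel increment sd is alpha*sqrt(2(1-exp(-1/(2 rho^2)))), tiny
        # for rho >= 10; the ramp contributes 2.5/(T-1) per step
        rng = np.random.default_rng(53)
        c = sample_harvest_trajectory(rng, 150, "shifting")
        assert np.max(np.abs(np.diff(c))) < 0.2


class TestEulerMaruyama:
    def _params(self, c, T=200, sigma=1e-12):
        return SimParams(T=T, r=1.0, K=10.0, h=1.0, sigma=sigma,
                         c_traj=np.full(T, float(c)), regime="stationary")

    def test_deterministic_equilibrium_conserved(self):
        out = euler_maruyama(self._params(0.0), np.random.default_rng(0), x0=10.0)
        assert np.max(np.abs(out.values - 10.0)) < 1e-6

    def test_converges_to_upper_stable_root(self):
        out = euler_maruyama(self._params(2.0), np.random.default_rng(0), x0=10.0)
        upper = equilibria(2.0, 1, 10, 1)[-1]
        assert out.values[-1] == pytest.approx(upper, abs=1e-4)

    def test_stable_roots_are_fixed_points(self):
        for c in (1.0, 2.2):
            for root in equilibria(c, 1, 10, 1)[::2]:  # lower & upper stable
                out = euler_maruyama(self._params(c, T=100), np.random.default_rng(0),
                                     x0=root)
                assert np.max(np.abs(out.values - root)) < 1e-5 * 10.0


class TestDetectShift:
    def _ramp_params(self, T=300):
        c = np.linspace(1.5, 3.2, T)
        return SimParams(T=T, r=1.0, K=10.0, h=1.0, sigma=1e-12, c_traj=c,
                         regime="shifting")

    def test_deterministic_ramp_drop_near_upper_fold(self):
        p = self._ramp_params()
        series = euler_maruyama(p, np.random.default_rng(0), x0=10.0)
        idx = detect_shift(series, p)
        assert idx is not None
        # oracle: the sigma=0 trajectory leaves the upper branch only after
        # c exceeds c2
        drop = np.flatnonzero(series.values < 5.0)[0]
        assert abs(idx - (drop + 1)) <= 3

    def test_stationary_replicates_rarely_flag(self):
        rng = np.random.default_rng(54)
        flags = 0
        for _ in range(100):
            p = sample_sim_params(rng, "stationary")
            series = euler_maruyama(p, rng)
            flags += detect_shift(series, p) is not None
        assert flags <= 5

    def test_series_below_threshold_from_start(self):
        T = 50
        p = SimParams(T=T, r=1.0, K=10.0, h=1.0, sigma=0.1,
                      c_traj=np.full(T, 2.3), regime="shifting")
        series = TimeSeries(np.arange(1.0, T + 1), np.full(T, 0.1))
        assert detect_shift(series, p) == 1


class TestObservationError:
    def test_zero_sd_is_identity(self):
        s = TimeSeries(np.arange(1.0, 11), np.arange(10.0))
        assert add_observation_error(s, 0.0, np.random.default_rng(0)) is s

    def test_noise_sd_concentrates(self):
        s = TimeSeries(np.arange(1.0, 10001), np.zeros(10000))
        noisy = add_observation_error(s, 1.0, np.random.default_rng(55))
        assert 0.97 < np.std(noisy.values - s.values) < 1.03


class TestBenchmarkSuite:
    def test_structure_matching_and_determinism(self):
        a = generate_benchmark_suite(5, seed=7)
        b = generate_benchmark_suite(5, seed=7)
        assert len(a) == 10
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.series.values, rb.series.values)
        for shift_rep, stat_rep in zip(a[:5], a[5:]):
            assert shift_rep.label and not stat_rep.label
            assert len(stat_rep.truncated) == len(shift_rep.truncated)
            assert len(shift_rep.truncated) >= 15
            assert shift_rep.shift_index > len(shift_rep.truncated)
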