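import numpy as np
import pytest

from probews import PTVARConfig, TimeSeries, generate_benchmark_suite, run_benchmark


def make_ar1_series(n: int, phi, sigma: float = 1.0, seed: int = 0) -> TimeSeries:
    """Simulate a (possibly time-varying) AR(1) path on integer times."""
    rng = np.random.default_rng(seed)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n - 1,))
    x = np.zeros(n)
    for t in range(n - 1):
        x[t + 1] = phi[t] * x[t] + sigma * rng.standard_normal()
    return TimeSeries(np.arange(1, n + 1, dtype=float), x)


@pytest.fixture(scope="session")
def bench_suite():
    """20 shifting + 20 stationary May-model replicates, fixed seed."""
    return generate_benchmark_suite(20, seed=1)


@pytest.fixture(scope="session")
def bench_result(bench_suite):
    """Full three-detector benchmark on the session suite (desk-scale MCMC)."""
    return run_benchmark(
        bench_suite,
        models=("ar1", "tvar", "ptvar"),
        alpha=0.1,
        n_surrogates=100,
        seed=1,
        compute_mse=False,
        ptvar_cfg=PTVARConfig(chains=2, warmup=500, draws=500),
    )
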