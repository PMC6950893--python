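"""Shared fixtures: benchmark data and fitted models are session-scoped
because the latent-gradient fit is the expensive step most tests lean on."""

import numpy as np
import pytest

from glvnet import (
    GLVLinearRegression, fit_lgr, make_benchmark_spec, simulate_sde,
)


@pytest.fixture(scope="session")
def benchmark():
    """(spec, sign constraints) of the 3-species benchmark community."""
    return make_benchmark_spec()


@pytest.fixture(scope="session")
def benchmark_series(benchmark):
    spec, _ = benchmark
    return spec.simulate_deterministic()


@pytest.fixture(scope="session")
def noisy_benchmark_series(benchmark):
    spec, _ = benchmark
    return simulate_sde(spec, seed=12345)


@pytest.fixture(scope="session")
def benchmark_lr(benchmark, benchmark_series):
    _, cons = benchmark
    return GLVLinearRegression(constraints=cons).fit(benchmark_series)


@pytest.fixture(scope="session")
def benchmark_lgr(benchmark, benchmark_series):
    _, cons = benchmark
    return fit_lgr(benchmark_series, constraints=cons)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
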