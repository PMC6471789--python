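import numpy as np
import pytest

from gdpsurv import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """100 samples, 10 groups x 4 features, 3 relevant groups."""
    cfg = SimulationConfig(
        n_samples=100, n_groups=10, group_size=4, n_relevant_groups=3, rng_seed=42
    )
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def censored_case(rng):
    """A small random censored instance for oracle comparisons."""
    n = 60
    risk = rng.standard_normal(n)
    time = rng.uniform(1.0, 50.0, n)
    status = rng.integers(0, 2, n).astype(np.int8)
    status[0] = 1
    return risk, time, status
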