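import numpy as np
import pytest

from tracerflux import SimulationConfig, simulate_experiment
from tracerflux.simulate import noise_free, simulate_ancillary


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free simulation settings (exact-recovery regime)."""
    return noise_free(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_experiment(quiet_config):
    """A 3-site x 2-point noise-free lab experiment (18 treatment triplets)."""
    return simulate_experiment(quiet_config, n_sites=3, n_points=2)


@pytest.fixture(scope="session")
def ancillary_data():
    return simulate_ancillary(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
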