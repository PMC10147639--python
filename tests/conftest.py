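import numpy as np
import pytest

from thetanet import SimulationConfig, default_rule, init_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return SimulationConfig()


@pytest.fixture
def quiet_config():
    """Noise-free, uncoupled configuration for closed-form checks."""
    return SimulationConfig(noise_variance=0.0, g=0.0)


@pytest.fixture
def small_ei_state(config, rng):
    return init_network(20, 4, "ei", config, rng)


@pytest.fixture
def ei_rule():
    return default_rule("ei")
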