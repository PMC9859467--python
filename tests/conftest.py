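import numpy as np
import pytest

from breathcal import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams(noise_amplitude=0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_params):
    """Full wet-bath design (10 concentrations x 20 trials), no noise."""
    return generate_dataset(params=noiseless_params, seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_params):
    """Full wet-bath design with the default +/-1 count noise."""
    return generate_dataset(params=default_params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
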