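import numpy as np
import pytest

from corticowave.eeg import standard_montage
from corticowave.network import NetworkConfig, build_network, simulate


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def default_network():
    return build_network(NetworkConfig())


@pytest.fixture(scope="session")
def rest_traces(default_network):
    """Shared 8 s resting-state run (2 trials) for analysis tests."""
    return simulate(default_network, None, 8.0, seed=42, batch=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
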