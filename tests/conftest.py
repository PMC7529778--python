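import numpy as np
import pytest

from cardioloop import load_packaged_network, run_simulation
from cardioloop.gravity import configure_0g

UNITS = {"pressure": "mmHg", "volume": "ml", "time": "s", "length": "cm"}


@pytest.fixture
def units():
    return dict(UNITS)


@pytest.fixture
def baseline_net():
    """Fresh supine-1G baseline network."""
    return load_packaged_network()


@pytest.fixture(scope="session")
def steady_1g():
    """Full 100-beat supine-1G run (shared across the suite)."""
    return run_simulation(load_packaged_network(), n_beats=100)


@pytest.fixture(scope="session")
def steady_0g():
    """Full 100-beat chronic-0G run (shared across the suite)."""
    net, _ = configure_0g(load_packaged_network())
    return run_simulation(net, n_beats=100)


@pytest.fixture
def rng():
    return np.random.default_rng(20231118)
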