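import numpy as np
import pytest

from pfcsim.config import default_config
from pfcsim.network import build_network
from pfcsim.simulate import BackgroundCurrents, run


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_graph():
    """300-neuron default-config network shared across fast tests."""
    return build_network(300, seed=11)


@pytest.fixture(scope="session")
def default_bg():
    return BackgroundCurrents.uniform(250.0, 200.0)


@pytest.fixture(scope="session")
def short_recording(small_graph, default_bg):
    """2 s default run of the small network (warms the compiled engine)."""
    return run(small_graph, default_bg, 2000.0, seed=21)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
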