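import numpy as np
import pytest
from hypothesis import settings

from tacsnet import default_config, make_toy_network

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_config():
    """Miniature network configuration for fast engine tests."""
    cfg = default_config(seed=7)
    cfg.network.py_shape = (8, 8)
    cfg.network.in_shape = (4, 4)
    cfg.network.degree_py_py = 8
    cfg.network.degree_py_in = 3
    cfg.network.degree_in_py = 5
    cfg.network.radius_py_py = None
    cfg.network.radius_py_in = None
    cfg.engine.duration_ms = 500.0
    return cfg


@pytest.fixture
def toy_network(rng):
    return make_toy_network((8, 8), (4, 4), (8, 3, 5), rng)
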