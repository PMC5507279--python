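import numpy as np
import pytest

from rpsim import KineticParams, TorusGeometry, make_state


@pytest.fixture
def geom10():
    return TorusGeometry(10.0, 10.0)


@pytest.fixture
def rng():
    return make_state(12345)


@pytest.fixture
def kin_default():
    return KineticParams()


def random_positions(n, geom, seed):
    g = np.random.default_rng(seed)
    pts = g.uniform([0, 0], [geom.width, geom.height], size=(n, 2))
    return np.minimum(pts, [geom.width * (1 - 1e-12), geom.height * (1 - 1e-12)])
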