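import numpy as np
import pytest

from tumorpotts.adhesion import AdhesionModel
from tumorpotts.testkit import make_small_lattice


@pytest.fixture
def model():
    return AdhesionModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lone_cell_state():
    """A single 4x4 PCancer cell (v = V = 16, s = S = 16) in Medium."""
    return make_small_lattice(
        [{"x0": 8, "y0": 8, "w": 4, "h": 4, "cad": 8.0, "int": 8.0}],
        dims=(20, 20),
    )


@pytest.fixture
def three_cell_state():
    return make_small_lattice(
        [
            {"x0": 1, "y0": 1, "w": 3, "h": 3, "cad": 8.0, "int": 8.0},
            {"x0": 6, "y0": 1, "w": 2, "h": 4, "cad": 2.0, "int": 12.0},
            {"x0": 3, "y0": 7, "w": 4, "h": 2, "cad": 15.0, "int": 1.0},
        ],
        dims=(12, 12),
    )
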