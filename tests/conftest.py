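import numpy as np
import pytest

from helixforge.fixtures import make_toy_monomer
from helixforge.geometry import Screw
from helixforge.reduce import coarse_grain


@pytest.fixture(scope="session")
def blob40():
    return make_toy_monomer(40, "blob", seed=1)


@pytest.fixture(scope="session")
def horseshoe36():
    return make_toy_monomer(36, "horseshoe", seed=2)


@pytest.fixture(scope="session")
def rod20():
    return make_toy_monomer(20, "rod", seed=3)


@pytest.fixture(scope="session")
def blob40_reduced(blob40):
    return coarse_grain(blob40)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def c6_screw():
    return Screw(np.zeros(3), np.array([0.0, 0.0, 1.0]), 60.0, 0.0)


@pytest.fixture
def helix_screw():
    # 6 monomers/turn, 85.02 A pitch, right-handed
    return Screw(np.zeros(3), np.array([0.0, 0.0, 1.0]), 60.0, 14.17)


def random_screw(rng, max_offset=20.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Screw(
        rng.normal(size=3) * max_offset,
        axis,
        rng.uniform(1.0, 179.0),
        rng.uniform(-20.0, 20.0),
    )
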