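import numpy as np
import pytest

from lcaodna import LcaoParameters, fixtures


@pytest.fixture(scope="session")
def params():
    return LcaoParameters()


@pytest.fixture(scope="session")
def adenine():
    return fixtures.nucleobase("A")


@pytest.fixture(scope="session")
def uracil():
    return fixtures.nucleobase("U")


@pytest.fixture(scope="session")
def at_pair():
    return fixtures.watson_crick_pair("A")


@pytest.fixture(scope="session")
def gc_pair():
    return fixtures.watson_crick_pair("G")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210830)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-10.0, 10.0, size=3)
    return R, t
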