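import numpy as np
import pytest

from acmap.io import BinaryMask
from acmap.phantoms import PhantomSpec, default_scheme, make_tensor_phantom


@pytest.fixture(scope="session")
def scheme():
    """10 b0 + 61 directions at b = 1200 s/mm^2."""
    return default_scheme()


@pytest.fixture(scope="session")
def tube_phantom():
    spec = PhantomSpec(geometry="straight_tube", dims=(20, 9, 9), radius=2.0)
    return make_tensor_phantom(spec)


@pytest.fixture(scope="session")
def small_tube_phantom():
    spec = PhantomSpec(geometry="straight_tube", dims=(12, 5, 5), radius=1.2)
    return make_tensor_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cube_mask():
    return BinaryMask(np.ones((8, 8, 8), dtype=np.uint8), np.eye(4))
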