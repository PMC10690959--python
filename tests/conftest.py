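import numpy as np
import pytest

from mvtseg.phantoms import PhantomParams, generate_phantom
from mvtseg.volume_io import LabelMap, Volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48³ phantom used across tests."""
    return generate_phantom(PhantomParams(), seed=123)


@pytest.fixture()
def random_labelmap(rng):
    def make(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
        data = rng.integers(0, 3, size=shape).astype(np.int16)
        return LabelMap(data, spacing)
    return make


@pytest.fixture()
def random_volume(rng):
    def make(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
        return Volume(rng.normal(size=shape).astype(np.float32), spacing)
    return make
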