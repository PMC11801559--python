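import numpy as np
import pytest

from radenhance.phantom import PhantomSpec, generate_phantom, make_fixture_batch
from radenhance.raster_io import NormalizedImage, RawImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_raw():
    return RawImage(pixels=np.array([[0, 128], [64, 255]], dtype=np.uint8), bit_depth=8)


@pytest.fixture
def default_phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_batch_20():
    """20 default phantoms, shared across tests that only read them."""
    return make_fixture_batch(20, base_seed=1)


@pytest.fixture
def random_normalized(rng):
    def factory(shape=(16, 16)):
        return NormalizedImage(values=rng.uniform(0.0, 1.0, size=shape))

    return factory
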