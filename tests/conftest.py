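import numpy as np
import pytest

from spineseg.nifti_io import LabelMap, Volume, default_affine
from spineseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noise-free phantom for geometric assertions."""
    spec = PhantomSpec(grid=(32, 48, 48), n_vertebrae=4, noise_sd=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom (with noise)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture
def random_volume(rng):
    data = rng.normal(loc=0.0, scale=300.0, size=(8, 12, 10))
    return Volume(data, default_affine((2.0, 1.5, 1.0)))


@pytest.fixture
def random_labels(rng):
    data = rng.integers(0, 4, size=(8, 12, 10)).astype(np.int16)
    return LabelMap(data, default_affine((2.0, 1.5, 1.0)))
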