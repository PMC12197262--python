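import numpy as np
import pytest

from choroid_sps import GrayImage, PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One quarter-scale phantom shared by read-only tests."""
    return generate_phantom(PhantomParams.scaled(248, 256, seed=0))


def make_gray(arr) -> GrayImage:
    return GrayImage(np.asarray(arr, dtype=np.float64))
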