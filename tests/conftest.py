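import numpy as np
import pytest

from tissuemetrics.image_io import GrayImage, RGBImage


@pytest.fixture
def rng():
    return np.random.default_rng(20241109)


@pytest.fixture
def random_gray(rng):
    """A 128x128 random grayscale image."""
    return GrayImage(pixels=rng.uniform(0, 255, size=(128, 128)))


@pytest.fixture
def rgb_ramp():
    """A small RGB image with distinct constant channels."""
    px = np.zeros((6, 8, 3))
    px[:, :, 0] = 10.0
    px[:, :, 1] = 20.0
    px[:, :, 2] = 30.0
    return RGBImage(pixels=px)
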