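import numpy as np
import pytest

from qipbox.cnn import surrogate_bank
from qipbox.io import GrayImage, RasterImage
from qipbox.synthetic import gray_to_raster, random_phase_image


@pytest.fixture(scope="session")
def bank():
    return surrogate_bank(0)


@pytest.fixture(scope="session")
def rp_image_256():
    """A mid-slope random-phase test image, promoted to RGB."""
    return gray_to_raster(random_phase_image(256, 1.2, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_raster(rng, h, w):
    return RasterImage(rng.integers(0, 256, (h, w, 3), dtype=np.uint8))


def random_gray(rng, h, w):
    return GrayImage(rng.integers(0, 256, (h, w)).astype(float))
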