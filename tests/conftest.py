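import numpy as np
import pytest

from artvalue.raster import RasterImage


@pytest.fixture
def banded_image() -> RasterImage:
    """64x64 image of three solid horizontal bands (heights 32/16/16)."""
    px = np.zeros((64, 64, 3))
    px[:32] = [0.9, 0.1, 0.1]
    px[32:48] = [0.1, 0.9, 0.1]
    px[48:] = [0.1, 0.1, 0.9]
    return RasterImage(px)


@pytest.fixture
def quadrant_image() -> RasterImage:
    """48x48 image of four solid quadrants."""
    px = np.zeros((48, 48, 3))
    px[:24, :24] = [1.0, 0.0, 0.0]
    px[:24, 24:] = [0.0, 1.0, 0.0]
    px[24:, :24] = [0.0, 0.0, 1.0]
    px[24:, 24:] = [1.0, 1.0, 0.0]
    return RasterImage(px)


@pytest.fixture
def noise_image() -> RasterImage:
    rng = np.random.default_rng(7)
    return RasterImage(rng.uniform(0.0, 1.0, (48, 48, 3)))
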