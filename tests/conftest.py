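import numpy as np
import pytest

from dentnum.raster import Modality, RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def bordered_image():
    """300x400 grayscale frame: 50 px all-zero border, bright interior."""
    px = np.zeros((300, 400), dtype=np.uint8)
    px[50:250, 50:350] = 180
    return RasterImage(px, Modality.PANO)


def random_gray(rng, h, w, modality=Modality.UNKNOWN):
    return RasterImage(rng.integers(0, 256, size=(h, w), dtype=np.uint8), modality)
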