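import numpy as np
import pytest

from perfquant.image_io import PixelGrid
from perfquant.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def grid8(arr, pd=1.0):
    """Wrap an array as an 8-bit PixelGrid."""
    return PixelGrid(np.asarray(arr, dtype=np.uint8), bit_depth=8, pd=pd)


def mask(arr, pd=1.0):
    return BinaryMask(np.asarray(arr, dtype=bool), pd=pd)
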