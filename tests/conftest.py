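import numpy as np
import pytest

from irfpquant.image_io import RawImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_raw_image(rng, shape=(32, 32), bit_depth=16, high=None):
    """Seeded random RawImage helper used across test modules."""
    ceiling = (1 << bit_depth) - 1
    high = ceiling if high is None else high
    pixels = rng.integers(0, high + 1, size=shape,
                          dtype=np.uint16 if bit_depth <= 16 else np.uint32)
    return RawImage(pixels, bit_depth=bit_depth)
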