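import numpy as np
import pytest

from difftx.dt_core import PixelGrid


def random_grid(rng, height, width, channels=1, bit_depth=8):
    """Uniform-random PixelGrid helper shared across test modules."""
    samples = rng.integers(0, 1 << bit_depth, size=(height, width, channels))
    return PixelGrid(samples=samples, bit_depth=bit_depth)


@pytest.fixture
def rng():
    return np.random.default_rng(20240951)
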