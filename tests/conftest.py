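import numpy as np
import pytest

from hjorth2d import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240926)


@pytest.fixture
def noise_image(rng):
    """Seeded 32x32 uniform-noise image."""
    return GrayImage(rng.uniform(0, 255, size=(32, 32)))


def ramp_x(n=16):
    """I(x, y) = x on an n x n grid."""
    return GrayImage(np.tile(np.arange(n, dtype=float), (n, 1)))


def quadratic_x(n=16):
    """I(x, y) = x^2."""
    x = np.arange(n, dtype=float)
    return GrayImage(np.tile(x**2, (n, 1)))
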