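import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Generic 64x64 grayscale test image."""
    return rng.random((64, 64))


@pytest.fixture
def smooth_image():
    """Smooth synthetic image with mixed radial and angular content."""
    yy, xx = np.meshgrid(np.linspace(-1, 1, 96), np.linspace(-1, 1, 96), indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    img = 0.5 + 0.3 * np.exp(-((xx - 0.2) ** 2 + yy**2) / 0.15)
    img += 0.15 * np.cos(3 * theta) * np.exp(-(r**2))
    return np.clip(img, 0.0, 1.0)
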