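import numpy as np
import pytest

from rrstrace.imaging import DEFAULT_EPS, GrayImage


@pytest.fixture
def constant_image():
    return GrayImage(np.full((20, 20), 0.5))


@pytest.fixture
def ramp_image():
    """I(row, col) = col / 10, clipped to [eps, 1]."""
    cols = np.tile(np.arange(20) / 10.0, (20, 1))
    return GrayImage(np.clip(cols, DEFAULT_EPS, 1.0))


@pytest.fixture
def ridge_image():
    """1-px bright horizontal ridge (0.9) on dark background (0.1)."""
    img = np.full((21, 40), 0.1)
    img[10, :] = 0.9
    return GrayImage(img)


@pytest.fixture
def blob_image():
    """Filled bright square much wider than the classification zone."""
    img = np.full((40, 40), 0.1)
    img[5:35, 5:35] = 0.9
    return GrayImage(img)


def random_image(rng, shape=(32, 32)):
    return GrayImage(rng.uniform(DEFAULT_EPS, 1.0, shape))
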