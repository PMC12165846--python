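import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from ringdecon import OpticalGrid, make_phantom


@pytest.fixture(scope="session")
def grid32():
    return OpticalGrid(n=32)


@pytest.fixture(scope="session")
def grid64():
    return OpticalGrid(n=64)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, seed=1)


@pytest.fixture(scope="session")
def smooth32():
    """Band-limited test image with a smooth taper to zero at the border."""
    rng = np.random.default_rng(7)
    img = gaussian_filter(rng.random((32, 32)), 2.5)
    n = 32
    m = 6
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
    win = np.ones(n)
    win[:m] = ramp
    win[-m:] = ramp[::-1]
    return img * win[:, None] * win[None, :]


@pytest.fixture(scope="session")
def smooth64():
    rng = np.random.default_rng(7)
    img = gaussian_filter(rng.random((64, 64)), 2.5)
    n = 64
    m = 10
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
    win = np.ones(n)
    win[:m] = ramp
    win[-m:] = ramp[::-1]
    return img * win[:, None] * win[None, :]
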