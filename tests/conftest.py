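import numpy as np
import pytest

from vesselmink.core_io import BinaryVolume
from vesselmink.phantoms import make_hollow_sphere, make_torus, standard_phantom


def digitized_ball(r, extra=2):
    n = 2 * (r + extra) + 1
    c = n // 2
    z, y, x = np.mgrid[:n, :n, :n]
    return BinaryVolume(((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= r * r)


@pytest.fixture(scope="session")
def ball24():
    return digitized_ball(24)


@pytest.fixture(scope="session")
def torus_8_3():
    return make_torus(8, 3, (13, 27, 27))


@pytest.fixture(scope="session")
def shell_10_7():
    return make_hollow_sphere(10, 7, (25, 25, 25))


@pytest.fixture(scope="session")
def snr5_phantom():
    """(ground-truth volume, truth dict, rendered SNR-5 stack)."""
    return standard_phantom(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
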