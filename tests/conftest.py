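import numpy as np
import pytest

from eatomo.field import Medium
from eatomo.forward import ArrayGeometry

V_SOUND = 1497.0
FS = 40e6


@pytest.fixture(scope="session")
def water_medium_small():
    """129x129 grid at 0.05 mm pixels (odd size: has an exact centre pixel)."""
    return Medium.homogeneous((129, 129), 0.05e-3, v_s=V_SOUND)


@pytest.fixture(scope="session")
def image_medium():
    """200x200 grid at 0.1 mm pixels for reconstruction round trips."""
    return Medium.homogeneous((200, 200), 0.1e-3, v_s=V_SOUND)


@pytest.fixture(scope="session")
def ring128():
    """Full 128-element, 50 mm ring at 40 MHz, windowed around the grid."""
    return ArrayGeometry(n_elements=128, ring_radius=0.050,
                         sampling_rate=FS, n_samples=2048, t0=25e-6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
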