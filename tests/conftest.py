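import numpy as np
import pytest

from sticklesim.fixtures import REGIME_PARAMS
from sticklesim.simulate import TankGeometry


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20230904)


@pytest.fixture
def medium_params():
    """Typical mover: gamma mean 4 mm, rank autocorrelation 0.81."""
    return REGIME_PARAMS["medium"]


@pytest.fixture
def roomy_tank():
    """Geometrically similar tank, scaled so the boundary rule rarely binds."""
    return TankGeometry(top_radius=600.0, base_radius=550.0, depth=320.0)


def random_axes(rng):
    """Random right-handed orthonormal triad."""
    Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q.T  # rows
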