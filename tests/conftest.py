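import numpy as np
import pytest

from shgpol.model import total_intensity
from shgpol.orientation import PolarizationStack

ANGLES18 = np.arange(18) * 10.0


def render_pixel_stack(phi_rad, rho, K=1.0, angles_deg=ANGLES18):
    """Noiseless single-pixel polarization stack from the harmonic model."""
    theta = np.deg2rad(np.asarray(angles_deg))
    frames = total_intensity(theta, phi_rad, rho, K)[None, None, :]
    return PolarizationStack(frames, angles_deg)


def circ_diff(a, b):
    """Signed axial (period-pi) difference a - b in radians."""
    return np.angle(np.exp(2j * (np.asarray(a) - np.asarray(b)))) / 2.0


@pytest.fixture(scope="session")
def adult_bundle():
    """One seeded 128x128 adult fixture shared by read-only tests."""
    from shgpol.simulate import make_fixture

    return make_fixture("adult", shape=(128, 128), seed=7)
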