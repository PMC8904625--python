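import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retiq import SamplingConfig, SpheroCylinder, ZernikeWavefront, sc_to_zernike, to_power_vector

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg128():
    """Fast sampling used throughout the suite (64 samples across the pupil)."""
    return SamplingConfig(grid_size=128, pupil_fill_fraction=0.5, psf_window_arcmin=30.0)


@pytest.fixture(scope="session")
def cfg256():
    return SamplingConfig(grid_size=256, pupil_fill_fraction=0.5, psf_window_arcmin=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_wavefront(rng, pupil=4.0, lo_scale=0.3, hoa_scale=0.05):
    """A plausible random eye: moderate low-order error plus small HOA."""
    c = np.zeros(15)
    c[3:6] = rng.normal(0.0, lo_scale, 3)
    c[6:] = rng.normal(0.0, hoa_scale, 9)
    return ZernikeWavefront(c, pupil)


def pure_low_order_wavefront(sc: SpheroCylinder, pupil=4.0):
    """Wavefront whose only content is the given prescription."""
    c = np.zeros(15)
    c[3:6] = sc_to_zernike(to_power_vector(sc), pupil)
    return ZernikeWavefront(c, pupil)
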