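import warnings

import numpy as np
import pytest

from tipwall.mechanics import ViscoplasticParams
from tipwall.simulator import steady_state_profile
from tipwall.synthetic import SynthesisSpec, cap_blend_profile
from tipwall.thickness import WallGradient

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def gradient():
    """The fitted Pearson wall-thickness gradient of the apical cell."""
    return WallGradient("pearson", 0.0362, 0.591, 16.81)


@pytest.fixture(scope="session")
def params():
    """Viscoplastic parameters: P=0.495 MPa, Phi=2.51e-3, sigma_y=11.18."""
    return ViscoplasticParams()


@pytest.fixture(scope="session")
def trumpet(gradient, params):
    """Exact self-similar (traveling-wave) profile at the default parameters."""
    return steady_state_profile(gradient, params, s_max=20.0)


@pytest.fixture(scope="session")
def trumpet_coarse(gradient, params):
    """Coarser steady profile for fast simulation tests."""
    return steady_state_profile(gradient, params, spacing=0.15, s_max=14.0)


@pytest.fixture(scope="session")
def cap_profile():
    """Spherical-cap dome (tip curvature 0.27) blended into an R=3.27 cylinder."""
    return cap_blend_profile()


@pytest.fixture()
def spec():
    return SynthesisSpec(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
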