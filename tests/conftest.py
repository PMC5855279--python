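import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermocr import NoiseModel, reference_curve

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curve():
    """The published cubic calibration, valid on 40-100 °C."""
    return reference_curve()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def quiet_noise():
    """Noise model with everything switched off."""
    return NoiseModel(
        sigma_cr=0.0, particle_fraction=0.0, illumination_offset_amplitude=0.0, seed=0
    )
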