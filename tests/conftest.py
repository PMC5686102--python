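import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfdiscope.optics import OpticalProperties
from sfdiscope.scene import NoiseModel, make_phantom_scene

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NOISE_OFF = NoiseModel(shot_scale=0.0, read_sigma=0.0, multiplicative_sigma=0.0)


@pytest.fixture(scope="session")
def noise_off():
    return NOISE_OFF


@pytest.fixture(scope="session")
def ref_ops():
    return {
        490.0: OpticalProperties(1.0, 15.0, 490.0),
        590.0: OpticalProperties(0.8, 12.5, 590.0),
    }


@pytest.fixture()
def flat_scene():
    """Small homogeneous noise-free scene with 10 ug/mL drug."""
    return make_phantom_scene(
        1.0, 15.0, 0.8, 12.5, dox_conc=10.0, shape=(32, 32), noise=NOISE_OFF
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
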