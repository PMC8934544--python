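import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from danioeye.oct_biometry import RefractiveIndexSet
from danioeye.synthkit import EyeGeometrySpec, OctRenderConfig


@pytest.fixture(scope="session")
def small_geometry() -> EyeGeometrySpec:
    """A small model eye that fits in the fast test volume."""
    return EyeGeometrySpec(
        corneal_thickness=20.0,
        acd=25.0,
        lens_diameter=200.0,
        vcd=120.0,
        retinal_thickness=60.0,
        rpe_thickness=12.0,
        equatorial_diameter_x=500.0,
        equatorial_diameter_y=500.0,
    )


@pytest.fixture(scope="session")
def small_cfg() -> OctRenderConfig:
    """Fast render configuration: ~0.35 mm of lateral field, 0.7 mm depth."""
    return OctRenderConfig(volume_shape=(350, 52, 52), z_offset_um=30.0)


@pytest.fixture(scope="session")
def indices() -> RefractiveIndexSet:
    return RefractiveIndexSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
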