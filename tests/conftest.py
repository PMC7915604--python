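import numpy as np
import pytest

from specsep import (
    Affine,
    BandDef,
    Scene,
    SensorModel,
    make_sensor,
)
from specsep.synthetic import default_scene_spec, generate_scene


@pytest.fixture(scope="session")
def hyper_sensor() -> SensorModel:
    return make_sensor("hyper")


@pytest.fixture(scope="session")
def multi_sensor() -> SensorModel:
    return make_sensor("multi")


def tiny_sensor(wavelengths, detector="MSI", res=30.0, name="tiny") -> SensorModel:
    return SensorModel(
        name,
        tuple(BandDef(i, float(w), detector) for i, w in enumerate(wavelengths)),
        res,
    )


@pytest.fixture
def small_sensor() -> SensorModel:
    return tiny_sensor([450.0, 560.0, 660.0, 860.0])


@pytest.fixture
def constant_scene(small_sensor) -> Scene:
    """4x4 scene, every band constant at 0.25."""
    values = np.full((4, 4, small_sensor.n_bands), 0.25)
    return Scene(
        values=values,
        transform=Affine.from_origin(0.0, 120.0, 30.0, 30.0),
        crs="EPSG:32632",
        sensor=small_sensor,
    )


@pytest.fixture(scope="session")
def generated_pair():
    """A seeded synthetic scene with its regions (shared across tests)."""
    spec = default_scene_spec(seed=42, block_px=16)
    scene, regions = generate_scene(spec)
    return spec, scene, regions
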