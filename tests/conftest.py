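import numpy as np
import pytest

from azimint.calibration import CalibrationSpec, GeometrySpec, MaskSpec
from azimint.synthetic import DEFAULT_WAVELENGTH, default_geometry


@pytest.fixture(scope="session")
def geom256() -> GeometrySpec:
    return default_geometry((256, 256))


@pytest.fixture(scope="session")
def geom64() -> GeometrySpec:
    return default_geometry((64, 64))


@pytest.fixture(scope="session")
def wavelength() -> float:
    return DEFAULT_WAVELENGTH


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_calibration(geom64) -> CalibrationSpec:
    """All-clear mask, unit radial step, classifier window 0.1-1.0 nm^-1."""
    return CalibrationSpec(
        geometry=geom64,
        masks=(MaskSpec(path_to_file="", pix_per_rad_element=1.0, q_start=0.1, q_stop=1.0),),
        wavelength=DEFAULT_WAVELENGTH,
        threads=2,
    )


def random_geometry(rng: np.random.Generator, size: int = 64) -> GeometrySpec:
    """A randomized but physically sensible small-detector geometry."""
    return GeometrySpec(
        beamcenter=(
            float(rng.uniform(size * 0.25, size * 0.75)),
            float(rng.uniform(size * 0.25, size * 0.75)),
        ),
        detector_distance=float(rng.uniform(300.0, 2000.0)),
        image_size=(size, size),
        pixel_size=(float(rng.uniform(75.0, 200.0)), float(rng.uniform(75.0, 200.0))),
        tilt_rotation=float(rng.uniform(-180.0, 180.0)),
        tilt_angle=float(rng.uniform(-10.0, 10.0)),
    )
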