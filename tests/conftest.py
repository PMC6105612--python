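import numpy as np
import pytest

from ppixquant.camera import external_camera, internal_ccd
from ppixquant.scene import StudyDesign, generate_series


@pytest.fixture(scope="session")
def small_design():
    """A reduced study (2 specimens, 128x128 grid, 5 time points) that keeps
    the default physics but runs in well under a second."""
    return StudyDesign(
        n_specimens=2,
        times_min=(0.0, 1.0, 5.0, 10.0, 30.0),
        shape=(128, 128),
        pitch_mm=0.4,
        roi_radius_px=10,
        cameras=(external_camera(), internal_ccd()),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_series(small_design)


@pytest.fixture(scope="session")
def default_study():
    """One full-size default study (6 specimens, 512x512, 15 frames),
    external camera only; shared across tests because it is the expensive
    fixture."""
    return generate_series(StudyDesign(cameras=(external_camera(),), seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
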