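import pytest

from mwcolon import array_forward as af
from mwcolon import imaging as im
from mwcolon.scene import Scatterer


@pytest.fixture(scope="session")
def geometry():
    return af.ArrayGeometry()


@pytest.fixture(scope="session")
def schedule(geometry):
    return af.build_schedule(geometry)


@pytest.fixture(scope="session")
def k_bg(geometry):
    return af.background_wavenumber(geometry)


@pytest.fixture(scope="session")
def baseline(geometry, schedule, k_bg):
    return af.compute_baseline(geometry, schedule, k_bg)


@pytest.fixture(scope="session")
def grid():
    return im.PolarGrid()


@pytest.fixture(scope="session")
def reconstructor(geometry, schedule, grid):
    return im.Reconstructor(geometry, schedule, grid)


def make_scatterer(r=13.0, theta=1.0, chi=0.2 + 0.05j, amplitude=1.0, kind="polyp"):
    return Scatterer(r=r, theta=theta, chi=chi, amplitude=amplitude, kind=kind)


@pytest.fixture
def single_scatterer():
    return make_scatterer()


def scattered(geometry, schedule, k, baseline, scatterers):
    """Noise-free scattered part of a frame (baseline removed)."""
    frame = af.simulate_frame(geometry, schedule, scatterers, k, baseline)
    return frame.data - baseline
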