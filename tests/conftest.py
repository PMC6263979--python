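import numpy as np
import pytest

from pasim.optical_transport import (
    CartesianGrid,
    IlluminationGeometry,
    LIPOFUNDIN_1PCT,
    PulseProfile,
    solve_fluence,
)
from pasim.us_array_imaging import LinearArray


@pytest.fixture(scope="session")
def medium():
    return LIPOFUNDIN_1PCT


@pytest.fixture(scope="session")
def pulse():
    return PulseProfile()


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheap full-domain grid for solver behaviour tests."""
    return CartesianGrid(spacing=2.0)


@pytest.fixture(scope="session")
def design_grid():
    """The 1 mm grid used for the design-sweep observables."""
    return CartesianGrid(spacing=1.0)


@pytest.fixture(scope="session")
def array():
    return LinearArray()


@pytest.fixture(scope="session")
def steady_field(medium, pulse, coarse_grid):
    """One shared steady solve at reference geometry (35 deg, 14 mm)."""
    geom = IlluminationGeometry()
    return solve_fluence(medium, pulse, geom, coarse_grid, mode="steady")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
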