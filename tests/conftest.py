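import numpy as np
import pytest

from isovel.grids import Grid2D
from isovel.synthetic import SyntheticScenario, make_dem, make_temperature_field


@pytest.fixture
def small_grid():
    """3x3 grid with one nodata cell, NW centre at (50N, 8E), 0.5 deg."""
    vals = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]])
    return Grid2D(values=vals, lat_origin=50.0, lon_origin=8.0, resolution=0.5, units="m")


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def dem(scenario):
    return make_dem(scenario)


@pytest.fixture(scope="session")
def temperature(dem, scenario):
    return make_temperature_field(dem, scenario)
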