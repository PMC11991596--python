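import numpy as np
import pytest

from vegcarbon.grid_io import Affine, RasterGrid
from vegcarbon.synthetic import (MonthlyClimate, SyntheticScenario,
                                 generate_climate, generate_drivers,
                                 generate_vegetation)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(shape=(25, 25), n_years=8, seed=11)


@pytest.fixture(scope="session")
def small_climate(small_scenario) -> MonthlyClimate:
    return generate_climate(small_scenario)


@pytest.fixture(scope="session")
def small_vegetation(small_scenario, small_climate):
    return generate_vegetation(small_scenario, small_climate)


@pytest.fixture(scope="session")
def small_drivers(small_scenario):
    return generate_drivers(small_scenario)


def make_grid(values, x0=0.0, north=None, dx=100.0, dy=100.0, **kw) -> RasterGrid:
    values = np.asarray(values, dtype=float)
    if north is None:
        north = values.shape[0] * dy
    return RasterGrid(values, Affine.from_origin(x0, north, dx, dy), **kw)
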