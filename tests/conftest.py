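import numpy as np
import pandas as pd
import pytest

from peatghg import (
    ClimateZone,
    GWPSet,
    LandUse,
    WorldSpec,
    generate_world,
    world_to_grid,
)
from peatghg.io import load_ef_table


@pytest.fixture(scope="session")
def ef_table():
    """Packaged synthetic emission-factor table, aggregated to CO2-eq."""
    return load_ef_table(gwp=GWPSet())


@pytest.fixture(scope="session")
def small_spec():
    """A fast 64x64 world exercising both allocation branches."""
    return WorldSpec(seed=7, shape=(64, 64), n_countries=4,
                     degradation_ratios=(0.05, 0.5, 0.0, 0.35))


@pytest.fixture(scope="session")
def small_world(small_spec):
    return generate_world(small_spec)


@pytest.fixture(scope="session")
def small_grid(small_world):
    return world_to_grid(small_world)


@pytest.fixture()
def toy_grid():
    """A hand-built 4-cell accountable grid (1 ha cells)."""
    peat = np.array([[1, 1], [1, 0]], dtype=bool)
    landuse = np.array(
        [[LandUse.CL, LandUse.GL], [LandUse.FL, LandUse.NONE]], dtype=np.int8
    )
    climate = np.full((2, 2), ClimateZone.TROPICAL, dtype=np.int8)
    from peatghg import build_grid

    return build_grid(peat, landuse, climate, country=np.zeros((2, 2), int),
                      cell_area_ha=1.0)


@pytest.fixture()
def country_table():
    return pd.DataFrame(
        {
            "country_id": [0, 1],
            "peat_area_ha": [100.0, 100.0],
            "cropland_on_peat_ha": [30.0, 10.0],
            "degraded_area_ha": [20.0, 40.0],
        }
    )
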