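import numpy as np
import pytest

from climascreen.climate_raster import ClimateGrid, SpecimenClimate
from climascreen.occurrence_io import OccurrenceRecord


def make_grid(values, variable="PDQ", x_ll=100.0, y_ll=20.0, cell_size=1.0):
    return ClimateGrid(
        variable=variable,
        values=np.asarray(values, dtype=float),
        x_ll=x_ll,
        y_ll=y_ll,
        cell_size=cell_size,
    )


@pytest.fixture
def grid_pair():
    """3x4 PDQ/MTCM grids over lon 100-104, lat 20-23 with distinct values."""
    pdq = make_grid(np.arange(12, dtype=float).reshape(3, 4) * 10 + 30, "PDQ")
    mtcm = make_grid(np.arange(12, dtype=float).reshape(3, 4) - 4, "MTCM")
    return pdq, mtcm


@pytest.fixture
def toy_specimens():
    """Three species with hand-pickable medians and widths."""
    def spec(name, lat, lon, pdq, mtcm):
        return SpecimenClimate(OccurrenceRecord(name, lat, lon), pdq, mtcm)

    return [
        spec("sp_a", 21.0, 101.0, 3.0, 0.0),
        spec("sp_a", 21.1, 101.1, 9.0, 1.0),
        spec("sp_a", 21.2, 101.2, 6.0, 2.0),
        spec("sp_b", 22.0, 102.0, 50.0, 5.0),
        spec("sp_b", 22.1, 102.1, 60.0, 6.0),
        spec("sp_c", 23.0, 103.0, 100.0, -3.0),
    ]
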