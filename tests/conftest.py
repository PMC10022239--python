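import numpy as np
import pytest

from chwplace import generate_region
from chwplace.grids import Grid


@pytest.fixture(scope="session")
def small_region():
    """A compact synthetic region small enough for exact solves in tests."""
    return generate_region(
        seed=20260928,
        shape=(24, 24),
        total_pop=40_000.0,
        n_urban_cores=2,
        urban_share=0.55,
        n_ccs=4,
        n_zones=2,
    )


@pytest.fixture
def uniform_friction():
    """5x5 friction grid at 12 min/km, 1 km cells."""
    return Grid(values=np.full((5, 5), 12.0), cell_size_km=1.0)


def make_grid(values, cell_size=1.0, nodata=None):
    values = np.asarray(values, dtype=float)
    mask = np.zeros_like(values, dtype=bool) if nodata is None else np.asarray(nodata, bool)
    return Grid(values=values, cell_size_km=cell_size, nodata_mask=mask)
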