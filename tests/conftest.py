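import numpy as np
import pytest

from silvocool import BiomeMap, Field, GeoGrid
from silvocool.biomes import DEFAULT_LEGEND


@pytest.fixture
def small_grid():
    return GeoGrid(origin_lat=2.0, origin_lon=10.0, cell_size=0.25,
                   n_rows=8, n_cols=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_field(grid, values, units="°C", missing=None):
    values = np.broadcast_to(np.asarray(values, dtype=float), grid.shape).copy()
    return Field(grid, values, units, missing)


@pytest.fixture
def uniform_biomes(small_grid):
    """Left two columns intact moist broadleaf forest, rest grasslands."""
    codes = np.full(small_grid.shape, 6, dtype=int)
    codes[:, :2] = 1
    return BiomeMap(small_grid, codes, DEFAULT_LEGEND)
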