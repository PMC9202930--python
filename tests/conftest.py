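import numpy as np
import pytest

from canidconnect.raster import RasterGrid, ResistanceSurface
from canidconnect.vector import OccurrenceSet


@pytest.fixture
def template():
    """10x10 grid of 100 m cells with origin at (0, 1000)."""
    return RasterGrid(values=np.zeros((10, 10)), cell_size=100.0, origin=(0.0, 1000.0))


@pytest.fixture
def uniform_resistance():
    """Factory for constant-resistance landscapes."""

    def make(n_rows=10, n_cols=10, cell_size=100.0, value=1.0, nodata_mask=None):
        grid = RasterGrid(
            values=np.full((n_rows, n_cols), value),
            cell_size=cell_size,
            origin=(0.0, n_rows * cell_size),
            nodata_mask=nodata_mask,
        )
        return ResistanceSurface(grid=grid)

    return make


@pytest.fixture
def point_at():
    """Factory for an OccurrenceSet at given cell centers of a grid."""

    def make(grid, *cells):
        pts = [grid.cell_center(r, c) for r, c in cells]
        return OccurrenceSet(species="test", points=np.array(pts, dtype=float))

    return make


def random_resistance_grid(rng, n_rows, n_cols, cell_size=100.0):
    """Random resistance in [1, 10], shared by the Dijkstra oracle tests."""
    vals = rng.uniform(1.0, 10.0, size=(n_rows, n_cols))
    grid = RasterGrid(values=vals, cell_size=cell_size, origin=(0.0, n_rows * cell_size))
    return ResistanceSurface(grid=grid)
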