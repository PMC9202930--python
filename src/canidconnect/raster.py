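"""Planar raster grids and aligned predictor stacks.

All coordinates are planar meters in a single projected frame; there is no
reprojection machinery.  Grids are row-major, 0-based, origin at the
upper-left corner; the center of cell (row, col) sits at
``origin + ((col + 0.5) * cell_size, -(row + 0.5) * cell_size)``.
Nodata cells are impassable and excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterGrid",
    "PredictorStack",
    "SuitabilitySurface",
    "ResistanceSurface",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Two grids that must share shape, cell size and origin do not."""


@dataclass
class RasterGrid:
    """Single-band planar grid with square cells and a nodata mask.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_rows, n_cols)``.
    cell_size
        Cell edge length in meters (> 0, square cells).
    origin
        ``(x, y)`` planar coordinate of the upper-left corner of the grid.
    nodata_mask
        Boolean array, ``True`` where the cell carries no data.  Defaults to
        all-valid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape must match values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint in meters."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.cell_size,
            x0 + self.n_cols * self.cell_size,
            y0,
        )

    def cell_center(self, row, col):
        """Planar (x, y) of one or many cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 - (row + 0.5) * self.cell_size,
        )

    def index_of(self, x, y):
        """(row, col) of the cell containing planar point(s); no bounds clip."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        # points exactly on the bottom/right edge belong to the last cell
        col = np.where((x == x0 + self.n_cols * self.cell_size), self.n_cols - 1, col)
        row = np.where((y == y0 - self.n_rows * self.cell_size), self.n_rows - 1, row)
        return row, col

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    # -- alignment ------------------------------------------------------
    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def require_aligned(self, other: "RasterGrid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} are not aligned: "
                f"{self.shape}/{self.cell_size}/{self.origin} vs "
                f"{other.shape}/{other.cell_size}/{other.origin}"
            )

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
        )

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]


@dataclass
class PredictorStack:
    """Named, mutually aligned predictor layers."""

    layers: list[RasterGrid]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.names):
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        for name, layer in zip(self.names[1:], self.layers[1:]):
            self.layers[0].require_aligned(layer, f"layers {self.names[0]!r} and {name!r}")

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no layer named {name!r}; have {self.names}") from None

    @property
    def template(self) -> RasterGrid:
        return self.layers[0]

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack(layers=[self[n] for n in names], names=list(names))

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) stacked values."""
        return np.stack([g.values for g in self.layers])

    def values_at_cells(self, rows, cols) -> np.ndarray:
        """(n_points, n_layers) predictor matrix for cell indices."""
        return np.column_stack([g.values[rows, cols] for g in self.layers])


@dataclass
class SuitabilitySurface:
    """Habitat suitability HS in [0, 1] on the non-nodata cells."""

    grid: RasterGrid

    def __post_init__(self) -> None:
        hs = self.grid.valid_values()
        if hs.size and (hs.min() < 0 or hs.max() > 1):
            raise ValueError("habitat suitability must lie in [0, 1]")


@dataclass
class ResistanceSurface:
    """Per-cell movement cost bounded in [r_min, r_max] (default [1, 10])."""

    grid: RasterGrid
    r_min: float = 1.0
    r_max: float = 10.0

    def __post_init__(self) -> None:
        r = self.grid.valid_values()
        if r.size and (r.min() < self.r_min - 1e-9 or r.max() > self.r_max + 1e-9):
            raise ValueError(
                f"resistance must lie in [{self.r_min}, {self.r_max}]"
            )
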