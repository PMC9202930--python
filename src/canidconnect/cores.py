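"""Core habitat patches: extraction, prioritization, and overlap accounting.

Core habitat is any 8-connected patch of cells whose cumulative resistant
kernel strictly exceeds 10% of the landscape maximum.  Patches are ranked
by size and by strength (sum of kernel values); the final priority is the
mean of the two sub-ranks, 1 = best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage, stats
from shapely.geometry import box

from .connectivity import KernelSurface
from .io import rasterize
from .raster import RasterGrid
from .vector import ProtectedAreas, RoadNetwork

__all__ = [
    "CorePatch",
    "extract_cores",
    "rank_cores",
    "protected_overlap",
    "species_overlap",
    "road_in_corridor_length",
    "corridor_surface",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class CorePatch:
    patch_id: int
    cell_count: int
    area_km2: float
    strength: float
    size_rank: float = 0.0
    strength_rank: float = 0.0
    final_rank: float = 0.0
    protected_km2: float = 0.0
    protected_pct: float = 0.0


def extract_cores(kernel: KernelSurface, frac: float = 0.10):
    """Label 8-connected patches above ``frac`` of the kernel maximum.

    Returns the patch list (unranked) and the labeled grid (0 = background).
    """
    grid = kernel.grid
    kmax = grid.values[~grid.nodata_mask].max() if (~grid.nodata_mask).any() else 0.0
    if kmax <= 0:
        raise ValueError("kernel surface has no positive values")
    binary = (grid.values > frac * kmax) & ~grid.nodata_mask
    labels, n = ndimage.label(binary, structure=_EIGHT)
    cell_area_km2 = (grid.cell_size / 1000.0) ** 2
    patches = []
    for pid in range(1, n + 1):
        mask = labels == pid
        cells = int(mask.sum())
        patches.append(
            CorePatch(
                patch_id=pid,
                cell_count=cells,
                area_km2=cells * cell_area_km2,
                strength=float(grid.values[mask].sum()),
            )
        )
    return patches, grid.like(labels.astype(float))


def rank_cores(patches: list[CorePatch]) -> list[CorePatch]:
    """Rank by descending size and strength (average ranks on ties); sort by mean rank."""
    if not patches:
        raise ValueError("no patches to rank")
    areas = np.array([p.area_km2 for p in patches])
    strengths = np.array([p.strength for p in patches])
    size_rank = stats.rankdata(-areas, method="average")
    strength_rank = stats.rankdata(-strengths, method="average")
    for p, sr, tr in zip(patches, size_rank, strength_rank):
        p.size_rank = float(sr)
        p.strength_rank = float(tr)
        p.final_rank = (float(sr) + float(tr)) / 2.0
    return sorted(patches, key=lambda p: (p.final_rank, p.patch_id))


def protected_overlap(surface: RasterGrid, pas: ProtectedAreas):
    """(extent km2, protected km2, protected %) of a binary surface vs protected areas."""
    binary = surface.values > 0
    n_cells = int(binary.sum())
    if n_cells == 0:
        raise ValueError("surface has no positive cells")
    pa_grid = rasterize(pas, surface) if pas.polygons else surface.like(np.zeros(surface.shape))
    inter = int((binary & (pa_grid.values > 0)).sum())
    cell_area = (surface.cell_size / 1000.0) ** 2
    return n_cells * cell_area, inter * cell_area, 100.0 * inter / n_cells


def species_overlap(a: RasterGrid, b: RasterGrid, mode: str = "iou") -> float:
    """Percent overlap of two binary surfaces.

    ``iou``: 100 * |a & b| / |a | b|; ``min``: 100 * |a & b| / min(|a|, |b|).
    """
    a.require_aligned(b, "species surfaces")
    ba, bb = a.values > 0, b.values > 0
    inter = int((ba & bb).sum())
    if mode == "iou":
        denom = int((ba | bb).sum())
    elif mode == "min":
        denom = min(int(ba.sum()), int(bb.sum()))
    else:
        raise ValueError("mode must be 'iou' or 'min'")
    if denom == 0:
        raise ValueError("both surfaces are empty")
    return 100.0 * inter / denom


def road_in_corridor_length(roads: RoadNetwork, corridor: RasterGrid) -> float:
    """Kilometers of road clipped to the corridor cells (exact geometric clip)."""
    rows, cols = np.nonzero(corridor.values > 0)
    if len(rows) == 0 or not roads.polylines:
        return 0.0
    cs = corridor.cell_size
    xmin, _, _, ymax = corridor.extent
    boxes = shapely.box(
        xmin + cols * cs, ymax - (rows + 1) * cs, xmin + (cols + 1) * cs, ymax - rows * cs
    )
    corridor_geom = shapely.unary_union(boxes)
    total_m = sum(line.intersection(corridor_geom).length for line in roads.as_linestrings())
    return total_m / 1000.0


def corridor_surface(density: RasterGrid, dilate_cells: int = 1) -> RasterGrid:
    """Binary corridor = positive path density dilated by ``dilate_cells``."""
    binary = density.values > 0
    if dilate_cells > 0:
        binary = ndimage.binary_dilation(binary, structure=_EIGHT, iterations=dilate_cells)
    binary = binary & ~density.nodata_mask
    return density.like(binary.astype(float))
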