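"""Resistance surfaces, cost distance, resistant kernels and factorial paths.

Movement cost is accumulated on the 8-neighbor grid graph: the edge between
adjacent cells a, b costs ``cell_size * d * (R(a) + R(b)) / 2`` with d = 1
for rook moves and sqrt(2) for diagonals, so one cost unit equals one meter
traversed at resistance 1.  A species with a 50 km dispersal ability through
optimal (resistance 1) habitat therefore exhausts a 50,000 cost-unit
threshold after 50 km.

Resistant kernels are cumulative over sources: each source contributes a
decayed kernel of its cost-distance field, truncated at the dispersal
threshold.  The factorial least-cost-path density counts, per cell, how
many pairwise least-cost paths among all source points traverse it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import RasterGrid, ResistanceSurface, SuitabilitySurface
from .vector import OccurrenceSet

__all__ = [
    "DispersalConfig",
    "KernelSurface",
    "PathDensitySurface",
    "LeastCostPath",
    "hs_to_resistance",
    "cost_distance",
    "resistant_kernel",
    "least_cost_path",
    "factorial_lcp",
]

DEFAULT_THRESHOLDS = (50_000.0, 100_000.0, 150_000.0, 200_000.0)


@dataclass
class DispersalConfig:
    """Dispersal-ability thresholds in cost units (1 unit = 1 m at R = 1)."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be positive and strictly increasing")
        self.thresholds = t


@dataclass
class KernelSurface:
    """Cumulative resistant-kernel values for one dispersal threshold."""

    grid: RasterGrid
    threshold: float
    n_sources: int


@dataclass
class PathDensitySurface:
    """Per-cell count of pairwise least-cost paths."""

    grid: RasterGrid
    n_pairs: int
    n_unreachable: int = 0


@dataclass
class LeastCostPath:
    cells: list[tuple[int, int]]
    cost: float
    reachable: bool = True


def hs_to_resistance(hs: SuitabilitySurface) -> ResistanceSurface:
    """Negative-exponential suitability-to-resistance transform, rescaled to [1, 10].

    raw = 1000 ** (-HS) maps HS in [0, 1] onto [0.001, 1]; linear rescaling
    of that range onto [1, 10] gives R = 1 exactly at HS = 1 and R = 10
    exactly at HS = 0, strictly decreasing in between.
    """
    grid = hs.grid
    h = grid.values
    if ((h < 0) | (h > 1))[~grid.nodata_mask].any():
        raise ValueError("habitat suitability must lie in [0, 1]")
    raw = np.power(1000.0, -h)
    r = 1.0 + 9.0 * (raw - 0.001) / (1.0 - 0.001)
    r = np.clip(r, 1.0, 10.0)  # guard float round-off at the endpoints
    r[grid.nodata_mask] = 0.0
    return ResistanceSurface(grid=grid.like(r))


# ---------------------------------------------------------------------------
# grid graph


def _build_graph(r: ResistanceSurface):
    """Sparse symmetric 8-neighbor cost graph over passable cells."""
    grid = r.grid
    nrow, ncol = grid.shape
    res = grid.values
    passable = ~grid.nodata_mask
    n = nrow * ncol
    rows_i, cols_j, weights = [], [], []
    # offsets: E, S, SE, SW cover all 8-neighbor edges once (graph is symmetric)
    for dr, dc, d in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))):
        r0 = slice(0, nrow - dr)
        r1 = slice(dr, nrow)
        c0 = slice(max(0, -dc), ncol - max(0, dc))
        c1 = slice(max(0, dc), ncol - max(0, -dc))
        ok = passable[r0, c0] & passable[r1, c1]
        w = grid.cell_size * d * 0.5 * (res[r0, c0] + res[r1, c1])
        ii, jj = np.nonzero(ok)
        a = (ii + r0.start) * ncol + (jj + c0.start)
        b = (ii + r1.start) * ncol + (jj + c1.start)
        rows_i.append(a)
        cols_j.append(b)
        weights.append(w[ok])
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(n, n),
    ).tocsr()
    return graph


def _source_nodes(r: ResistanceSurface, sources: OccurrenceSet):
    """Snap source points to cell centers; return node ids with multiplicities."""
    grid = r.grid
    inside = grid.contains(sources.x, sources.y)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} source point(s) fall outside the grid extent")
    rows, cols = grid.index_of(sources.x, sources.y)
    if grid.nodata_mask[rows, cols].any():
        raise ValueError("source point(s) fall on nodata cells")
    nodes = rows * grid.n_cols + cols
    uniq, counts = np.unique(nodes, return_counts=True)
    return nodes, uniq, counts


def cost_distance(
    r: ResistanceSurface, sources: OccurrenceSet, max_cost: float = np.inf
) -> RasterGrid:
    """Minimum accumulated cost from the nearest source to every cell.

    Cells costlier than ``max_cost`` (and unreachable cells) carry +inf.
    """
    if not max_cost > 0:
        raise ValueError("max_cost must be positive")
    graph = _build_graph(r)
    _, uniq, _ = _source_nodes(r, sources)
    limit = max_cost if np.isfinite(max_cost) else np.inf
    dist = dijkstra(graph, directed=False, indices=uniq, min_only=True, limit=limit)
    vals = dist.reshape(r.grid.shape)
    vals = np.where(vals > max_cost, np.inf, vals)
    vals[r.grid.nodata_mask] = np.inf
    return r.grid.like(vals)


def resistant_kernel(
    r: ResistanceSurface,
    sources: OccurrenceSet,
    threshold: float,
    decay: str = "linear",
) -> KernelSurface:
    """Cumulative cost-weighted dispersal kernel truncated at ``threshold``.

    Per source s, K_s(x) = max(0, (t - d(s, x)) / t) under linear decay, or
    exp(-0.5 * (3 d / t)^2) truncated at d >= t under the gaussian option;
    the surface is the source-multiplicity-weighted sum of the K_s.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if decay not in {"linear", "gaussian"}:
        raise ValueError("decay must be 'linear' or 'gaussian'")
    graph = _build_graph(r)
    nodes, uniq, counts = _source_nodes(r, sources)
    dist = dijkstra(graph, directed=False, indices=uniq, limit=threshold)
    dist = np.atleast_2d(dist)
    with np.errstate(invalid="ignore"):
        if decay == "linear":
            k = np.clip((threshold - dist) / threshold, 0.0, None)
        else:
            k = np.exp(-0.5 * (3.0 * dist / threshold) ** 2)
        k[~np.isfinite(dist)] = 0.0
        k[dist >= threshold] = 0.0
    cum = (counts[:, None] * k).sum(axis=0).reshape(r.grid.shape)
    cum[r.grid.nodata_mask] = 0.0
    return KernelSurface(grid=r.grid.like(cum), threshold=float(threshold), n_sources=len(nodes))


def _backtrack(pred_row: np.ndarray, start: int, end: int) -> list[int] | None:
    """Node path start->end from one dijkstra predecessor row, or None."""
    if start == end:
        return [start]
    path = [end]
    node = end
    while node != start:
        node = pred_row[node]
        if node < 0:
            return None
        path.append(node)
    path.reverse()
    return path


def least_cost_path(r: ResistanceSurface, a, b) -> LeastCostPath:
    """Least-cost path between two points (cells), or an explicit unreachable result."""
    src = OccurrenceSet(species="", points=np.asarray([a], dtype=float))
    dst = OccurrenceSet(species="", points=np.asarray([b], dtype=float))
    graph = _build_graph(r)
    _, ua, _ = _source_nodes(r, src)
    _, ub, _ = _source_nodes(r, dst)
    dist, pred = dijkstra(graph, directed=False, indices=ua, return_predecessors=True)
    dist, pred = np.atleast_2d(dist), np.atleast_2d(pred)
    target = int(ub[0])
    if not np.isfinite(dist[0, target]):
        return LeastCostPath(cells=[], cost=np.inf, reachable=False)
    nodes = _backtrack(pred[0], int(ua[0]), target)
    ncol = r.grid.n_cols
    return LeastCostPath(
        cells=[(n // ncol, n % ncol) for n in nodes],
        cost=float(dist[0, target]),
        reachable=True,
    )


def factorial_lcp(r: ResistanceSurface, sources: OccurrenceSet) -> PathDensitySurface:
    """Sum of pairwise least-cost paths among all source points.

    Every unordered pair of source points contributes +1 to each cell on its
    least-cost path; unreachable pairs are skipped and counted.
    """
    if sources.n < 2:
        raise ValueError("factorial least-cost paths need at least 2 sources")
    graph = _build_graph(r)
    nodes, uniq, _ = _source_nodes(r, sources)
    dist, pred = dijkstra(graph, directed=False, indices=uniq, return_predecessors=True)
    dist, pred = np.atleast_2d(dist), np.atleast_2d(pred)
    node_to_row = {int(u): i for i, u in enumerate(uniq)}
    density = np.zeros(r.grid.n_rows * r.grid.n_cols, dtype=float)
    routed = 0
    unreachable = 0
    # cache distinct cell pairs; multiply by point-pair multiplicity
    pair_counts: dict[tuple[int, int], int] = {}
    for i in range(sources.n):
        for j in range(i + 1, sources.n):
            key = (min(nodes[i], nodes[j]), max(nodes[i], nodes[j]))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    for (na, nb), mult in pair_counts.items():
        row = node_to_row[int(na)]
        if not np.isfinite(dist[row, nb]):
            unreachable += mult
            continue
        path = _backtrack(pred[row], int(na), int(nb))
        density[path] += mult
        routed += mult
    vals = density.reshape(r.grid.shape)
    vals[r.grid.nodata_mask] = 0.0
    return PathDensitySurface(grid=r.grid.like(vals), n_pairs=routed, n_unreachable=unreachable)
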