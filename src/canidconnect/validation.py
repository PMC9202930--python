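"""Road sampling, the spatial randomization test, and seasonal road-kill stats.

The randomization test asks whether animals cross roads where predicted
connectivity (the cumulative resistant-kernel surface) is high: the median
kernel value at observed crossing locations is ranked within the
distribution of medians of equally sized random road samples.  Kernel values
are read from the containing cell — the surfaces are per-pixel incidence
functions, so no interpolation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import KernelSurface
from .vector import OccurrenceSet, RoadKillTable, RoadNetwork

__all__ = [
    "RandomizationResult",
    "SeasonalSummary",
    "sample_road_points",
    "randomization_test",
    "kruskal_wallis",
    "seasonal_summary",
]


@dataclass
class RandomizationResult:
    observed_median: float
    null_medians: np.ndarray
    p_value: float
    rank: int
    b: int
    summary: dict  # max/min/median/average of observed crossing kernel values

    def __post_init__(self) -> None:
        self.null_medians = np.asarray(self.null_medians, dtype=float)


@dataclass
class SeasonalSummary:
    totals: dict[str, int]
    grand_total: int
    percentages: dict[str, float]
    stated_total: int | None = None
    total_discrepancy: bool = False


def _cumulative_arclength(roads: RoadNetwork):
    """Flattened segment table: starts, ends, cumulative length offsets."""
    starts, ends = [], []
    for p in roads.polylines:
        starts.append(p[:-1])
        ends.append(p[1:])
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    seg_len = np.hypot(*(ends - starts).T)
    keep = seg_len > 0
    starts, ends, seg_len = starts[keep], ends[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return starts, ends, seg_len, cum


def sample_road_points(roads: RoadNetwork, n: int, seed) -> OccurrenceSet:
    """Sample ``n`` points uniformly by arc length over the whole network."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = roads.total_length
    if total <= 0:
        raise ValueError("road network has zero length")
    rng = np.random.default_rng(seed)
    starts, ends, seg_len, cum = _cumulative_arclength(roads)
    pts = _points_at(starts, ends, seg_len, cum, rng.uniform(0.0, cum[-1], size=n))
    return OccurrenceSet(species="road_sample", points=pts)


def _points_at(starts, ends, seg_len, cum, dist):
    idx = np.clip(np.searchsorted(cum, dist, side="right") - 1, 0, len(seg_len) - 1)
    frac = (dist - cum[idx]) / seg_len[idx]
    return starts[idx] + frac[:, None] * (ends[idx] - starts[idx])


def _kernel_at(kernel: KernelSurface, pts: np.ndarray) -> np.ndarray:
    grid = kernel.grid
    inside = grid.contains(pts[:, 0], pts[:, 1])
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} point(s) fall outside the kernel grid extent")
    rows, cols = grid.index_of(pts[:, 0], pts[:, 1])
    return grid.values[rows, cols]


def randomization_test(
    kernel: KernelSurface,
    crossings: OccurrenceSet,
    roads: RoadNetwork,
    b: int = 10_000,
    seed=0,
) -> RandomizationResult:
    """Rank the median crossing-cell kernel value among ``b`` random road samples.

    p = (1 + #{null medians >= observed}) / (b + 1); rank 1 means the
    observed median exceeds every null median.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if crossings.n == 0:
        raise ValueError("crossings must be non-empty")
    obs_vals = _kernel_at(kernel, crossings.points)
    observed = float(np.median(obs_vals))

    rng = np.random.default_rng(seed)
    starts, ends, seg_len, cum = _cumulative_arclength(roads)
    dists = rng.uniform(0.0, cum[-1], size=(b, crossings.n))
    pts = _points_at(starts, ends, seg_len, cum, dists.ravel())
    null_vals = _kernel_at(kernel, pts).reshape(b, crossings.n)
    null_medians = np.median(null_vals, axis=1)

    n_ge = int((null_medians >= observed).sum())
    p = (1 + n_ge) / (b + 1)
    return RandomizationResult(
        observed_median=observed,
        null_medians=null_medians,
        p_value=p,
        rank=1 + n_ge,
        b=b,
        summary={
            "max": float(obs_vals.max()),
            "min": float(obs_vals.min()),
            "median": observed,
            "average": float(obs_vals.mean()),
        },
    )


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected), degrees of freedom k-1, chi-square p."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    df = len(arrays) - 1
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def seasonal_summary(table: RoadKillTable, stated_total: int | None = None) -> SeasonalSummary:
    """Per-season totals pooled across years, and their percentage of the total.

    ``stated_total`` lets percentages be expressed against an externally
    reported study total; any disagreement with the table's own grand total
    is flagged rather than hidden.
    """
    totals = {s: int(t) for s, t in zip(table.seasons, table.season_totals)}
    grand = table.grand_total
    denom = stated_total if stated_total is not None else grand
    if denom == 0:
        raise ValueError("all-zero road-kill table: percentages undefined")
    pct = {s: 100.0 * t / denom for s, t in totals.items()}
    return SeasonalSummary(
        totals=totals,
        grand_total=grand,
        percentages=pct,
        stated_total=stated_total,
        total_discrepancy=stated_total is not None and stated_total != grand,
    )
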