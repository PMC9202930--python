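"""Synthetic landscapes with the statistical structure the pipeline assumes.

Predictors are spatially autocorrelated Gaussian random fields (smoothed,
standardized white noise); true suitability is logistic-linear in the
predictors so suitability models can genuinely recover structure; roads are
axis-spanning wandering polylines; protected areas are non-overlapping
rectangles; road crossings can be biased toward high-connectivity road
cells; road-kill tables are seasonal Poisson draws.

Every generator is a pure function of its configuration, including the
seed: independent substreams are spawned per generator from the one
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .connectivity import KernelSurface
from .raster import PredictorStack, RasterGrid, SuitabilitySurface
from .validation import _cumulative_arclength, _kernel_at, _points_at
from .vector import OccurrenceSet, ProtectedAreas, RoadKillTable, RoadNetwork

__all__ = [
    "SyntheticConfig",
    "DEFAULT_PREDICTORS",
    "gen_predictors",
    "gen_truth_suitability",
    "gen_occurrences",
    "gen_roads",
    "gen_protected_areas",
    "gen_crossings",
    "gen_roadkill",
]

DEFAULT_PREDICTORS = ("elevation", "roughness", "ndvi", "dist_settlements", "dist_dumps")

# per-generator substream labels, fixed so partial re-runs stay reproducible
_STREAMS = {"predictors": 1, "occurrences": 2, "roads": 3, "pas": 4, "crossings": 5, "roadkill": 6}


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the reference synthetic landscape.

    The 200 x 200 grid of 1 km cells spans a 200 km province-scale extent
    commensurate with the 50-200 km dispersal thresholds; seasonal road-kill
    rates default to the observed per-year seasonal means of the golden
    jackal mortality table (63, 41, 23, 46 kills over 6 years).
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1000.0
    autocorr_range: float = 20_000.0
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS
    effect_weights: tuple[float, ...] = (2.0, -1.5, 1.0, 1.5, -1.0)
    n_presence: int = 150
    n_roads: int = 3
    pa_fraction: float = 0.15
    crossing_bias: float = 2.0
    seasonal_rates: tuple[float, float, float, float] = (63 / 6, 41 / 6, 23 / 6, 46 / 6)
    n_years: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_presence < 1 or self.n_years < 1:
            raise ValueError("counts must be >= 1")
        if self.n_roads < 0:
            raise ValueError("n_roads must be >= 0")
        if not 0 <= self.pa_fraction <= 1:
            raise ValueError("pa_fraction must lie in [0, 1]")
        if any(r < 0 for r in self.seasonal_rates) or len(self.seasonal_rates) != 4:
            raise ValueError("seasonal_rates must be 4 non-negative Poisson means")
        if self.crossing_bias < 0:
            raise ValueError("crossing_bias must be >= 0")
        if len(self.effect_weights) != len(self.predictor_names):
            raise ValueError("one effect weight per predictor required")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def template(self) -> RasterGrid:
        return RasterGrid(
            values=np.zeros((self.n_rows, self.n_cols)),
            cell_size=self.cell_size,
            origin=(0.0, self.n_rows * self.cell_size),
        )


def gen_predictors(cfg: SyntheticConfig) -> PredictorStack:
    """Smoothed, standardized Gaussian-random-field predictor layers."""
    sigma_cells = cfg.autocorr_range / cfg.cell_size
    if cfg.n_rows == 1 and cfg.n_cols == 1 and sigma_cells > 0:
        raise ValueError("cannot impose spatial autocorrelation on a 1x1 grid")
    rng = cfg.rng("predictors")
    template = cfg.template()
    layers = []
    for _ in cfg.predictor_names:
        noise = rng.standard_normal((cfg.n_rows, cfg.n_cols))
        fieldv = gaussian_filter(noise, sigma=sigma_cells) if sigma_cells > 0 else noise
        fieldv = (fieldv - fieldv.mean()) / fieldv.std()
        layers.append(template.like(fieldv))
    return PredictorStack(layers=layers, names=list(cfg.predictor_names))


def gen_truth_suitability(stack: PredictorStack, effect_weights) -> SuitabilitySurface:
    """True suitability HS = logistic(sum_i w_i * layer_i)."""
    w = np.asarray(effect_weights, dtype=float)
    if len(w) != len(stack):
        raise ValueError(f"{len(w)} weights for {len(stack)} layers")
    lin = np.tensordot(w, stack.as_array(), axes=1)
    hs = special.expit(lin)
    grid = stack.template.like(hs)
    grid.values[grid.nodata_mask] = 0.0
    return SuitabilitySurface(grid=grid)


def gen_occurrences(hs: SuitabilitySurface, n: int, seed, species: str = "synthetic") -> OccurrenceSet:
    """Presence points: cell chosen with probability proportional to HS, jittered within the cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = hs.grid
    weights = np.where(grid.nodata_mask, 0.0, grid.values).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability surface has no positive-weight cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n, p=weights / total)
    rows, cols = np.divmod(cells, grid.n_cols)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    cx, cy = grid.cell_center(rows, cols)
    pts = np.column_stack([cx + jitter[:, 0] * grid.cell_size, cy + jitter[:, 1] * grid.cell_size])
    return OccurrenceSet(species=species, points=pts)


def gen_roads(cfg: SyntheticConfig) -> RoadNetwork:
    """Axis-spanning polylines with smoothed random perpendicular wander."""
    rng = cfg.rng("roads")
    template = cfg.template()
    xmin, ymin, xmax, ymax = template.extent
    polylines = []
    for i in range(cfg.n_roads):
        horizontal = i % 2 == 0
        n_span = (cfg.n_cols if horizontal else cfg.n_rows) + 1
        along = np.linspace(xmin if horizontal else ymin, xmax if horizontal else ymax, n_span)
        width = (ymax - ymin) if horizontal else (xmax - xmin)
        wander = np.cumsum(rng.normal(0.0, cfg.cell_size, size=n_span))
        wander = gaussian_filter(wander, sigma=5, mode="nearest")
        center = rng.uniform(0.25, 0.75) * width
        perp = np.clip(center + wander - wander.mean(), 0.02 * width, 0.98 * width)
        if horizontal:
            polylines.append(np.column_stack([along, ymin + perp]))
        else:
            polylines.append(np.column_stack([xmin + perp, along]))
    return RoadNetwork(polylines=polylines)


def gen_protected_areas(cfg: SyntheticConfig, max_retries: int = 2000) -> ProtectedAreas:
    """Non-overlapping rectangles totaling about ``pa_fraction`` of the landscape."""
    template = cfg.template()
    xmin, ymin, xmax, ymax = template.extent
    total_area = (xmax - xmin) * (ymax - ymin)
    target = cfg.pa_fraction * total_area
    if target == 0:
        return ProtectedAreas(polygons=[], categories=[])
    rng = cfg.rng("pas")
    placed: list = []
    cats: list[str] = []
    area = 0.0
    retries = 0
    cat_cycle = ("WR", "CA", "NHA")
    while area < 0.95 * target:
        if retries > max_retries:
            raise RuntimeError(
                f"could not place protected areas to {cfg.pa_fraction:.0%} without overlap"
            )
        w = rng.uniform(0.08, 0.25) * (xmax - xmin)
        h = rng.uniform(0.08, 0.25) * (ymax - ymin)
        if w * h > 1.1 * target - area:  # do not overshoot the target band
            retries += 1
            continue
        x0 = rng.uniform(xmin, xmax - w)
        y0 = rng.uniform(ymin, ymax - h)
        rect = box(x0, y0, x0 + w, y0 + h)
        if any(rect.intersects(p) for p in placed):
            retries += 1
            continue
        placed.append(rect)
        cats.append(cat_cycle[(len(placed) - 1) % 3])
        area += w * h
    return ProtectedAreas(polygons=placed, categories=cats)


def gen_crossings(
    kernel: KernelSurface,
    roads: RoadNetwork,
    n: int,
    crossing_bias: float,
    seed,
    species: str = "synthetic",
) -> OccurrenceSet:
    """Road points with selection weight proportional to (kernel at cell) ** bias.

    bias = 0 reduces to length-uniform road sampling.
    """
    if n == 0:
        return OccurrenceSet(species=species, points=np.empty((0, 2)))
    rng = np.random.default_rng(seed)
    starts, ends, seg_len, cum = _cumulative_arclength(roads)
    m = max(2000, 20 * n)
    cand = _points_at(starts, ends, seg_len, cum, rng.uniform(0.0, cum[-1], size=m))
    if crossing_bias == 0:
        chosen = rng.choice(m, size=n)
    else:
        kv = _kernel_at(kernel, cand)
        if kv.max() <= 0:
            raise ValueError("kernel is zero along the road network; bias undefined")
        w = kv**crossing_bias
        chosen = rng.choice(m, size=n, p=w / w.sum())
    return OccurrenceSet(species=species, points=cand[chosen])


def gen_roadkill(cfg: SyntheticConfig, species: str = "synthetic") -> RoadKillTable:
    """Season x year counts, independent Poisson per season."""
    rng = cfg.rng("roadkill")
    rates = np.asarray(cfg.seasonal_rates, dtype=float)
    counts = rng.poisson(rates[:, None], size=(4, cfg.n_years))
    return RoadKillTable(species=species, counts=counts, years=list(range(2013, 2013 + cfg.n_years)))
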