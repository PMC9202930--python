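# Methods

`canidconnect` implements a habitat-suitability → resistance → connectivity
→ prioritization → validation workflow for wide-ranging carnivores on
raster landscapes, together with a synthetic-landscape generator that makes
every stage testable without geodata downloads. This note records the
models, the numerical choices, and what the synthetic tests do and do not
demonstrate.

## Coordinate and raster conventions

All coordinates are planar meters in a single projected frame; the package
performs no reprojection. Rasters are row-major, 0-based, origin at the
upper-left corner, square cells; the center of cell (row, col) is at
`origin + ((col + 0.5)·s, −(row + 0.5)·s)` for cell size `s`. Two grids
must share shape, cell size and origin for any surface-on-surface
operation; misalignment raises rather than resampling silently. Nodata
cells are impassable and excluded from every statistic. Rasters are stored
as ESRI ASCII grids (plain text, GIS-interchangeable); vectors as GeoJSON;
points and road-kill records as headed CSV.

## Suitability ensemble

Predictors are screened for collinearity by pairwise Pearson correlation at
the conventional |r| < 0.7 threshold; when a pair violates, the layer later
in the priority order is dropped. Sampling bias in occurrence data can be
probed with a global Moran's I on per-cell presence counts over the
occupied cells, with inverse-distance row-standardized weights,
expectation −1/(n−1), and a normal-approximation z and two-sided p. When
every occupied cell holds exactly one point the statistic is undefined
(zero variance) and the function says so rather than returning a number.

Member suitability models are pluggable learners behind one contract:
fit on presence/background predictor vectors, return scores in [0, 1].
The reference registry holds five members — `glm` (logistic regression),
`mars` (piecewise-linear regression-spline basis + logistic regression),
`maxent` (degree-2 polynomial features + logistic regression, the standard
exponential-family approximation), `rf` (random forest) and `gbm`
(histogram gradient boosting) — plus an explicit `bagged_trees` learner.
All are scikit-learn estimators seeded for determinism. Background points
default to 10× the presences, uniform over valid cells; evaluation uses a
seeded 80/20 presence/background split with metrics on the held-out fold.

Discrimination is scored by rank-statistic (Mann–Whitney) AUC and by TSS
maximized over all observed score thresholds, with the customary verbal
grades (AUC > 0.9 excellent, 0.8–0.9 good, 0.7–0.8 moderate, below poor;
TSS > 0.75 excellent, 0.4–0.75 good, < 0.4 poor). The ensemble is a
weighted average of member scores with weights proportional to held-out
AUC (configurable to TSS; members below a cutoff are dropped, default
cutoff 0 retains all). Variable contribution is permutation importance,
`1 − r(intact predictions, permuted predictions)` averaged over
permutations and clipped to [0, 1]; response curves are partial-dependence
means over an observed-range grid. A binary suitability map uses the
median ensemble score at the presence cells as threshold.

## Resistance and connectivity

Suitability maps to movement resistance through the negative exponential
`raw = 1000^(−HS)` followed by linear rescaling of [0.001, 1] onto
[10, 1], so R = 1 exactly at HS = 1 and R = 10 exactly at HS = 0,
strictly decreasing in between.

Cost distance runs on the 8-neighbor grid graph with edge weight
`s·d·(R(a)+R(b))/2`, d = 1 for rook moves and √2 for diagonals: one cost
unit is one meter traversed at resistance 1, so a 50 km transect of
resistance-1 cells accumulates exactly 50,000 cost units — the anchor that
ties the dispersal thresholds (50,000–200,000 units) to 50–200 km of
movement through optimal habitat. Shortest paths use Dijkstra's algorithm
(scipy's compiled sparse-graph implementation). Path reconstruction uses
the predecessor matrix, which is deterministic for a fixed graph; where
equal-cost paths exist the realized path is one canonical member of the
tie set and the cost is tie-independent. Sources are occurrence points
snapped to cell centers; coincident sources are allowed and summed.

The cumulative resistant kernel around the sources is, per source s,
`K_s(x) = max(0, (t − d(s,x))/t)` under the default linear decay with
compact support at the dispersal threshold t (a truncated Gaussian option
is provided), summed over sources. The factorial least-cost-path density
adds 1 to every cell of the least-cost path of each unordered source pair;
unreachable pairs are skipped and counted. The corridor surface for
overlap and road-length accounting is the positive path density dilated by
one cell — the path itself has no physical width, and the one-cell buffer
is the minimal explicit choice (configurable).

## Cores, ranking, metrics

Core habitat is any 8-connected patch of cells whose kernel value strictly
exceeds 10% of the landscape maximum (boundary-equal cells excluded).
Patches are ranked by descending area and by descending strength (sum of
kernel values), ties receiving average ranks; the final priority is the
mean of the two sub-ranks. Protected-area overlap is computed on the
rasterized polygons; species overlap defaults to intersection-over-union
with an intersection-over-minimum option. Road length inside corridors is
an exact geometric clip of the polylines against the corridor cell boxes.

Class-level fragmentation metrics on the binarized kernel: NP (8-connected
patch count), PLAND and LPI (percentages of the landscape), and GYRATE_AM —
the area-weighted mean of per-patch radii of gyration, each the mean
distance from a cell center to the patch centroid, reported in meters
(single-cell patches have gyrate 0). The correlation-length column of the
output tables is GYRATE_AM in meters.

## Validation statistics

The spatial randomization test compares the median kernel value at the
observed road-crossing cells against the distribution of medians of B
equally sized length-uniform random road samples. Kernel values are read
from the containing cell without interpolation. The p-value uses the
add-one convention `p = (1 + #{null ≥ observed})/(B + 1)`, so it is never
zero, and the rank (1 = observed exceeds all nulls) is reported with the
max/min/median/mean of the observed crossing values. B defaults to 10,000
(2,000 in the reference pipeline run) and is fully configurable.

Seasonal road-kill counts are summarized as per-season totals pooled
across years and percentages of the grand total; percentages can instead
be expressed against an externally stated study total, and any
disagreement between the two is flagged rather than hidden. Seasonal
differences are tested with a tie-corrected Kruskal–Wallis H on the
per-year seasonal counts, df = k − 1 (3 for four seasons); an all-constant
table returns H = 0, p = 1.

The bundled Markazi Province 2013–2018 mortality table stores the per-cell
counts only; totals are always derived. For the grey wolf the cell counts
sum to 103 — the published marginal totals of that table are internally
inconsistent with its cells, which is why the summary derives everything
from cells and exposes the stated-total comparison.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes,
not any real geography. Predictors are Gaussian random fields (white noise
smoothed with a Gaussian kernel of width `autocorr_range`, then
standardized), giving tunable Moran's I. True suitability is
logistic-linear in the predictors so suitability models can genuinely
recover structure. Presences sample cells with probability proportional to
suitability and jitter uniformly within the cell. Roads are axis-spanning
polylines with smoothed perpendicular wander, so road cells span both
high- and low-connectivity regions; protected areas are non-overlapping
random rectangles hitting a target landscape fraction within ±20%.
Crossing points sample road locations with weight `kernel^β`; β = 0 is
exactly length-uniform sampling. Road-kill tables are independent seasonal
Poisson draws. Every generator is a pure function of its configuration
including the seed.

Reference conditions: a 200 × 200 grid of 1 km cells (a 200 km extent
commensurate with the 50–200 km dispersal thresholds), predictor
autocorrelation range 20 km, 150 presences per species, 3 roads, 15%
protected fraction, seasonal Poisson means set to the observed per-year
seasonal means of the golden jackal mortality table, 6 years. These sizes
keep a full two-species run (ensemble fits, four kernels, ~11,000
factorial paths and a B = 2,000 randomization test per species) around
twenty seconds while exercising every code path at meaningful scale.

A structural limitation worth stating plainly: with zero-intercept
logistic-linear truth on standardized symmetric fields, presences sampled
proportional to suitability, and a uniform background, the distribution of
true suitability is symmetric about 0.5, which bounds the
presence-vs-background AUC of *any* score — including the true suitability
itself — near 0.75 (the bound is `2·E[HS·F(HS)] ≤ 0.75` for symmetric HS,
approached in the near-binary limit). Held-out ensemble AUCs of ~0.65–0.74
on these landscapes therefore indicate near-ceiling recovery, not weak
models; tests of model quality here rely on sign/driver recovery and on
the ordering of importances rather than on absolute AUC. Real SDM studies
escape this bound because real occurrence data are closer to thresholded
presence with prevalence well below one half.

What passing synthetic tests do not show: robustness to predictor
measurement error, spatially biased sampling effort, non-stationary
autocorrelation, or real road-network topology; none of these are
emulated.

## Pipeline and reproducibility

The end-to-end run derives one named integer seed per stage (SHA-256 of
`master_seed:stage:index`, reduced below 2^31) so partial re-runs stay
reproducible, validates its configuration against known keys with
did-you-mean suggestions, logs per-stage timing, and writes a manifest of
SHA-256 content hashes; identical configuration and seed produce
byte-identical artifacts. A stage failure aborts with the stage name. The
output tables are: per-member and ensemble evaluation; per-threshold core
extent / protected extent / % protected; corridor extent, % protected and
road-kilometers crossing corridors; per-threshold NP/LPI/PLAND/correlation
length; per-threshold randomization results; seasonal road-kill summaries
for both the synthetic and the bundled observed tables.
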