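"""Suitability modelling: predictor screening, member models, ensembles.

Member suitability models are pluggable learners behind one contract — fit
on presence/background predictor vectors, predict a score in [0, 1].  The
reference registry holds five members: two regression-based (``glm``,
``mars``-style regression splines) and three machine-learning members
(``maxent``-style exponential-family logistic with quadratic features,
``rf`` random forest, ``gbm`` gradient boosting), plus an explicit
``bagged_trees`` learner.  The ensemble is a score-weighted average of the
retained members, weighted by held-out AUC (or TSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    BaggingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .raster import PredictorStack, RasterGrid, SuitabilitySurface
from .vector import OccurrenceSet

__all__ = [
    "ModelEval",
    "EnsembleModel",
    "MoransResult",
    "SDMMember",
    "MEMBER_REGISTRY",
    "REFERENCE_MEMBERS",
    "pearson_screen",
    "global_morans_i",
    "sample_background",
    "predictor_matrix",
    "fit_member",
    "evaluate_model",
    "build_ensemble",
    "predict_surface",
    "variable_importance",
    "partial_dependence",
    "binarize_at_presence_median",
]


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ModelEval:
    """Discrimination scores and their customary verbal grades."""

    auc: float
    tss: float
    auc_grade: str
    tss_grade: str


def _auc_grade(auc: float) -> str:
    if auc > 0.9:
        return "excellent"
    if auc > 0.8:
        return "good"
    if auc > 0.7:
        return "moderate"
    return "poor"


def _tss_grade(tss: float) -> str:
    if tss > 0.75:
        return "excellent"
    if tss >= 0.4:
        return "good"
    return "poor"


def evaluate_model(scores, labels) -> ModelEval:
    """Rank-statistic AUC and threshold-maximized TSS with verbal grades.

    AUC is the Mann-Whitney probability that a random presence outscores a
    random background point; TSS is max over observed score thresholds of
    sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to evaluate a model")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    # TSS threshold sweep: predict presence when score >= threshold
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    sens = tp / n1
    spec = 1 - fp / n0
    # evaluate only at the last index of each tied score block
    sorted_scores = scores[order]
    block_end = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tss = float(max(0.0, (sens + spec - 1)[block_end].max()))
    return ModelEval(auc=float(auc), tss=tss, auc_grade=_auc_grade(auc), tss_grade=_tss_grade(tss))


# ---------------------------------------------------------------------------
# spatial screening


@dataclass
class MoransResult:
    i_stat: float
    expected_i: float
    z: float
    p: float
    n: int


def _morans_i(values: np.ndarray, coords: np.ndarray) -> MoransResult:
    """Global Moran's I with inverse-distance, row-standardized weights."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 spatial units")
    d = np.hypot(
        coords[:, None, 0] - coords[None, :, 0], coords[:, None, 1] - coords[None, :, 1]
    )
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)

    z_dev = x - x.mean()
    denom = (z_dev**2).sum()
    if denom == 0:
        raise ValueError("values are constant; Moran's I undefined")
    s0 = w.sum()
    i_stat = (n / s0) * (z_dev @ w @ z_dev) / denom
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z = (i_stat - e_i) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return MoransResult(i_stat=float(i_stat), expected_i=e_i, z=float(z), p=float(p), n=n)


def global_morans_i(points: OccurrenceSet, template: RasterGrid) -> MoransResult:
    """Moran's I of per-cell presence counts over the occupied cells."""
    inside = template.contains(points.x, points.y)
    if not inside.all():
        raise ValueError("presence points fall outside the template extent")
    rows, cols = template.index_of(points.x, points.y)
    nodes, counts = np.unique(rows * template.n_cols + cols, return_counts=True)
    if len(nodes) < 3:
        raise ValueError("need at least 3 occupied cells for Moran's I")
    r, c = np.divmod(nodes, template.n_cols)
    cx, cy = template.cell_center(r, c)
    return _morans_i(counts.astype(float), np.column_stack([cx, cy]))


def pearson_screen(
    stack: PredictorStack, threshold: float = 0.7, priority: list[str] | None = None
) -> list[str]:
    """Drop collinear layers: retain a layer only if |r| < threshold vs all kept.

    When a pair violates the threshold the layer later in ``priority``
    (default: stack order) is dropped.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers to screen")
    priority = list(priority) if priority is not None else list(stack.names)
    valid = ~np.logical_or.reduce([g.nodata_mask for g in stack.layers])
    data = {name: stack[name].values[valid] for name in stack.names}
    for name, v in data.items():
        if np.std(v) == 0:
            raise ValueError(f"layer {name!r} is constant; correlation undefined")
    kept: list[str] = []
    for name in priority:
        if all(abs(np.corrcoef(data[name], data[k])[0, 1]) < threshold for k in kept):
            kept.append(name)
    return kept


# ---------------------------------------------------------------------------
# members


@dataclass
class SDMMember:
    """A fitted member: opaque predictor mapping predictor vectors to [0, 1]."""

    kind: str
    estimator: object
    layer_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _make_glm(seed):
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))


def _make_mars(seed):
    return make_pipeline(
        StandardScaler(),
        SplineTransformer(n_knots=5, degree=1),
        LogisticRegression(max_iter=1000),
    )


def _make_maxent(seed):
    return make_pipeline(
        StandardScaler(),
        PolynomialFeatures(degree=2, include_bias=False),
        LogisticRegression(max_iter=2000),
    )


def _make_rf(seed):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def _make_gbm(seed):
    return HistGradientBoostingClassifier(random_state=seed)


def _make_bagged_trees(seed):
    return BaggingClassifier(DecisionTreeClassifier(), n_estimators=50, random_state=seed)


MEMBER_REGISTRY = {
    "glm": _make_glm,
    "mars": _make_mars,
    "maxent": _make_maxent,
    "rf": _make_rf,
    "gbm": _make_gbm,
    "bagged_trees": _make_bagged_trees,
}

REFERENCE_MEMBERS = ("glm", "mars", "maxent", "rf", "gbm")


def sample_background(template: RasterGrid, n: int, seed) -> OccurrenceSet:
    """Background (pseudo-absence) points uniform over non-nodata cells."""
    valid = np.flatnonzero(~template.nodata_mask.ravel())
    if valid.size == 0:
        raise ValueError("template has no valid cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(valid, size=n)
    rows, cols = np.divmod(cells, template.n_cols)
    cx, cy = template.cell_center(rows, cols)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * template.cell_size
    return OccurrenceSet(species="background", points=np.column_stack([cx, cy]) + jitter)


def predictor_matrix(stack: PredictorStack, points: OccurrenceSet) -> np.ndarray:
    """(n_points, n_layers) predictor values at each point's containing cell."""
    template = stack.template
    inside = template.contains(points.x, points.y)
    if not inside.all():
        raise ValueError("points fall outside the predictor stack extent")
    rows, cols = template.index_of(points.x, points.y)
    return stack.values_at_cells(rows, cols)


def fit_member(
    kind: str,
    presences: OccurrenceSet,
    background: OccurrenceSet,
    stack: PredictorStack,
    seed: int = 0,
) -> SDMMember:
    """Fit one registry member on presence-vs-background predictor vectors."""
    if kind not in MEMBER_REGISTRY:
        raise ValueError(
            f"unknown member kind {kind!r}; registered kinds: {sorted(MEMBER_REGISTRY)}"
        )
    if presences.n < 10 or background.n < 10:
        raise ValueError("need at least 10 presence and 10 background points")
    X = np.vstack([predictor_matrix(stack, presences), predictor_matrix(stack, background)])
    y = np.r_[np.ones(presences.n), np.zeros(background.n)]
    est = MEMBER_REGISTRY[kind](int(seed))
    est.fit(X, y)
    return SDMMember(kind=kind, estimator=est, layer_names=list(stack.names))


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    members: list[SDMMember]
    member_evals: list[ModelEval]
    weights: np.ndarray
    metric: str = "auc"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return np.clip(self.weights @ preds, 0.0, 1.0)


def build_ensemble(
    members: list[SDMMember],
    evals: list[ModelEval],
    metric: str = "auc",
    cutoff: float = 0.0,
    stack: PredictorStack | None = None,
):
    """Score-weighted ensemble of the members whose metric clears ``cutoff``.

    Returns the EnsembleModel, and the ensemble SuitabilitySurface when a
    predictor stack is supplied.
    """
    if metric not in {"auc", "tss"}:
        raise ValueError("metric must be 'auc' or 'tss'")
    scores = np.array([getattr(e, metric) for e in evals], dtype=float)
    keep = scores >= cutoff
    if not keep.any():
        raise ValueError(f"no member has {metric} >= {cutoff}")
    kept_scores = np.clip(scores[keep], 0.0, None)
    if kept_scores.sum() == 0:
        kept_scores = np.ones_like(kept_scores)
    weights = kept_scores / kept_scores.sum()
    ens = EnsembleModel(
        members=[m for m, k in zip(members, keep) if k],
        member_evals=[e for e, k in zip(evals, keep) if k],
        weights=weights,
        metric=metric,
    )
    surface = predict_surface(ens, stack) if stack is not None else None
    return ens, surface


def predict_surface(model, stack: PredictorStack) -> SuitabilitySurface:
    """Evaluate a member or ensemble on every valid cell of the stack."""
    template = stack.template
    valid = ~template.nodata_mask
    rows, cols = np.nonzero(valid)
    scores = model.predict(stack.values_at_cells(rows, cols))
    vals = np.zeros(template.shape)
    vals[rows, cols] = np.clip(scores, 0.0, 1.0)
    return SuitabilitySurface(grid=template.like(vals))


# ---------------------------------------------------------------------------
# interpretation


def variable_importance(
    model, stack: PredictorStack, X: np.ndarray, n_perm: int = 5, seed: int = 0
) -> dict[str, float]:
    """Permutation importance: 1 - r(intact predictions, permuted predictions).

    Averaged over ``n_perm`` permutations per layer and clipped to [0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    base = model.predict(X)
    if np.std(base) == 0:
        warnings.warn("model predictions are constant; importances are all 0", stacklevel=2)
        return {name: 0.0 for name in stack.names}
    out = {}
    for j, name in enumerate(stack.names):
        drops = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = model.predict(Xp)
            r = np.corrcoef(base, perm)[0, 1] if np.std(perm) > 0 else 0.0
            drops.append(1.0 - r)
        out[name] = float(np.clip(np.mean(drops), 0.0, 1.0))
    return out


def partial_dependence(
    model,
    stack: PredictorStack,
    variable: str,
    n_grid: int = 25,
    n_sample: int = 1000,
    seed: int = 0,
):
    """Mean model response over a grid of one variable, others at observations."""
    if variable not in stack.names:
        raise KeyError(f"unknown variable {variable!r}; have {stack.names}")
    j = stack.names.index(variable)
    template = stack.template
    rows, cols = np.nonzero(~template.nodata_mask)
    rng = np.random.default_rng(seed)
    take = rng.choice(len(rows), size=min(n_sample, len(rows)), replace=False)
    X = stack.values_at_cells(rows[take], cols[take])
    vmin, vmax = stack[variable].valid_values().min(), stack[variable].valid_values().max()
    grid = np.linspace(vmin, vmax, n_grid)
    response = np.empty(n_grid)
    for i, v in enumerate(grid):
        Xi = X.copy()
        Xi[:, j] = v
        response[i] = model.predict(Xi).mean()
    return grid, response


def binarize_at_presence_median(hs: SuitabilitySurface, presences: OccurrenceSet):
    """Binary suitability at the presence-median threshold, plus % suitable.

    The threshold is the median HS over the presence cells; cells at or
    above it are classed suitable.
    """
    grid = hs.grid
    inside = grid.contains(presences.x, presences.y)
    rows, cols = grid.index_of(presences.x[inside], presences.y[inside])
    ok = ~grid.nodata_mask[rows, cols]
    if not ok.any():
        raise ValueError("no presence point falls on a valid cell")
    threshold = float(np.median(grid.values[rows[ok], cols[ok]]))
    binary = np.where((grid.values >= threshold) & ~grid.nodata_mask, 1.0, 0.0)
    n_valid = int((~grid.nodata_mask).sum())
    pct = 100.0 * binary.sum() / n_valid
    return grid.like(binary), float(pct), threshold
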