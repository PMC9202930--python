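import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canidconnect import sdm, synth
from canidconnect.raster import PredictorStack, RasterGrid, SuitabilitySurface
from canidconnect.vector import OccurrenceSet


def make_stack(arrays, names, cell_size=100.0):
    n_rows = arrays[0].shape[0]
    layers = [
        RasterGrid(values=a, cell_size=cell_size, origin=(0, n_rows * cell_size)) for a in arrays
    ]
    return PredictorStack(layers=layers, names=names)


def tss_oracle(scores, labels):
    """Brute-force threshold sweep for max(sensitivity + specificity - 1)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = 0.0
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestEvaluateModel:
    def test_perfect_separation(self):
        ev = sdm.evaluate_model([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ev.auc == 1.0
        assert ev.tss == 1.0
        assert ev.auc_grade == "excellent"
        assert ev.tss_grade == "excellent"

    def test_uninformative_constant_scores(self):
        ev = sdm.evaluate_model([0.5] * 10, [1] * 5 + [0] * 5)
        assert ev.auc == 0.5
        assert ev.tss == 0.0
        assert ev.tss_grade == "poor"

    @pytest.mark.parametrize(
        "auc,grade",
        [(0.980, "excellent"), (0.85, "good"), (0.75, "moderate"), (0.65, "poor")],
    )
    def test_auc_grade_cutpoints(self, auc, grade):
        assert sdm._auc_grade(auc) == grade

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sdm.evaluate_model([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tss_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # deliberate ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        ev = sdm.evaluate_model(scores, labels)
        assert ev.tss == pytest.approx(tss_oracle(scores, labels), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        a = sdm.evaluate_model(scores, labels).auc
        b = sdm.evaluate_model(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestPearsonScreen:
    def test_exact_copy_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((20, 20))
        stack = make_stack([a, a.copy(), rng.standard_normal((20, 20))], ["a", "a_copy", "b"])
        kept = sdm.pearson_screen(stack)
        assert kept == ["a", "b"]

    def test_independent_noise_all_kept(self):
        rng = np.random.default_rng(1)
        arrays = [rng.standard_normal((100, 100)) for _ in range(4)]
        stack = make_stack(arrays, list("abcd"))
        assert sdm.pearson_screen(stack) == list("abcd")

    def test_derived_terrain_layers_collinear(self):
        # slope and roughness derived from one synthetic elevation field
        cfg = synth.SyntheticConfig(n_rows=40, n_cols=40, autocorr_range=5000.0, seed=2)
        dem = synth.gen_predictors(cfg).layers[0].values
        gy, gx = np.gradient(dem)
        slope = np.hypot(gx, gy)
        roughness = np.hypot(*np.gradient(dem))  # same construction: near-perfect correlation
        stack = make_stack([dem, slope, roughness], ["elevation", "slope", "roughness"])
        kept = sdm.pearson_screen(stack)
        assert "slope" in kept and "roughness" not in kept

    def test_constant_layer_named_in_error(self):
        stack = make_stack([np.zeros((5, 5)), np.ones((5, 5))], ["flat", "one"])
        with pytest.raises(ValueError, match="flat"):
            sdm.pearson_screen(stack)


class TestMoransI:
    def test_expected_value_is_minus_one_over_n_minus_one(self, template):
        rng = np.random.default_rng(0)
        # 101 occupied cells with varying point multiplicities
        big = RasterGrid(values=np.zeros((50, 50)), cell_size=100.0, origin=(0, 5000))
        cells = rng.choice(2500, size=101, replace=False)
        rows, cols = np.divmod(cells, 50)
        mult = rng.integers(1, 4, size=101)
        cx, cy = big.cell_center(np.repeat(rows, mult), np.repeat(cols, mult))
        occ = OccurrenceSet(species="t", points=np.column_stack([cx, cy]))
        res = sdm.global_morans_i(occ, big)
        assert res.expected_i == pytest.approx(-0.01)

    def test_uniform_scatter_not_significant(self):
        big = RasterGrid(values=np.zeros((50, 50)), cell_size=100.0, origin=(0, 5000))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.column_stack([rng.uniform(0, 5000, 500), rng.uniform(0, 5000, 500)])
            res = sdm.global_morans_i(OccurrenceSet(species="t", points=pts), big)
            hits += abs(res.z) < 3
        assert hits >= 17

    def test_tight_cluster_significant_positive(self):
        big = RasterGrid(values=np.zeros((50, 50)), cell_size=100.0, origin=(0, 5000))
        rng = np.random.default_rng(5)
        # heavy multi-cell cluster plus sparse background occupancy
        cluster = rng.normal(2500, 120, size=(400, 2))
        sparse = np.column_stack([rng.uniform(0, 5000, 30), rng.uniform(0, 5000, 30)])
        occ = OccurrenceSet(species="t", points=np.vstack([cluster, sparse]))
        res = sdm.global_morans_i(occ, big)
        assert res.i_stat > res.expected_i
        assert res.p < 0.05

    def test_single_cell_rejected(self, template):
        occ = OccurrenceSet(species="t", points=[[50.0, 950.0]] * 5)
        with pytest.raises(ValueError):
            sdm.global_morans_i(occ, template)


@pytest.fixture(scope="module")
def toy_separable():
    """Linearly separable presence/background on a 2-layer stack."""
    rng = np.random.default_rng(42)
    layer1 = np.linspace(-3, 3, 40)[None, :].repeat(40, axis=0)
    layer2 = rng.standard_normal((40, 40))
    stack = make_stack([layer1, layer2], ["driver", "noise"], cell_size=100.0)
    grid = stack.template
    rows = rng.integers(0, 40, size=60)
    pres_cols = rng.integers(28, 40, size=60)  # layer1 > 1
    bg_cols = rng.integers(0, 12, size=60)  # layer1 < -1
    px, py = grid.cell_center(rows, pres_cols)
    bx, by = grid.cell_center(rows, bg_cols)
    presences = OccurrenceSet(species="p", points=np.column_stack([px, py]))
    background = OccurrenceSet(species="b", points=np.column_stack([bx, by]))
    return stack, presences, background


class TestFitMember:
    def test_logistic_member_separates_toy(self, toy_separable):
        stack, presences, background = toy_separable
        member = sdm.fit_member("glm", presences, background, stack, seed=0)
        X = np.vstack(
            [sdm.predictor_matrix(stack, presences), sdm.predictor_matrix(stack, background)]
        )
        y = np.r_[np.ones(presences.n), np.zeros(background.n)]
        assert sdm.evaluate_model(member.predict(X), y).auc == 1.0

    def test_all_reference_members_fit_and_bound_scores(self, toy_separable):
        stack, presences, background = toy_separable
        X = sdm.predictor_matrix(stack, presences)
        for kind in sdm.REFERENCE_MEMBERS + ("bagged_trees",):
            member = sdm.fit_member(kind, presences, background, stack, seed=1)
            scores = member.predict(X)
            assert np.all((scores >= 0) & (scores <= 1))

    def test_unknown_kind_lists_registry(self, toy_separable):
        stack, presences, background = toy_separable
        with pytest.raises(ValueError, match="glm"):
            sdm.fit_member("boosted_ferns", presences, background, stack)

    def test_too_few_points_rejected(self, toy_separable):
        stack, presences, background = toy_separable
        few = OccurrenceSet(species="p", points=presences.points[:5])
        with pytest.raises(ValueError):
            sdm.fit_member("glm", few, background, stack)

    def test_sign_recovery_from_synthetic_truth(self):
        wins = 0
        for seed in range(10):
            cfg = synth.SyntheticConfig(
                n_rows=40, n_cols=40, autocorr_range=4000.0, effect_weights=(2.0, 0, 0, 0, 0), seed=seed
            )
            stack = synth.gen_predictors(cfg)
            truth = synth.gen_truth_suitability(stack, cfg.effect_weights)
            presences = synth.gen_occurrences(truth, 200, seed=seed + 500)
            background = sdm.sample_background(stack.template, 1000, seed=seed + 900)
            member = sdm.fit_member("glm", presences, background, stack, seed=seed)
            coef = member.estimator[-1].coef_[0][0]
            wins += coef > 0
        assert wins >= 9


class TestEnsemble:
    class _Const:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)

    def _eval(self, auc):
        return sdm.ModelEval(auc=auc, tss=2 * auc - 1, auc_grade="", tss_grade="")

    def test_weighted_average_of_two_members(self):
        members = [self._Const(0.8), self._Const(0.5)]
        ens, _ = sdm.build_ensemble(members, [self._eval(0.9), self._eval(0.6)])
        assert ens.predict(np.zeros((1, 1)))[0] == pytest.approx((0.9 * 0.8 + 0.6 * 0.5) / 1.5)

    def test_single_member_identity(self):
        ens, _ = sdm.build_ensemble([self._Const(0.37)], [self._eval(0.8)])
        assert ens.predict(np.zeros((3, 1)))[0] == pytest.approx(0.37)

    def test_equal_scores_give_simple_mean(self):
        members = [self._Const(v) for v in (0.2, 0.4, 0.9)]
        ens, _ = sdm.build_ensemble(members, [self._eval(0.7)] * 3)
        assert ens.predict(np.zeros((1, 1)))[0] == pytest.approx(0.5)

    def test_cutoff_filters_members(self):
        members = [self._Const(0.9), self._Const(0.1)]
        ens, _ = sdm.build_ensemble(members, [self._eval(0.9), self._eval(0.55)], cutoff=0.7)
        assert len(ens.members) == 1
        with pytest.raises(ValueError):
            sdm.build_ensemble(members, [self._eval(0.3), self._eval(0.2)], cutoff=0.7)

    def test_surface_bounded_by_member_predictions(self, toy_separable):
        stack, presences, background = toy_separable
        members = [
            sdm.fit_member(k, presences, background, stack, seed=0) for k in ("glm", "rf")
        ]
        evals = [self._eval(0.8), self._eval(0.7)]
        _, surface = sdm.build_ensemble(members, evals, stack=stack)
        preds = np.stack([sdm.predict_surface(m, stack).grid.values for m in members])
        assert np.all(surface.grid.values <= preds.max(axis=0) + 1e-12)
        assert np.all(surface.grid.values >= preds.min(axis=0) - 1e-12)


class TestVariableImportance:
    def test_driving_layer_dominates_and_null_layer_negligible(self, toy_separable):
        stack, presences, background = toy_separable
        member = sdm.fit_member("glm", presences, background, stack, seed=0)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 2)) * [2.0, 1.0]
        imp = sdm.variable_importance(member, stack, X, n_perm=5, seed=1)
        assert imp["driver"] > imp["noise"]
        assert imp["noise"] < 0.05

    def test_deterministic_given_seed(self, toy_separable):
        stack, presences, background = toy_separable
        member = sdm.fit_member("glm", presences, background, stack, seed=0)
        X = np.random.default_rng(3).standard_normal((200, 2))
        a = sdm.variable_importance(member, stack, X, n_perm=3, seed=7)
        b = sdm.variable_importance(member, stack, X, n_perm=3, seed=7)
        assert a == b

    def test_constant_model_warns_all_zero(self, toy_separable):
        stack, *_ = toy_separable

        class Flat:
            def predict(self, X):
                return np.full(len(X), 0.5)

        with pytest.warns(UserWarning):
            imp = sdm.variable_importance(Flat(), stack, np.zeros((50, 2)), n_perm=2, seed=0)
        assert set(imp.values()) == {0.0}


class TestPartialDependence:
    def test_constant_model_flat_curve(self, toy_separable):
        stack, *_ = toy_separable

        class Flat:
            def predict(self, X):
                return np.full(len(X), 0.25)

        grid, resp = sdm.partial_dependence(Flat(), stack, "driver", n_grid=25)
        assert len(grid) == len(resp) == 25
        np.testing.assert_allclose(resp, 0.25)

    def test_positive_logistic_coefficient_gives_nondecreasing_curve(self, toy_separable):
        stack, presences, background = toy_separable
        member = sdm.fit_member("glm", presences, background, stack, seed=0)
        _, resp = sdm.partial_dependence(member, stack, "driver", n_grid=20)
        assert np.all(np.diff(resp) >= -1e-9)

    def test_unknown_variable(self, toy_separable):
        stack, *_ = toy_separable
        with pytest.raises(KeyError):
            sdm.partial_dependence(None, stack, "ndvi")


class TestBinarizeAtPresenceMedian:
    def test_uniform_surface_fully_suitable(self, template, point_at):
        hs = SuitabilitySurface(grid=template.like(np.full((10, 10), 0.5)))
        occ = point_at(template, (2, 2), (5, 5))
        binary, pct, threshold = sdm.binarize_at_presence_median(hs, occ)
        assert threshold == 0.5
        assert pct == 100.0

    def test_presences_in_top_decile(self, point_at):
        # distinct-valued surface; presences occupy the top decile of cells,
        # so the threshold is that decile's median and ~5% of cells pass
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(0, 1, 400)).reshape(20, 20)
        grid = RasterGrid(values=vals, cell_size=100.0, origin=(0, 2000))
        hs = SuitabilitySurface(grid=grid)
        rows, cols = np.nonzero(vals > 0.9)
        occ = point_at(grid, *zip(rows, cols))
        _, pct, _ = sdm.binarize_at_presence_median(hs, occ)
        assert pct == pytest.approx(5.0, abs=1.0)

    def test_no_valid_presence_rejected(self, template):
        hs = SuitabilitySurface(grid=template.like(np.full((10, 10), 0.5)))
        occ = OccurrenceSet(species="t", points=np.empty((0, 2)))
        with pytest.raises(ValueError):
            sdm.binarize_at_presence_median(hs, occ)
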