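"""One-command end-to-end run: synthetic inputs to all tables and surfaces.

Every stochastic stage draws from a named substream of one master seed, so
identical configurations produce byte-identical outputs (the manifest
records a content hash per file).
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cores as cores_mod
from . import markazi_roadkill_path
from . import metrics as metrics_mod
from . import sdm, synth, validation
from .connectivity import (
    DEFAULT_THRESHOLDS,
    DispersalConfig,
    factorial_lcp,
    hs_to_resistance,
    resistant_kernel,
)
from .io import read_roadkill, write_points, write_raster, write_vector
from .vector import OccurrenceSet

__all__ = ["PipelineConfig", "SpeciesConfig", "validate_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("canidconnect")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class SpeciesConfig:
    effect_weights: tuple[float, ...] = (2.0, -1.5, 1.0, 1.5, -1.0)
    n_presence: int = 150
    n_crossings: int = 100
    crossing_bias: float = 2.0


@dataclass
class PipelineConfig:
    output_dir: str = "canidconnect_out"
    seed: int = 0
    members: tuple[str, ...] = sdm.REFERENCE_MEMBERS
    metric: str = "auc"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    core_fraction: float = 0.10
    randomization_b: int = 2000
    background_ratio: int = 10
    eval_fraction: float = 0.2
    synthetic: dict = field(default_factory=dict)
    species: dict[str, SpeciesConfig] = field(
        default_factory=lambda: {
            "grey_wolf": SpeciesConfig(effect_weights=(2.0, -1.5, 1.0, 1.5, -1.0), n_crossings=101),
            "golden_jackal": SpeciesConfig(
                effect_weights=(-1.0, -1.5, 0.5, -2.0, -1.5), n_crossings=170
            ),
        }
    )

    def __post_init__(self) -> None:
        DispersalConfig(self.thresholds)  # validates
        if self.randomization_b < 1:
            raise ValueError("randomization_b must be >= 1")
        if self.metric not in {"auc", "tss"}:
            raise ValueError("metric must be 'auc' or 'tss'")
        unknown = [m for m in self.members if m not in sdm.MEMBER_REGISTRY]
        if unknown:
            raise ValueError(f"unknown members {unknown}; registered: {sorted(sdm.MEMBER_REGISTRY)}")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}:{index}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


_TOP_KEYS = {
    "output_dir", "seed", "members", "metric", "thresholds", "core_fraction",
    "randomization_b", "background_ratio", "eval_fraction", "synthetic", "species",
}
_SPECIES_KEYS = {"effect_weights", "n_presence", "n_crossings", "crossing_bias"}


def _reject_unknown(keys, allowed, where: str) -> None:
    for key in keys:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown {where} key {key!r}{suggestion}")


def validate_config(source) -> PipelineConfig:
    """Build a typed, defaulted, seed-complete PipelineConfig from YAML or dict."""
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text()) or {}
    else:
        doc = dict(source or {})
    _reject_unknown(doc, _TOP_KEYS, "config")
    species_doc = doc.pop("species", None)
    kwargs = dict(doc)
    for tup_key in ("members", "thresholds"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    cfg = PipelineConfig(**kwargs)
    if species_doc is not None:
        species = {}
        for name, sdoc in species_doc.items():
            sdoc = dict(sdoc or {})
            _reject_unknown(sdoc, _SPECIES_KEYS, f"species {name!r}")
            if "effect_weights" in sdoc:
                sdoc["effect_weights"] = tuple(sdoc["effect_weights"])
            species[name] = SpeciesConfig(**sdoc)
        cfg.species = species
    if "synthetic" in doc or cfg.synthetic:
        synth.SyntheticConfig(**{**cfg.synthetic, "seed": 0})  # validates keys/values
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.1f s", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic-landscape pipeline; return the artifact manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    base_synth = synth.SyntheticConfig(
        **{**cfg.synthetic, "seed": cfg.stage_seed("landscape")}
    )

    with _stage("landscape"):
        stack = synth.gen_predictors(base_synth)
        roads = synth.gen_roads(base_synth)
        pas = synth.gen_protected_areas(base_synth)
        if roads.polylines:
            emit(write_vector(roads, out / "roads.geojson"))
        if pas.polygons:
            emit(write_vector(pas, out / "protected_areas.geojson"))
        for name in stack.names:
            emit(write_raster(stack[name], out / f"predictor_{name}.asc"))

    core_binaries: dict[str, object] = {}
    corridors: dict[str, object] = {}
    for si, (species, scfg) in enumerate(sorted(cfg.species.items())):
        sdir = out / species
        sdir.mkdir(exist_ok=True)

        with _stage(f"{species}/sdm"):
            truth = synth.gen_truth_suitability(stack, scfg.effect_weights)
            presences = synth.gen_occurrences(
                truth, scfg.n_presence, cfg.stage_seed("occurrences", si), species=species
            )
            emit(write_points(presences, sdir / "presences.csv"))
            kept = sdm.pearson_screen(stack)
            kstack = stack.subset(kept)
            background = sdm.sample_background(
                stack.template, cfg.background_ratio * presences.n, cfg.stage_seed("background", si)
            )
            rng = np.random.default_rng(cfg.stage_seed("split", si))
            test_p = rng.random(presences.n) < cfg.eval_fraction
            test_b = rng.random(background.n) < cfg.eval_fraction
            train_p = OccurrenceSet(species, presences.points[~test_p])
            train_b = OccurrenceSet("background", background.points[~test_b])
            X_test = np.vstack(
                [
                    sdm.predictor_matrix(kstack, OccurrenceSet(species, presences.points[test_p])),
                    sdm.predictor_matrix(kstack, OccurrenceSet("bg", background.points[test_b])),
                ]
            )
            y_test = np.r_[np.ones(test_p.sum()), np.zeros(test_b.sum())]
            members, evals = [], []
            for mi, kind in enumerate(cfg.members):
                member = sdm.fit_member(
                    kind, train_p, train_b, kstack, seed=cfg.stage_seed(f"member_{kind}", si)
                )
                members.append(member)
                evals.append(sdm.evaluate_model(member.predict(X_test), y_test))
            ensemble, surface = sdm.build_ensemble(
                members, evals, metric=cfg.metric, stack=kstack
            )
            ens_eval = sdm.evaluate_model(ensemble.predict(X_test), y_test)
            eval_df = pd.DataFrame(
                {
                    "model": list(cfg.members) + ["ensemble"],
                    "tss": [e.tss for e in evals] + [ens_eval.tss],
                    "auc": [e.auc for e in evals] + [ens_eval.auc],
                    "tss_grade": [e.tss_grade for e in evals] + [ens_eval.tss_grade],
                    "auc_grade": [e.auc_grade for e in evals] + [ens_eval.auc_grade],
                }
            )
            eval_df.to_csv(sdir / "evaluation.csv", index=False, float_format="%.6f")
            emit(sdir / "evaluation.csv")
            emit(write_raster(surface.grid, sdir / "ensemble_suitability.asc"))

            X_imp = np.vstack(
                [sdm.predictor_matrix(kstack, train_p), sdm.predictor_matrix(kstack, train_b)]
            )
            imp = sdm.variable_importance(
                ensemble, kstack, X_imp, n_perm=3, seed=cfg.stage_seed("importance", si)
            )
            pd.DataFrame(
                {"variable": list(imp), "importance": list(imp.values())}
            ).to_csv(sdir / "importance.csv", index=False, float_format="%.6f")
            emit(sdir / "importance.csv")
            curves = []
            for var in kstack.names:
                g, r = sdm.partial_dependence(
                    ensemble, kstack, var, seed=cfg.stage_seed("pd", si)
                )
                curves.append(pd.DataFrame({"variable": var, "value": g, "response": r}))
            pd.concat(curves).to_csv(sdir / "response_curves.csv", index=False, float_format="%.6f")
            emit(sdir / "response_curves.csv")
            binary_suit, pct_suitable, hs_threshold = sdm.binarize_at_presence_median(
                surface, presences
            )
            emit(write_raster(binary_suit, sdir / "binary_suitability.asc"))

        with _stage(f"{species}/connectivity"):
            resistance = hs_to_resistance(surface)
            emit(write_raster(resistance.grid, sdir / "resistance.asc"))
            kernels = {}
            for t in cfg.thresholds:
                kernels[t] = resistant_kernel(resistance, presences, t)
                emit(write_raster(kernels[t].grid, sdir / f"kernel_{int(t)}.asc"))
            density = factorial_lcp(resistance, presences)
            emit(write_raster(density.grid, sdir / "path_density.asc"))
            corridor = cores_mod.corridor_surface(density.grid)
            corridors[species] = corridor

        with _stage(f"{species}/cores"):
            rows2, rows4, core_rows = [], [], []
            for t in cfg.thresholds:
                patches, labeled = cores_mod.extract_cores(kernels[t], cfg.core_fraction)
                ranked = cores_mod.rank_cores(patches)
                binary = metrics_mod.binarize_connected(kernels[t], cfg.core_fraction)
                if t == cfg.thresholds[-1]:
                    core_binaries[species] = binary
                    emit(write_raster(labeled, sdir / "core_patches.asc"))
                extent, protected, pct = cores_mod.protected_overlap(binary, pas)
                rows2.append(
                    {
                        "dispersal_km": t / 1000.0,
                        "extent_km2": extent,
                        "protected_km2": protected,
                        "protected_pct": pct,
                    }
                )
                cm = metrics_mod.compute_class_metrics(binary)
                rows4.append(
                    {
                        "dispersal_km": t / 1000.0,
                        "np": cm.np_,
                        "lpi": cm.lpi,
                        "pland": cm.pland,
                        "correlation_length_m": cm.gyrate_am,
                    }
                )
                for p in ranked:
                    core_rows.append(
                        {
                            "dispersal_km": t / 1000.0,
                            "patch_id": p.patch_id,
                            "area_km2": p.area_km2,
                            "strength": p.strength,
                            "size_rank": p.size_rank,
                            "strength_rank": p.strength_rank,
                            "final_rank": p.final_rank,
                        }
                    )
            pd.DataFrame(rows2).to_csv(sdir / "core_protection.csv", index=False, float_format="%.6f")
            emit(sdir / "core_protection.csv")
            pd.DataFrame(rows4).to_csv(sdir / "fragmentation_metrics.csv", index=False, float_format="%.6f")
            emit(sdir / "fragmentation_metrics.csv")
            pd.DataFrame(core_rows).to_csv(sdir / "core_ranks.csv", index=False, float_format="%.6f")
            emit(sdir / "core_ranks.csv")

            c_extent, c_prot, c_pct = cores_mod.protected_overlap(corridor, pas)
            road_km = cores_mod.road_in_corridor_length(roads, corridor)
            pd.DataFrame(
                [
                    {
                        "species": species,
                        "corridor_km2": c_extent,
                        "protected_km2": c_prot,
                        "protected_pct": c_pct,
                        "road_in_corridor_km": road_km,
                        "pct_suitable_at_presence_median": pct_suitable,
                        "hs_threshold": hs_threshold,
                    }
                ]
            ).to_csv(sdir / "corridor_protection.csv", index=False, float_format="%.6f")
            emit(sdir / "corridor_protection.csv")

        with _stage(f"{species}/validation"):
            top_kernel = kernels[cfg.thresholds[-1]]
            crossings = synth.gen_crossings(
                top_kernel,
                roads,
                scfg.n_crossings,
                scfg.crossing_bias,
                cfg.stage_seed("crossings", si),
                species=species,
            )
            emit(write_points(crossings, sdir / "crossings.csv"))
            rand_rows = {}
            for t in cfg.thresholds:
                res = validation.randomization_test(
                    kernels[t],
                    crossings,
                    roads,
                    b=cfg.randomization_b,
                    seed=cfg.stage_seed("randomization", si),
                )
                rand_rows[f"{int(t / 1000)}km"] = {
                    "observed_median": res.observed_median,
                    "p_value": res.p_value,
                    "rank": res.rank,
                    "b": res.b,
                    **{f"crossing_{k}": v for k, v in res.summary.items()},
                    "null_median_of_medians": float(np.median(res.null_medians)),
                }
            (sdir / "randomization.json").write_text(
                json.dumps(rand_rows, indent=1, sort_keys=True)
            )
            emit(sdir / "randomization.json")

            table = synth.gen_roadkill(
                synth.SyntheticConfig(
                    **{**cfg.synthetic, "seed": cfg.stage_seed("roadkill", si)}
                ),
                species=species,
            )
            summary = validation.seasonal_summary(table)
            h, dof, p = validation.kruskal_wallis([row for row in table.counts])
            pd.DataFrame(
                {
                    "season": list(table.seasons),
                    "total": [summary.totals[s] for s in table.seasons],
                    "percentage": [summary.percentages[s] for s in table.seasons],
                }
            ).assign(grand_total=summary.grand_total, kw_h=h, kw_df=dof, kw_p=p).to_csv(
                sdir / "roadkill_summary.csv", index=False, float_format="%.6f"
            )
            emit(sdir / "roadkill_summary.csv")

    with _stage("species_overlap"):
        names = sorted(core_binaries)
        if len(names) == 2:
            core_pct = cores_mod.species_overlap(core_binaries[names[0]], core_binaries[names[1]])
            corr_pct = cores_mod.species_overlap(corridors[names[0]], corridors[names[1]])
            pd.DataFrame(
                [{"core_overlap_pct": core_pct, "corridor_overlap_pct": corr_pct}]
            ).to_csv(out / "species_overlap.csv", index=False, float_format="%.6f")
            emit(out / "species_overlap.csv")

    with _stage("observed_roadkill"):
        rows = []
        for species, stated in (("golden_jackal", 173), ("grey_wolf", 103)):
            table = read_roadkill(markazi_roadkill_path(), species=species)
            summ = validation.seasonal_summary(table, stated_total=stated)
            h, dof, p = validation.kruskal_wallis([row for row in table.counts])
            for season in table.seasons:
                rows.append(
                    {
                        "species": species,
                        "season": season,
                        "total": summ.totals[season],
                        "percentage_of_stated_total": summ.percentages[season],
                        "table_grand_total": summ.grand_total,
                        "stated_total": stated,
                        "totals_disagree": summ.total_discrepancy,
                        "kw_h": h,
                        "kw_df": dof,
                        "kw_p": p,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "observed_roadkill_summary.csv", index=False, float_format="%.6f")
        emit(out / "observed_roadkill_summary.csv")

    manifest = {
        "config_seed": cfg.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
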