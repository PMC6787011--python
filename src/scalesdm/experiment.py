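"""Factorial multi-scale experiment: extents x grains x variable sets.

Orchestrates the full design: generate (or load) a landscape and survey,
construct the nested extent replicates, build the grain ladder for each
admissible variable set, and for every design cell rasterize presences,
sample background, split folds, fit the maximum-entropy model and evaluate.
Produces a tidy results table (one row per fold plus a fold-averaged row per
design cell), replicate summaries, environmental-gradient tables, parsimony
comparisons, cross-extent transfer evaluation and suitability map export.

Determinism: a master seed derives every child seed through a counter-based
hash of the design-cell labels, so adding cells never perturbs the seeds of
existing ones, and identical configs reproduce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import design as dz
from . import landscape as lz
from .maxent import FeatureSpec, MaxentModel
from .metrics import EvalResult, evaluate, evaluate_folds, transfer_evaluate
from .raster import (
    GRAIN_LADDER_M,
    VARIABLE_SET_MIN_GRAIN,
    PredictorStack,
    Raster,
    aggregate,
    pca_reduce,
    rasterize_presence,
    write_ascii_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "Experiment",
    "run_factorial",
    "summarize_replicates",
    "gradient_analysis",
    "compare_parsimony",
    "export_maps",
    "child_seed",
]

VARIABLE_SETS = ("base", "base_pheno", "base_pheno_clim")


def child_seed(master: int, *parts) -> int:
    """Stable child seed from the master seed and design-cell labels."""
    key = f"{master}|" + "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """Complete experiment recipe (YAML-serializable)."""

    landscape: lz.TruthConfig = dc_field(default_factory=lz.TruthConfig)
    survey: lz.SurveyDesign = dc_field(default_factory=lz.SurveyDesign)
    block_area_km2: float = 50.0
    min_presence: int = 20
    buffer_area_km2: float = 500.0
    n_buffers: int = 9
    grains: tuple = GRAIN_LADDER_M
    variable_sets: tuple = VARIABLE_SETS
    levels: tuple = (1, 2, 3, 4)
    k_folds: int = 5
    n_background: int = 10000
    max_elev: float = 3600.0
    reg_lambda: float | None = None
    feature_classes: tuple = ("linear", "quadratic")
    pca_variance: float = 0.99
    pca_max_components: int = 5
    pheno_pca_grain: float = 240.0
    max_level1: int | None = None  # cap level-1 replicates (None = all)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw = dict(raw)
        if "landscape" in kw:
            lc = dict(kw["landscape"])
            if "shape" in lc:
                lc["shape"] = tuple(lc["shape"])
            if "coefficients" in lc:
                lc["coefficients"] = {
                    int(r): {v: tuple(ab) for v, ab in cm.items()}
                    for r, cm in lc["coefficients"].items()
                }
            if "intercepts" in lc:
                lc["intercepts"] = {int(r): v for r, v in lc["intercepts"].items()}
            kw["landscape"] = lz.TruthConfig(**lc)
        if "survey" in kw:
            kw["survey"] = lz.SurveyDesign(**kw["survey"])
        for key in ("grains", "variable_sets", "levels", "feature_classes"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "landscape": self.landscape.to_record(),
            "survey": {
                "transect_cell": self.survey.transect_cell,
                "detection_scale": self.survey.detection_scale,
                "seed": self.survey.seed,
            },
            "block_area_km2": self.block_area_km2,
            "min_presence": self.min_presence,
            "buffer_area_km2": self.buffer_area_km2,
            "n_buffers": self.n_buffers,
            "grains": list(self.grains),
            "variable_sets": list(self.variable_sets),
            "levels": list(self.levels),
            "k_folds": self.k_folds,
            "n_background": self.n_background,
            "max_elev": self.max_elev,
            "reg_lambda": self.reg_lambda,
            "feature_classes": list(self.feature_classes),
            "pca_variance": self.pca_variance,
            "pca_max_components": self.pca_max_components,
            "pheno_pca_grain": self.pheno_pca_grain,
            "max_level1": self.max_level1,
            "seed": self.seed,
        }


RESULT_COLUMNS = [
    "extent_level", "replicate_id", "grain_m", "variable_set", "fold",
    "status", "auc", "tss_max", "tss_threshold", "cor", "aicc",
    "n_presence_cells", "n_presence_points", "prevalence",
    "n_background", "importance",
]


class Experiment:
    """Stateful driver for one factorial experiment on one landscape."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.stack: PredictorStack | None = None
        self.regions: Raster | None = None
        self.truth_record: dict | None = None
        self.suitability: Raster | None = None
        self.points: np.ndarray | None = None
        self.extents: list[dz.ExtentSpec] = []
        self.ladders: dict[str, dict[float, PredictorStack]] = {}
        self.results: pd.DataFrame | None = None
        self._fitted: dict = {}

    # -- preparation --------------------------------------------------------

    def prepare(self) -> "Experiment":
        cfg = self.config
        base = cfg.landscape
        # child seeds fold in both the master seed and any user-set seeds
        lcfg = lz.TruthConfig(
            shape=base.shape, cell=base.cell, field_range=base.field_range,
            coefficients=base.coefficients, intercepts=base.intercepts,
            n_regions=base.n_regions,
            seed=child_seed(cfg.seed, "landscape", base.seed),
        )
        self.stack, self.regions, self.truth_record = lz.make_landscape(lcfg)
        self.suitability = lz.true_suitability(self.stack, lcfg, self.regions)
        rng = np.random.default_rng(child_seed(cfg.seed, "survey", cfg.survey.seed))
        self.points = lz.simulate_survey(self.suitability, cfg.survey, rng=rng)
        self._build_extents()
        self._build_ladders()
        return self

    def _build_extents(self):
        cfg = self.config
        domain = self.stack.template.bounds
        blocks, buffers = [], []
        if 1 in cfg.levels or 2 in cfg.levels:
            blocks = dz.grid_blocks(domain, self.points, cfg.block_area_km2,
                                    cfg.min_presence)
            if cfg.max_level1 is not None and len(blocks) > cfg.max_level1:
                rng = np.random.default_rng(child_seed(cfg.seed, "level1-cap"))
                idx = np.sort(rng.choice(len(blocks), cfg.max_level1, replace=False))
                blocks = [blocks[i] for i in idx]
            if cfg.n_buffers:
                buffers = dz.buffer_nonoverlapping(
                    blocks, domain, cfg.buffer_area_km2, cfg.n_buffers,
                    seed=child_seed(cfg.seed, "buffers"),
                )
        extents: list[dz.ExtentSpec] = []
        if 1 in cfg.levels:
            extents += blocks
        if 2 in cfg.levels:
            extents += buffers
        if 3 in cfg.levels:
            extents += dz.region_extents(self.regions)
        if 4 in cfg.levels:
            extents.append(dz.full_domain_extent(self.stack.template))
        self.extents = extents

    def _build_ladders(self):
        """Grain ladders per variable set, built by successive factor-2 means.

        Phenology bands are reduced by PCA once at the PCA grain (default
        240 m), and the components are aggregated up the rest of the ladder.
        """
        cfg = self.config
        base30 = self.stack.subset(list(lz.BASE_VARIABLES))
        grains = sorted(set(cfg.grains))
        base_ladder = {}
        cur = base30
        g = cur.grain
        base_ladder[g] = cur
        while g < max(grains):
            cur = cur.aggregate(2, "mean")
            g = cur.grain
            base_ladder[g] = cur
        self.ladders["base"] = {g: base_ladder[g] for g in grains if g in base_ladder}

        pheno30 = self.stack.subset(list(lz.PHENO_VARIABLES))
        cur = pheno30
        while cur.grain < cfg.pheno_pca_grain:
            cur = cur.aggregate(2, "mean")
        pcs = pca_reduce(cur, cfg.pca_variance, cfg.pca_max_components)
        pheno_ladder = {pcs.grain: pcs}
        cur = pcs
        while cur.grain < max(grains):
            cur = cur.aggregate(2, "mean")
            pheno_ladder[cur.grain] = cur

        clim30 = self.stack.subset(list(lz.CLIMATE_VARIABLES))
        clim_ladder = {}
        cur = clim30
        while cur.grain < max(grains):
            cur = cur.aggregate(2, "mean")
            if cur.grain >= VARIABLE_SET_MIN_GRAIN["base_pheno_clim"]:
                clim_ladder[cur.grain] = cur

        def merge(g, *stacks):
            layers = {}
            for s in stacks:
                layers.update(s.layers)
            return PredictorStack(name="merged", layers=layers, grain=g)

        self.ladders["base_pheno"] = {
            g: merge(g, self.ladders["base"][g], pheno_ladder[g])
            for g in grains
            if g >= VARIABLE_SET_MIN_GRAIN["base_pheno"]
            and g in self.ladders["base"] and g in pheno_ladder
        }
        self.ladders["base_pheno_clim"] = {
            g: merge(g, self.ladders["base_pheno"][g], clim_ladder[g])
            for g in grains
            if g >= VARIABLE_SET_MIN_GRAIN["base_pheno_clim"]
            and g in self.ladders["base_pheno"] and g in clim_ladder
        }

    # -- the factorial ------------------------------------------------------

    def admissible_grains(self, variable_set: str) -> list[float]:
        return sorted(self.ladders.get(variable_set, {}))

    def run(self) -> pd.DataFrame:
        if self.stack is None:
            self.prepare()
        cfg = self.config
        rows = []
        for extent in self.extents:
            for vset in cfg.variable_sets:
                for grain in self.admissible_grains(vset):
                    rows.extend(self._run_cell(extent, vset, grain))
        self.results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return self.results

    def _run_cell(self, extent: dz.ExtentSpec, vset: str, grain: float) -> list[dict]:
        cfg = self.config
        base_row = dict(
            extent_level=extent.level, replicate_id=extent.replicate_id,
            grain_m=grain, variable_set=vset,
        )

        def skip(reason):
            logger.info("skip %s %s %sm: %s", extent.replicate_id, vset, grain, reason)
            row = dict(base_row, fold="mean", status=f"skipped:{reason}",
                       auc=np.nan, tss_max=np.nan, tss_threshold=np.nan,
                       cor=np.nan, aicc=np.nan, n_presence_cells=0,
                       n_presence_points=0, prevalence=np.nan,
                       n_background=0, importance="")
            return [row]

        try:
            stack = self.ladders[vset][grain].crop(extent.rect)
        except ValueError as exc:
            return skip(f"crop:{exc}")
        template = stack.template
        inside = dz.points_in_rect(self.points, extent.rect)
        pts = self.points[inside]
        pgrid = rasterize_presence(pts, template)
        if pgrid.n_cells < cfg.k_folds:
            return skip(f"presence_cells<{cfg.k_folds}")
        X, Y = template.cell_centers()
        pmask = pgrid.mask.values > 0
        pres_xy = np.column_stack([X[pmask], Y[pmask]])
        try:
            bg_xy = dz.sample_background(
                extent, template, stack.layers.get("elevation", template),
                n=cfg.n_background, max_elev=cfg.max_elev,
                seed=child_seed(cfg.seed, extent.replicate_id, grain, vset, "bg"),
            )
        except ValueError as exc:
            return skip(f"background:{exc}")
        Xp = stack.sample(pres_xy[:, 0], pres_xy[:, 1])
        Xb = stack.sample(bg_xy[:, 0], bg_xy[:, 1])
        okp = np.isfinite(Xp).all(axis=1)
        okb = np.isfinite(Xb).all(axis=1)
        Xp, pres_xy = Xp[okp], pres_xy[okp]
        Xb = Xb[okb]
        if len(Xp) < cfg.k_folds or len(Xb) < 2:
            return skip("too_few_valid_cells")

        folds = dz.kfold_split(
            len(Xp), cfg.k_folds,
            seed=child_seed(cfg.seed, extent.replicate_id, grain, vset, "folds"),
        )
        fold_rows, fold_evals, fold_imps = [], [], []
        for fs in folds:
            if len(fs.train_idx) < 2:
                return skip("fold_too_small")
            fseed = child_seed(cfg.seed, extent.replicate_id, grain, vset, fs.fold_id)
            model = MaxentModel(
                Xp[fs.train_idx], Xb, stack.variables,
                features=FeatureSpec(classes=frozenset(cfg.feature_classes)),
                reg_lambda=cfg.reg_lambda,
                metadata=dict(extent=extent.replicate_id, grain=grain,
                              variable_set=vset, fold=fs.fold_id),
            )
            res = model.fit(seed=fseed)
            ev = evaluate(
                res.predict(Xp[fs.test_idx], scale="cloglog"),
                res.predict(Xb, scale="cloglog"),
                aicc=res.aicc(),
            )
            imp = res.permutation_importance(seed=fseed)
            fold_evals.append(ev)
            fold_imps.append(imp)
            self._fitted[(extent.replicate_id, grain, vset, fs.fold_id)] = res
            fold_rows.append(dict(
                base_row, fold=str(fs.fold_id), status="ok",
                auc=ev.auc, tss_max=ev.tss_max, tss_threshold=ev.tss_threshold,
                cor=ev.cor, aicc=ev.aicc, n_presence_cells=pgrid.n_cells,
                n_presence_points=pgrid.n_points, prevalence=pgrid.prevalence,
                n_background=len(Xb),
                importance=json.dumps({k: round(v, 6) for k, v in imp.items()}),
            ))
        mean_ev = evaluate_folds(fold_evals)
        mean_imp = {
            v: float(np.mean([imp[v] for imp in fold_imps])) for v in fold_imps[0]
        }
        fold_rows.append(dict(
            base_row, fold="mean", status="ok",
            auc=mean_ev.auc, tss_max=mean_ev.tss_max,
            tss_threshold=mean_ev.tss_threshold, cor=mean_ev.cor,
            aicc=mean_ev.aicc, n_presence_cells=pgrid.n_cells,
            n_presence_points=pgrid.n_points, prevalence=pgrid.prevalence,
            n_background=len(Xb),
            importance=json.dumps({k: round(v, 6) for k, v in mean_imp.items()}),
        ))
        return fold_rows

    # -- transfer -----------------------------------------------------------

    def run_transfer(self, grain: float = 30.0, variable_set: str = "base",
                     test_fraction: float = 0.2) -> pd.DataFrame:
        """Cross-extent transfer: predict each buffered level-1 target with
        models trained at every extent that nests it, on identical test data."""
        cfg = self.config
        targets = [e for e in self.extents if e.level == 2 and e.parent]
        blocks = {e.replicate_id: e for e in self.extents if e.level == 1}
        rows = []
        for buf in targets:
            tgt = blocks.get(buf.parent)
            if tgt is None:
                continue
            sources = [tgt, buf] + [
                e for e in self.extents
                if e.level >= 3 and e.contains_rect(tgt.rect)
            ]
            try:
                tstack = self.ladders[variable_set][grain].crop(tgt.rect)
            except (KeyError, ValueError):
                continue
            template = tstack.template
            pts = self.points[dz.points_in_rect(self.points, tgt.rect)]
            pgrid = rasterize_presence(pts, template)
            if pgrid.n_cells < 5:
                continue
            X, Y = template.cell_centers()
            pmask = pgrid.mask.values > 0
            pres_xy = np.column_stack([X[pmask], Y[pmask]])
            rng = np.random.default_rng(
                child_seed(cfg.seed, "transfer", tgt.replicate_id)
            )
            n_test = max(2, int(round(test_fraction * len(pres_xy))))
            test_idx = np.sort(rng.choice(len(pres_xy), n_test, replace=False))
            test_xy = pres_xy[test_idx]
            bg_xy = dz.sample_background(
                tgt, template, tstack.layers.get("elevation", template),
                n=cfg.n_background, max_elev=cfg.max_elev,
                seed=child_seed(cfg.seed, "transfer", tgt.replicate_id, "bg"),
            )
            for src in sources:
                res = self._fit_extent_model(src, variable_set, grain,
                                             exclude_xy=test_xy if src is tgt else None)
                if res is None:
                    continue
                ev = transfer_evaluate(res, tstack, test_xy, bg_xy,
                                       source_rect=src.rect)
                rows.append(dict(
                    target_id=tgt.replicate_id, source_id=src.replicate_id,
                    source_level=src.level, grain_m=grain,
                    variable_set=variable_set, **ev.as_dict(),
                ))
        return pd.DataFrame(rows)

    def _fit_extent_model(self, extent, vset, grain, exclude_xy=None):
        cfg = self.config
        key = (extent.replicate_id, grain, vset, "transfer-full")
        if key in self._fitted and exclude_xy is None:
            return self._fitted[key]
        try:
            stack = self.ladders[vset][grain].crop(extent.rect)
        except (KeyError, ValueError):
            return None
        template = stack.template
        pts = self.points[dz.points_in_rect(self.points, extent.rect)]
        pgrid = rasterize_presence(pts, template)
        if pgrid.n_cells < 5:
            return None
        X, Y = template.cell_centers()
        pmask = pgrid.mask.values > 0
        pres_xy = np.column_stack([X[pmask], Y[pmask]])
        if exclude_xy is not None and len(exclude_xy):
            # train on cells not held out for testing
            keep = ~(
                (pres_xy[:, 0][:, None] == exclude_xy[:, 0][None, :])
                & (pres_xy[:, 1][:, None] == exclude_xy[:, 1][None, :])
            ).any(axis=1)
            pres_xy = pres_xy[keep]
            if len(pres_xy) < 2:
                return None
        try:
            bg_xy = dz.sample_background(
                extent, template, stack.layers.get("elevation", template),
                n=cfg.n_background, max_elev=cfg.max_elev,
                seed=child_seed(cfg.seed, "transfer-src", extent.replicate_id, "bg"),
            )
        except ValueError:
            return None
        Xp = stack.sample(pres_xy[:, 0], pres_xy[:, 1])
        Xb = stack.sample(bg_xy[:, 0], bg_xy[:, 1])
        Xp = Xp[np.isfinite(Xp).all(axis=1)]
        Xb = Xb[np.isfinite(Xb).all(axis=1)]
        if len(Xp) < 2 or len(Xb) < 2:
            return None
        model = MaxentModel(
            Xp, Xb, stack.variables,
            features=FeatureSpec(classes=frozenset(cfg.feature_classes)),
            reg_lambda=cfg.reg_lambda,
            metadata=dict(extent=extent.replicate_id, grain=grain,
                          variable_set=vset, fold="transfer"),
        )
        res = model.fit(seed=child_seed(cfg.seed, "transfer-fit", extent.replicate_id))
        if exclude_xy is None:
            self._fitted[key] = res
        return res


def run_factorial(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full factorial and return the tidy results table."""
    return Experiment(config).prepare().run()


def summarize_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of each metric over replicates, per extent x grain x set.

    Uses the fold-averaged rows only. Single-replicate cells carry SD 0 and
    ``single_replicate = True``.
    """
    ok = results[(results["fold"] == "mean") & (results["status"] == "ok")]
    metrics = ["auc", "tss_max", "cor", "aicc", "n_presence_cells", "prevalence"]
    rows = []
    for (lvl, grain, vset), grp in ok.groupby(
        ["extent_level", "grain_m", "variable_set"]
    ):
        row = dict(extent_level=lvl, grain_m=grain, variable_set=vset,
                   n_replicates=len(grp), single_replicate=len(grp) == 1)
        for m in metrics:
            vals = grp[m].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            row[f"{m}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{m}_sd"] = (
                float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size else np.nan)
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["extent_level", "variable_set", "grain_m"]
    ).reset_index(drop=True)


def gradient_analysis(results: pd.DataFrame, stack30: PredictorStack,
                      extents, variable_set: str = "base",
                      grain: float | None = None) -> pd.DataFrame:
    """Join each replicate's predictor mean/SD (30 m grain) to its accuracy.

    One row per replicate x predictor, carrying the replicate's placement on
    the environmental gradient (mean) and its heterogeneity (SD) together
    with the fold-averaged accuracy metrics.
    """
    ok = results[
        (results["fold"] == "mean")
        & (results["status"] == "ok")
        & (results["variable_set"] == variable_set)
    ]
    if grain is not None:
        ok = ok[ok["grain_m"] == grain]
    if ok.empty:
        raise ValueError(f"no factorial results for variable set {variable_set!r}")
    ext_by_id = {e.replicate_id: e for e in extents}
    rows = []
    for _, rec in ok.iterrows():
        ext = ext_by_id.get(rec["replicate_id"])
        if ext is None:
            continue
        cropped = stack30.crop(ext.rect)
        for var in cropped.variables:
            vals = cropped.layers[var].masked()
            rows.append(dict(
                replicate_id=rec["replicate_id"], extent_level=rec["extent_level"],
                grain_m=rec["grain_m"], variable=var,
                mean_value=float(np.nanmean(vals)), sd_value=float(np.nanstd(vals)),
                auc=rec["auc"], tss_max=rec["tss_max"], cor=rec["cor"],
            ))
    return pd.DataFrame(rows)


PARSIMONY_COMPARISONS = (
    ("base", "base_pheno", 240.0),
    ("base_pheno", "base_pheno_clim", 960.0),
    ("base", "base_pheno_clim", 960.0),
)


def compare_parsimony(results: pd.DataFrame, delta: float = 2.0,
                      comparisons=PARSIMONY_COMPARISONS) -> pd.DataFrame:
    """AICc-change bookkeeping between nested variable sets.

    For each comparison and extent level: the fractions of replicates where
    adding variables raised AICc by more than ``delta`` (reduced parsimony,
    '-'), lowered it by more than ``delta`` (improved, '+'), or changed it by
    at most ``delta`` ('no change'). Fractions sum to 1 over the replicates
    with computable AICc in both sets; others are counted as excluded.
    """
    ok = results[(results["fold"] == "mean") & (results["status"] == "ok")]
    rows = []
    for small, large, grain in comparisons:
        a = ok[(ok["variable_set"] == small) & (ok["grain_m"] == grain)]
        b = ok[(ok["variable_set"] == large) & (ok["grain_m"] == grain)]
        merged = a.merge(b, on=["extent_level", "replicate_id"],
                         suffixes=("_small", "_large"))
        for lvl, grp in merged.groupby("extent_level"):
            d = grp["aicc_large"].to_numpy(float) - grp["aicc_small"].to_numpy(float)
            finite = np.isfinite(d)
            n = int(finite.sum())
            row = dict(comparison=f"{small}:{large}", grain_m=grain,
                       extent_level=lvl, n_replicates=n,
                       n_excluded=int((~finite).sum()))
            if n:
                dv = d[finite]
                row["frac_minus"] = float((dv > delta).mean())
                row["frac_plus"] = float((dv < -delta).mean())
                row["frac_nochange"] = float((np.abs(dv) <= delta).mean())
            else:
                row.update(frac_minus=np.nan, frac_plus=np.nan, frac_nochange=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def export_maps(source_results: dict, target_stack: PredictorStack,
                test_presence_xy, background_xy, outdir) -> pd.DataFrame:
    """Write one cloglog suitability grid per source model over a common
    target extent, with an evaluation sidecar; returns the sidecar table."""
    import os

    if len(source_results) < 2:
        raise ValueError("export_maps expects models from at least 2 source extents")
    os.makedirs(outdir, exist_ok=True)
    ref = None
    rows = []
    for name, res in source_results.items():
        grid = res.predict_raster(target_stack, scale="cloglog")
        if ref is None:
            ref = grid
        assert grid.shape == ref.shape and grid.x0 == ref.x0 and grid.cell == ref.cell
        write_ascii_grid(grid, os.path.join(outdir, f"suitability_{name}.asc"))
        ev = transfer_evaluate(res, target_stack, test_presence_xy, background_xy)
        valid = grid.valid_mask()
        rows.append(dict(source=name, spatial_variance=float(np.var(grid.values[valid])),
                         **ev.as_dict()))
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "map_evaluation.csv"), index=False)
    return df
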