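"""Factorial orchestration: design accounting, summaries, parsimony, transfer."""

import numpy as np
import pandas as pd
import pytest

from scalesdm.experiment import (
    Experiment,
    ExperimentConfig,
    child_seed,
    compare_parsimony,
    export_maps,
    gradient_analysis,
    summarize_replicates,
)
from scalesdm.landscape import SurveyDesign, TruthConfig


@pytest.fixture(scope="module")
def small_experiment():
    """One modest landscape driven through the full factorial."""
    cfg = ExperimentConfig(
        landscape=TruthConfig(shape=(300, 300), n_regions=4),
        survey=SurveyDesign(detection_scale=15),
        grains=(30, 240, 960, 1920),
        levels=(1, 3, 4),
        n_buffers=0,
        n_background=1500,
        max_level1=3,
        seed=21,
    )
    exp = Experiment(cfg).prepare()
    results = exp.run()
    return exp, results


class TestFactorial:
    def test_grain_availability_per_variable_set(self, small_experiment):
        exp, results = small_experiment
        assert exp.admissible_grains("base") == [30, 240, 960, 1920]
        assert exp.admissible_grains("base_pheno") == [240, 960, 1920]
        assert exp.admissible_grains("base_pheno_clim") == [960, 1920]
        by_set = results[results["fold"] == "mean"].groupby("variable_set")[
            "grain_m"
        ].unique()
        assert set(by_set["base_pheno_clim"]) == {960, 1920}

    def test_full_grain_ladder_for_base(self):
        cfg = ExperimentConfig(landscape=TruthConfig(shape=(70, 70)),
                               levels=(4,), n_buffers=0, seed=1)
        exp = Experiment(cfg).prepare()
        assert exp.admissible_grains("base") == [30, 60, 120, 240, 480, 960, 1920]

    def test_design_cell_accounting(self, small_experiment):
        exp, results = small_experiment
        mean_rows = results[results["fold"] == "mean"]
        expected = sum(
            len(exp.admissible_grains(vs)) for vs in exp.config.variable_sets
        ) * len(exp.extents)
        assert len(mean_rows) == expected  # every cell recorded: ok or skipped

    def test_fold_rows_accompany_ok_cells(self, small_experiment):
        exp, results = small_experiment
        ok_means = results[(results["fold"] == "mean") & (results["status"] == "ok")]
        for _, row in ok_means.iterrows():
            folds = results[
                (results["replicate_id"] == row["replicate_id"])
                & (results["grain_m"] == row["grain_m"])
                & (results["variable_set"] == row["variable_set"])
                & (results["fold"] != "mean")
            ]
            assert len(folds) == exp.config.k_folds

    def test_fold_average_is_arithmetic_mean(self, small_experiment):
        _, results = small_experiment
        ok = results[results["status"] == "ok"]
        grp = ok[ok["fold"] != "mean"].groupby(
            ["replicate_id", "grain_m", "variable_set"]
        )["auc"].mean()
        means = ok[ok["fold"] == "mean"].set_index(
            ["replicate_id", "grain_m", "variable_set"]
        )["auc"]
        for key, v in grp.items():
            assert means[key] == pytest.approx(v, abs=1e-12)

    def test_prevalence_rises_with_grain(self, small_experiment):
        # coarser cells: fewer total cells, so presence cells occupy more of them
        _, results = small_experiment
        ok = results[(results["fold"] == "mean") & (results["status"] == "ok")
                     & (results["variable_set"] == "base")
                     & (results["extent_level"] == 4)]
        prev = ok.sort_values("grain_m")["prevalence"].to_numpy()
        assert np.all(np.diff(prev) > 0)


class TestChildSeed:
    def test_stable_and_distinct(self):
        a = child_seed(1, "L1-000", 30, "base", 1)
        assert a == child_seed(1, "L1-000", 30, "base", 1)
        assert a != child_seed(1, "L1-000", 30, "base", 2)
        assert a != child_seed(2, "L1-000", 30, "base", 1)
        assert 0 <= a < 2**31


class TestSummaries:
    def _results(self):
        rows = []
        for rep, tss in [("a", 0.4), ("b", 0.6)]:
            rows.append(dict(extent_level=1, replicate_id=rep, grain_m=30,
                             variable_set="base", fold="mean", status="ok",
                             auc=0.7, tss_max=tss, tss_threshold=0.5, cor=0.2,
                             aicc=100.0, n_presence_cells=10,
                             n_presence_points=12, prevalence=0.01,
                             n_background=100, importance="{}"))
        rows.append(dict(extent_level=2, replicate_id="c", grain_m=30,
                         variable_set="base", fold="mean", status="ok",
                         auc=0.8, tss_max=0.5, tss_threshold=0.5, cor=0.3,
                         aicc=90.0, n_presence_cells=20, n_presence_points=25,
                         prevalence=0.005, n_background=100, importance="{}"))
        return pd.DataFrame(rows)

    def test_mean_and_sd_across_replicates(self):
        out = summarize_replicates(self._results())
        row = out[out["extent_level"] == 1].iloc[0]
        assert row["tss_max_mean"] == pytest.approx(0.5)
        assert row["tss_max_sd"] == pytest.approx(np.std([0.4, 0.6], ddof=1))
        assert row["n_replicates"] == 2

    def test_single_replicate_flagged_with_zero_sd(self):
        out = summarize_replicates(self._results())
        row = out[out["extent_level"] == 2].iloc[0]
        assert bool(row["single_replicate"]) and row["tss_max_sd"] == 0.0

    def test_presence_and_prevalence_columns_present(self):
        out = summarize_replicates(self._results())
        assert {"n_presence_cells_mean", "n_presence_cells_sd",
                "prevalence_mean", "prevalence_sd"} <= set(out.columns)


class TestParsimony:
    def _results(self, deltas, level=2, grain=240.0):
        rows = []
        for i, d in enumerate(deltas):
            for vset, aicc in [("base", 100.0), ("base_pheno", 100.0 + d)]:
                rows.append(dict(extent_level=level, replicate_id=f"r{i}",
                                 grain_m=grain, variable_set=vset, fold="mean",
                                 status="ok", auc=0.7, tss_max=0.5,
                                 tss_threshold=0.5, cor=0.2, aicc=aicc,
                                 n_presence_cells=10, n_presence_points=10,
                                 prevalence=0.01, n_background=100,
                                 importance="{}"))
        return pd.DataFrame(rows)

    def test_identical_models_all_no_change(self):
        out = compare_parsimony(self._results([0.0, 0.0, 0.0]))
        row = out.dropna(subset=["frac_nochange"]).iloc[0]
        assert (row["frac_minus"], row["frac_plus"], row["frac_nochange"]) == (0, 0, 1)

    def test_fractions_partition_to_one(self):
        out = compare_parsimony(self._results([5.0, -4.0, 1.0, 2.5, -2.1]))
        row = out.dropna(subset=["frac_nochange"]).iloc[0]
        total = row["frac_minus"] + row["frac_plus"] + row["frac_nochange"]
        assert total == pytest.approx(1.0, abs=1e-12)
        assert row["frac_minus"] == pytest.approx(2 / 5)  # +5.0, +2.5
        assert row["frac_plus"] == pytest.approx(2 / 5)  # -4.0, -2.1
        assert row["frac_nochange"] == pytest.approx(1 / 5)

    def test_three_comparison_rows_per_level(self, small_experiment):
        _, results = small_experiment
        out = compare_parsimony(results)
        assert set(out["comparison"]) <= {
            "base:base_pheno", "base_pheno:base_pheno_clim",
            "base:base_pheno_clim",
        }
        for _, row in out.dropna(subset=["frac_nochange"]).iterrows():
            s = row["frac_minus"] + row["frac_plus"] + row["frac_nochange"]
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_excluded_replicates_counted(self):
        df = self._results([5.0, np.nan])
        out = compare_parsimony(df)
        row = out[out["n_replicates"] > 0].iloc[0]
        assert row["n_excluded"] == 1


class TestGradient:
    def test_replicate_rows_per_variable(self, small_experiment):
        exp, results = small_experiment
        table = gradient_analysis(results, exp.stack.subset(
            ["elevation", "forest"]), exp.extents, variable_set="base", grain=30)
        n_reps = results[(results["fold"] == "mean") & (results["status"] == "ok")
                         & (results["variable_set"] == "base")
                         & (results["grain_m"] == 30)]["replicate_id"].nunique()
        assert len(table) == n_reps * 2
        assert {"mean_value", "sd_value", "tss_max"} <= set(table.columns)

    def test_constant_predictor_has_zero_sd_and_shared_mean(self, small_experiment):
        exp, results = small_experiment
        const = exp.stack.subset(["elevation"])
        flat = const.layers["elevation"].with_values(
            np.full(const.template.shape, 5.0))
        from scalesdm.raster import PredictorStack

        stack = PredictorStack("c", {"flat": flat}, 30.0)
        table = gradient_analysis(results, stack, exp.extents,
                                  variable_set="base", grain=30)
        assert np.allclose(table["sd_value"], 0.0)
        assert table["mean_value"].nunique() == 1

    def test_unknown_variable_set_raises(self, small_experiment):
        exp, results = small_experiment
        with pytest.raises(ValueError):
            gradient_analysis(results, exp.stack, exp.extents,
                              variable_set="nope")


class TestTransferAndMaps:
    def test_transfer_shares_test_data_across_sources(self, small_experiment):
        exp, _ = small_experiment
        # build a level-2-style setting by hand: target block vs full domain
        cfg = ExperimentConfig(
            landscape=TruthConfig(shape=(300, 300)),
            survey=SurveyDesign(detection_scale=20),
            grains=(30,), levels=(1, 2, 4), n_buffers=2,
            n_background=800, max_level1=4, seed=33,
        )
        e2 = Experiment(cfg).prepare()
        e2.run()
        table = e2.run_transfer(grain=30.0)
        if len(table):
            for tid, grp in table.groupby("target_id"):
                # identical test sets: presence/background counts agree
                assert grp["n_presence_test"].nunique() == 1
                assert grp["n_background"].nunique() == 1

    def test_export_maps_aligned_grids_and_sidecar(self, tmp_path):
        cfg = ExperimentConfig(
            landscape=TruthConfig(shape=(200, 200)),
            survey=SurveyDesign(detection_scale=25),
            grains=(30,), levels=(1, 4), n_buffers=0,
            block_area_km2=10.0, min_presence=10,
            n_background=500, max_level1=2, seed=55,
        )
        exp = Experiment(cfg).prepare()
        exp.run()
        blocks = [e for e in exp.extents if e.level == 1]
        if not blocks:
            pytest.skip("no qualifying blocks at this seed")
        tgt = blocks[0]
        sources = {}
        for src in [tgt, exp.extents[-1]]:
            res = exp._fit_extent_model(src, "base", 30.0)
            if res is not None:
                sources[src.replicate_id] = res
        if len(sources) < 2:
            pytest.skip("not enough fitted sources")
        tstack = exp.ladders["base"][30.0].crop(tgt.rect)
        from scalesdm.design import points_in_rect, sample_background

        pts = exp.points[points_in_rect(exp.points, tgt.rect)]
        bg = sample_background(tgt, tstack.template,
                               tstack.layers["elevation"], n=300, seed=1)
        out = export_maps(sources, tstack, pts, bg, tmp_path)
        assert len(out) == 2
        import glob

        assert len(glob.glob(str(tmp_path / "suitability_*.asc"))) == 2


class TestConfigRoundtrip:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = ExperimentConfig(
            landscape=TruthConfig(shape=(64, 64), n_regions=4),
            grains=(30, 60), seed=3,
        )
        path = tmp_path / "cfg.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        back = ExperimentConfig.from_yaml(path)
        assert back.landscape.shape == (64, 64)
        assert back.grains == (30, 60)
        assert back.seed == 3
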