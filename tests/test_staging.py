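"""Additive/stage regression models, BH FDR control, and contiguous
segmentation, checked against exact identifiability cases and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lungdev.containers import make_sample_meta
from lungdev.staging import (CANONICAL_STAGES, StageMap, benjamini_hochberg,
                             build_stage_map, fit_additive_model,
                             fit_stage_model, segment_stages)
from lungdev.simdata import SyntheticDesign, simulate_gene_matrix

from _oracles import bh_stepup, best_contiguous_partition


def scores_from_effects(tp_effects, strain_effects, mu=0.0, noise=None,
                        reps=2, missing=()):
    """Build a score table from planted sum-to-zero effects."""
    recs, vals = [], []
    for strain, b in strain_effects.items():
        for tp, a in tp_effects.items():
            if (strain, tp) in missing:
                continue
            for r in range(1, reps + 1):
                recs.append((f"{strain}_{tp}_r{r}", strain, tp, r))
                vals.append(mu + a + b)
    meta = make_sample_meta(recs)
    y = np.asarray(vals, dtype=float)
    if noise is not None:
        y = y + noise(len(y))
    return pd.DataFrame({"PC1": y}, index=meta.index), meta


class TestAdditiveModel:
    TP = {"P0": 1.0, "P2": -0.5, "P4": 2.0, "P7": -2.5}
    ST = {"AJ": 0.5, "B6": -0.2, "C3H": -0.3}

    def test_exact_recovery_of_planted_effects(self):
        scores, meta = scores_from_effects(self.TP, self.ST, mu=3.0)
        fit = fit_additive_model(scores, meta)
        for tp, a in self.TP.items():
            assert fit.timepoint_effects.loc[tp, "PC1"] == pytest.approx(a)
        for s, b in self.ST.items():
            assert fit.strain_effects.loc[s, "PC1"] == pytest.approx(b)
        assert fit.intercept["PC1"] == pytest.approx(3.0)

    def test_fitted_plus_residual_reconstructs(self):
        rng = np.random.default_rng(0)
        scores, meta = scores_from_effects(self.TP, self.ST,
                                           noise=lambda n: rng.normal(size=n))
        fit = fit_additive_model(scores, meta)
        assert np.allclose(fit.fitted["PC1"] + fit.residuals["PC1"],
                           scores["PC1"])

    def test_missing_cell_handled(self):
        scores, meta = scores_from_effects(
            self.TP, self.ST, missing={("B6", "P7"), ("C3H", "P7")})
        fit = fit_additive_model(scores, meta)
        # zero-noise data remain exactly identifiable on available cells
        assert np.allclose(fit.residuals["PC1"], 0.0, atol=1e-9)

    def test_null_strain_pvalues_roughly_uniform(self):
        # b_j = 0 with noise: strain p-values behave like a null test
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(400):
            scores, meta = scores_from_effects(
                {"P0": 1.0, "P2": -1.0, "P4": 0.0},
                {"AJ": 0.0, "B6": 0.0, "C3H": 0.0},
                noise=lambda n: rng.normal(size=n), reps=3)
            fit = fit_additive_model(scores, meta)
            pvals.append(fit.pvalues.loc["PC1", "strain"])
        pvals = np.asarray(pvals)
        assert abs((pvals < 0.1).mean() - 0.1) < 0.05
        assert abs(pvals.mean() - 0.5) < 0.06

    def test_single_strain_reduces_to_timepoint_means(self):
        scores, meta = scores_from_effects(self.TP, {"AJ": 0.0}, mu=1.0)
        fit = fit_additive_model(scores, meta)
        for tp, a in self.TP.items():
            assert fit.intercept["PC1"] + fit.timepoint_effects.loc[tp, "PC1"] \
                == pytest.approx(1.0 + a)

    def test_confounded_design_rejected(self):
        # each strain observed at its own private time point
        recs = [("a", "AJ", "P0", 1), ("b", "AJ", "P0", 2),
                ("c", "B6", "P2", 1), ("d", "B6", "P2", 2)]
        meta = make_sample_meta(recs)
        scores = pd.DataFrame({"PC1": [0.0, 1.0, 2.0, 3.0]}, index=meta.index)
        with pytest.raises(ValueError, match="confounded"):
            fit_additive_model(scores, meta)


class TestBenjaminiHochberg:
    def test_hand_stepup_example(self):
        reject, adjusted = benjamini_hochberg([0.001, 0.02, 0.03, 0.5], 0.1)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_no_rejections(self):
        reject, _ = benjamini_hochberg([1.0] * 5, 0.1)
        assert not reject.any()

    def test_single_test_plain_threshold(self):
        reject, adjusted = benjamini_hochberg([0.05], 0.1)
        assert reject.tolist() == [True]
        assert adjusted[0] == pytest.approx(0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2], 0.1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.floats(0.01, 0.5))
    def test_matches_naive_oracle_and_monotone_in_q(self, pvals, q):
        reject, _ = benjamini_hochberg(pvals, q)
        assert reject.tolist() == bh_stepup(pvals, q)
        looser, _ = benjamini_hochberg(pvals, min(1.0, q * 2))
        assert (reject <= looser).all()


class TestSegmentation:
    def test_constant_effects_single_stage(self):
        eff = pd.DataFrame({"PC1": [1.0] * 6},
                           index=[f"P{i}" for i in range(6)])
        smap = segment_stages(eff)
        assert len(smap.stages) == 1

    def test_zero_noise_plateaus_recovered_exactly(self):
        eff = pd.DataFrame({"PC1": [0, 0, 0, 5, 5, 9, 9, 9]},
                           index=[f"P{i}" for i in range(8)], dtype=float)
        smap = segment_stages(eff, n_stages=3)
        assert [tps for _, tps in smap.stages] == [
            ["P0", "P1", "P2"], ["P3", "P4"], ["P5", "P6", "P7"]]

    def test_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(2)
        levels = np.repeat([0.0, 3.0, -2.0, 4.0], [3, 2, 3, 2])
        noisy = levels + rng.normal(scale=0.3, size=10)
        eff = pd.DataFrame({"PC1": noisy}, index=[f"P{i}" for i in range(10)])
        smap = segment_stages(eff, n_stages=4)
        _, cuts = best_contiguous_partition(noisy, 4)
        bounds = [0] + list(cuts) + [10]
        expected = [[f"P{i}" for i in range(a, b)]
                    for a, b in zip(bounds, bounds[1:])]
        assert [tps for _, tps in smap.stages] == expected

    def test_must_link_pin_respected(self):
        eff = pd.DataFrame({"PC1": [0, 0, 5, 5.2, 9, 9]},
                           index=[f"P{i}" for i in range(6)], dtype=float)
        smap = segment_stages(eff, n_stages=3, must_link=[("P1", "P2")])
        joined = next(tps for _, tps in smap.stages if "P1" in tps)
        assert "P2" in joined

    def test_must_split_pin_respected(self):
        eff = pd.DataFrame({"PC1": [0, 0, 0, 0, 9, 9]},
                           index=[f"P{i}" for i in range(6)], dtype=float)
        smap = segment_stages(eff, n_stages=3, must_split=[("P0", "P1")])
        first = smap.stages[0][1]
        assert first == ["P0"]

    def test_too_many_stages_rejected(self):
        eff = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["P0", "P1"])
        with pytest.raises(ValueError):
            segment_stages(eff, n_stages=3)

    def test_canonical_names_at_nine_stages(self):
        vals = np.repeat(np.arange(9, dtype=float) * 3, 2)
        eff = pd.DataFrame({"PC1": vals},
                           index=[f"P{i}" for i in range(18)])
        smap = segment_stages(eff, n_stages=9)
        assert smap.stage_names == CANONICAL_STAGES

    def test_whole_embryo_kept_apart(self):
        idx = ["E9.5"] + [f"P{i}" for i in range(4)]
        eff = pd.DataFrame({"PC1": [9.0, 0.0, 0.0, 5.0, 5.0]}, index=idx)
        smap = build_stage_map(eff, n_stages=2)
        assert smap.stages[0] == ("WE", ["E9.5"])
        assert len(smap.stages) == 3


class TestStageModel:
    def _stage_map(self):
        return StageMap([("EARLY", ["P0", "P2"]), ("LATE", ["P4", "P7"])])

    def _scores(self, interaction=None, noise=None, reps=3):
        stage_eff = {"P0": 1.0, "P2": 1.0, "P4": -1.0, "P7": -1.0}
        strain_eff = {"AJ": 0.5, "B6": -0.5}
        recs, vals = [], []
        rng = np.random.default_rng(3)
        for strain, b in strain_eff.items():
            for tp, d in stage_eff.items():
                for r in range(1, reps + 1):
                    recs.append((f"{strain}_{tp}_r{r}", strain, tp, r))
                    v = d + b
                    if interaction is not None:
                        stage = "EARLY" if tp in ("P0", "P2") else "LATE"
                        v += interaction.get((stage, strain), 0.0)
                    vals.append(v)
        meta = make_sample_meta(recs)
        y = np.asarray(vals)
        if noise is not None:
            y = y + noise(rng, len(y))
        return pd.DataFrame({"PC1": y}, index=meta.index), meta

    def test_no_interaction_data_gives_zero_interaction(self):
        scores, meta = self._scores()
        fit = fit_stage_model(scores, meta, self._stage_map())
        assert np.allclose(fit.interaction["PC1"].to_numpy(), 0.0, atol=1e-9)
        assert fit.stage_effects.loc["EARLY", "PC1"] == pytest.approx(1.0)
        assert fit.strain_effects.loc["AJ", "PC1"] == pytest.approx(0.5)

    def test_interaction_sums_to_zero_over_rows_and_columns(self):
        scores, meta = self._scores(
            interaction={("EARLY", "AJ"): 0.8, ("EARLY", "B6"): -0.8,
                         ("LATE", "AJ"): -0.8, ("LATE", "B6"): 0.8},
            noise=lambda rng, n: rng.normal(scale=0.1, size=n))
        fit = fit_stage_model(scores, meta, self._stage_map())
        g = fit.interaction["PC1"]
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-9)

    def test_planted_interaction_recovered(self):
        planted = {("EARLY", "AJ"): 1.2, ("EARLY", "B6"): -1.2,
                   ("LATE", "AJ"): -1.2, ("LATE", "B6"): 1.2}
        reps, sd = 6, 0.3
        scores, meta = self._scores(
            interaction=planted,
            noise=lambda rng, n: rng.normal(scale=sd, size=n), reps=reps)
        fit = fit_stage_model(scores, meta, self._stage_map())
        # each cell mean has SE sd/sqrt(2 tp x reps); the interaction
        # contrast is a linear combination bounded by that scale
        se = sd / np.sqrt(2 * reps)
        got = fit.interaction["PC1"].loc["EARLY", "AJ"]
        assert abs(got - 1.2) < 3 * se

    def test_fitted_plus_residual_reconstructs(self):
        scores, meta = self._scores(
            noise=lambda rng, n: rng.normal(size=n))
        fit = fit_stage_model(scores, meta, self._stage_map())
        assert np.allclose(fit.fitted["PC1"] + fit.residuals["PC1"],
                           scores["PC1"])

    def test_unmapped_timepoint_rejected(self):
        scores, meta = self._scores()
        bad_map = StageMap([("EARLY", ["P0", "P2"]), ("LATE", ["P4"])])
        with pytest.raises(ValueError, match="not covered"):
            fit_stage_model(scores, meta, bad_map)

    def test_significant_stage_effect_on_planted_data(self):
        scores, meta = self._scores(
            noise=lambda rng, n: rng.normal(scale=0.2, size=n))
        fit = fit_stage_model(scores, meta, self._stage_map())
        assert fit.pvalues.loc["PC1", "stage"] < 1e-4


class TestStageMapContainer:
    def test_round_trip_json_and_tsv(self, tmp_path):
        smap = StageMap([("A", ["P0", "P2"]), ("B", ["P4"])])
        smap.to_json(tmp_path / "s.json")
        assert StageMap.from_json(tmp_path / "s.json").stages == smap.stages
        smap.to_tsv(tmp_path / "s.tsv")
        assert StageMap.from_tsv(tmp_path / "s.tsv").stages == smap.stages

    def test_duplicate_timepoint_rejected(self):
        with pytest.raises(ValueError):
            StageMap([("A", ["P0"]), ("B", ["P0"])])

    def test_contiguity_check(self):
        good = StageMap([("A", ["E11.5", "E12.5"]), ("B", ["P0"])])
        assert good.is_contiguous()
        bad = StageMap([("A", ["P0"]), ("B", ["E11.5"])])
        assert not bad.is_contiguous()


def test_nine_stage_recovery_on_full_synthetic_design():
    """The planted stage partition of the full 3-strain design is recovered
    from PCs 1-3 time-point effects (whole-embryo samples set apart)."""
    from lungdev.decompose import run_pca
    from lungdev.preprocess import zscore_rows

    design = SyntheticDesign(n_genes=150, strain_class_spec={},
                             noise_sd=0.3, seed=8)
    matrix, truth = simulate_gene_matrix(design)
    pca = run_pca(zscore_rows(matrix), K=3)
    fit = fit_additive_model(pca.scores, matrix.sample_meta)
    smap = build_stage_map(fit.timepoint_effects[["PC1", "PC2", "PC3"]],
                           n_stages=9)
    assert smap.stages == truth.stage_map_true.stages
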