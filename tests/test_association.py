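"""ddCt folds, genotype-group summaries, concordance, and DEG filters."""

import numpy as np
import pandas as pd
import pytest

from foxyloci.association import (
    FoldResult,
    concordance,
    ddct_fold,
    deg_filter,
    group_stats,
)
from foxyloci.junction_genotyping import GenotypeCall
from foxyloci.synthetic_locus import (
    ExpressionEffectModel,
    build_diploid,
    simulate_expression_panel,
)


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["accession", "replicate", "gene", "ct"])


class TestDdctFold:
    def test_closed_form_ddct_minus2_gives_fold_4(self):
        rows = []
        for rep in (1, 2):
            rows += [("base", rep, "reference", 20.0),
                     ("base", rep, "target", 25.0),
                     ("x", rep, "reference", 20.0),
                     ("x", rep, "target", 23.0)]      # ddCt = -2
        folds = {f.accession: f for f in ddct_fold(_ct_table(rows), "base")}
        assert folds["base"].fold == 1.0
        assert folds["x"].fold == pytest.approx(4.0)

    def test_fold_range_from_dct_sd(self):
        rows = [("base", 1, "reference", 20.0), ("base", 1, "target", 25.0),
                ("base", 2, "reference", 20.0), ("base", 2, "target", 25.0),
                ("x", 1, "reference", 20.0), ("x", 1, "target", 23.0),
                ("x", 2, "reference", 20.0), ("x", 2, "target", 25.0)]
        f = {r.accession: r for r in ddct_fold(_ct_table(rows), "base")}["x"]
        sd = np.std([3.0, 5.0], ddof=1)
        assert f.fold_range[0] == pytest.approx(f.fold / 2 ** sd)
        assert f.fold_range[1] == pytest.approx(f.fold * 2 ** sd)
        assert f.fold_range[0] <= f.fold <= f.fold_range[1]

    def test_simulated_panel_effect_recovered_exactly_without_noise(self):
        panel = [build_diploid("Merlot", "caco", "del3kb"),
                 build_diploid("Concord", "concord", "concord")]
        ct = simulate_expression_panel(
            panel, ExpressionEffectModel(baseline="Merlot"), seed=0)
        folds = {f.accession: f.fold for f in ddct_fold(ct, "Merlot")}
        assert folds["Concord"] == pytest.approx(14.0, abs=1e-9)

    def test_missing_reference_gene_rows_error_lists_accessions(self):
        rows = [("base", 1, "reference", 20.0), ("base", 1, "target", 25.0),
                ("x", 1, "target", 23.0)]
        with pytest.raises(ValueError, match="x"):
            ddct_fold(_ct_table(rows), "base")

    def test_bias_shrinks_with_replicates(self):
        # convergence is a property of the estimator, so average the error
        # over independent simulated panels rather than judging one draw
        panel = [build_diploid("Merlot", "caco", "del3kb"),
                 build_diploid("Concord", "concord", "concord")]
        mean_err = {}
        for n in (3, 30):
            errs = []
            for seed in range(20):
                model = ExpressionEffectModel(baseline="Merlot",
                                              ct_noise_sd=0.5, replicates=n)
                ct = simulate_expression_panel(panel, model, seed=seed)
                fold = {f.accession: f.fold
                        for f in ddct_fold(ct, "Merlot")}["Concord"]
                errs.append(abs(fold - 14.0) / 14.0)
            mean_err[n] = np.mean(errs)
        assert mean_err[30] < mean_err[3]
        assert mean_err[30] < 0.15


class TestGroupStats:
    def _folds(self, d):
        return [FoldResult(a, f, (f, f)) for a, f in d.items()]

    def _genos(self, d):
        return [GenotypeCall(a, "426", g) for a, g in d.items()]

    def test_two_member_group_mean_and_se(self):
        folds = self._folds({"a": 2.0, "b": 4.0})
        genos = self._genos({"a": "0/0", "b": "0/0"})
        (g,) = group_stats(folds, genos)
        assert g.mean_fold == 3.0 and g.se == pytest.approx(1.0)

    def test_groups_partition_accessions(self):
        folds = self._folds({"a": 2.0, "b": 4.0, "c": 1.0, "d": 9.0})
        genos = self._genos({"a": "0/0", "b": "426/426", "c": "0/426",
                             "d": "-/-"})
        groups = group_stats(folds, genos)
        members = sorted(m for g in groups for m in g.members)
        assert members == ["a", "b", "c", "d"]

    def test_permutation_invariant(self):
        folds = self._folds({"a": 2.0, "b": 4.0, "c": 1.0})
        genos = self._genos({"a": "0/0", "b": "0/0", "c": "426/426"})
        g1 = group_stats(folds, genos)
        g2 = group_stats(folds[::-1], genos[::-1])
        assert [(g.label, g.mean_fold, g.se) for g in g1] == \
            [(g.label, g.mean_fold, g.se) for g in g2]

    def test_unmatched_accessions_rejected(self):
        with pytest.raises(ValueError, match="without both"):
            group_stats(self._folds({"a": 1.0}), self._genos({"b": "0/0"}))

    def test_group_effect_ratio_recovered_under_noise(self):
        # configured contrast: element-absent alleles express 7x -> the
        # homozygous-absent vs homozygous-present group ratio is 7; the
        # baseline is itself a carrier so the groups stay pure
        panel = ([build_diploid(f"abs{i}", "concord", "concord")
                  for i in range(3)]
                 + [build_diploid(f"pres{i}", "caco", "caco")
                    for i in range(3)])
        model = ExpressionEffectModel(baseline="pres0", ct_noise_sd=0.5,
                                      replicates=30)
        ct = simulate_expression_panel(panel, model, seed=5)
        folds = ddct_fold(ct, "pres0")
        genos = [GenotypeCall(d.accession, "426", d.genotype_string("el426"))
                 for d in panel]
        by_label = {g.label: g for g in group_stats(folds, genos)}
        ratio = (by_label["element absent (0/0)"].mean_fold
                 / by_label["element present (X/X or X/-)"].mean_fold)
        assert ratio == pytest.approx(7.0, rel=0.20)


class TestConcordance:
    def test_perfectly_monotone_panel_has_rho_1(self):
        folds = [FoldResult(a, f, (f, f)) for a, f in
                 [("a", 1.0), ("b", 2.0), ("c", 5.0), ("d", 20.0)]]
        ma = pd.DataFrame({"accession": list("abcd"),
                           "ma": [0.5, 1.0, 3.0, 9.0]})
        rho, disc, viol = concordance(folds, ma)
        assert rho == pytest.approx(1.0)
        assert disc == [] and viol == []

    def test_high_expression_low_ma_accession_flagged_discordant(self):
        folds = [FoldResult(a, f, (f, f)) for a, f in
                 [("base", 1.0), ("mid", 5.0), ("hubbard", 40.0)]]
        ma = pd.DataFrame({"accession": ["base", "mid", "hubbard"],
                           "ma": [1.0, 4.0, 0.5]})
        _, disc, viol = concordance(folds, ma)
        assert disc == ["hubbard"] and viol == []

    def test_low_expression_high_ma_is_model_violating(self):
        folds = [FoldResult(a, f, (f, f)) for a, f in
                 [("base", 1.0), ("odd", 1.5), ("hi", 30.0)]]
        ma = pd.DataFrame({"accession": ["base", "odd", "hi"],
                           "ma": [1.0, 50.0, 20.0]})
        _, disc, viol = concordance(folds, ma)
        assert viol == ["odd"]

    def test_fewer_than_three_pairs_reports_missing_correlation(self):
        folds = [FoldResult("a", 1.0, (1, 1)), FoldResult("b", 2.0, (2, 2))]
        ma = pd.DataFrame({"accession": ["a", "b"], "ma": [1.0, 2.0]})
        rho, _, _ = concordance(folds, ma)
        assert rho is None


class TestDegFilter:
    def _tpm(self):
        rows = [
            # gene, class, fruit_set, veraison, ripening
            ("g1", "c1", 10.0, 100.0, 80.0),   # passes: 100>=50, 10x
            ("g1", "c2", 10.0, 12.0, 11.0),
            ("g2", "c1", 60.0, 55.0, 50.0),    # floor ok but fold < 5
            ("g2", "c2", 60.0, 58.0, 50.0),
            ("g3", "c1", 10.0, 50.0, 40.0),    # exactly 50 TPM, exactly 5x
            ("g3", "c2", 5.0, 6.0, 7.0),
            ("g4", "c1", 2.0, 9.0, 9.0),       # never reaches the floor
            ("g4", "c2", 2.0, 8.0, 9.0),
            ("g5", "c1", 200.0, 30.0, 20.0),   # fruit-set peak, >5x down
            ("g5", "c2", 8.0, 7.0, 7.0),
            ("g6", "c1", 30.0, 35.0, 30.0),
            ("g6", "c2", 30.0, 32.0, 30.0),
        ]
        return pd.DataFrame(rows, columns=["gene", "genotype_class",
                                           "fruit_set", "veraison",
                                           "ripening"])

    def test_developmental_list_matches_hand_evaluation(self):
        result = deg_filter(self._tpm())
        assert result["developmental"] == ["g1", "g3", "g5"]

    def test_thresholds_are_inclusive(self):
        result = deg_filter(self._tpm())
        assert "g3" in result["developmental"]

    def test_between_class_list_requires_both_stages(self):
        tpm = self._tpm()
        padj_rows = []
        for gene in tpm["gene"].unique():
            for stage in ("veraison", "ripening"):
                padj_rows.append((gene, stage, 0.01))
        padj = pd.DataFrame(padj_rows, columns=["gene", "stage", "padj"])
        result = deg_filter(tpm, padj)
        # g1: veraison 100 vs 12 (8.3x), ripening 80 vs 11 (7.3x) -> passes
        assert "g1" in result["higher_in_first_class"]
        # g5: veraison 30 vs 7 (4.3x) -> fails the fold test at veraison
        assert "g5" not in result["higher_in_first_class"]

    def test_padj_threshold_excludes(self):
        tpm = self._tpm()
        padj = pd.DataFrame(
            [("g1", "veraison", 0.2), ("g1", "ripening", 0.01)],
            columns=["gene", "stage", "padj"])
        result = deg_filter(tpm, padj)
        assert result["higher_in_first_class"] == []

    def test_missing_stage_columns_rejected(self):
        bad = pd.DataFrame({"gene": ["g"], "genotype_class": ["c"],
                            "fruit_set": [1.0]})
        with pytest.raises(ValueError, match="missing column"):
            deg_filter(bad)
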