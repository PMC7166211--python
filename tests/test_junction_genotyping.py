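"""Junction templates, crossing-read counting, and genotype inference."""

import numpy as np
import pytest

from foxyloci.indel_detection import IndelCall, align_alleles
from foxyloci.junction_genotyping import (
    ConflictingDosageError,
    CrossingEvidence,
    JunctionTemplate,
    call_allele_presence,
    count_crossing_reads,
    element_templates,
    genotype_element,
    infer_diploid_genotype,
    insertion_templates,
    make_junction_template,
    make_insertion_templates,
    pcr_genotype,
)
from foxyloci.synthetic_locus import build_diploid, simulate_reads, revcomp


class TestTemplateConstruction:
    def test_default_flanks_give_160bp_templates(self, quartet):
        calls, _ = align_alleles(quartet["caco"], quartet["concord"])
        c = [x for x in calls if x.kind == "deletion"][0]
        tpl = make_junction_template(quartet["caco"], c)
        assert len(tpl.sequence) == 160
        assert tpl.junction_offset == 80

    def test_toy_deletion_template_equals_manual_flank_concatenation(self):
        ref = "ACGTTGCAAGGCTTACCGGATAACGTGCATTGCCAATGCG"  # 40 bp
        call = IndelCall("r", "a", "deletion", 15, 10, ref[15:25])
        tpl = make_junction_template(ref, call, flank=15)
        assert tpl.sequence == ref[0:15] + ref[25:40]
        assert tpl.junction_offset == 15

    def test_minimal_flank(self):
        ref = "AACCGGTT"
        call = IndelCall("r", "a", "deletion", 4, 2, "GG")
        tpl = make_junction_template(ref, call, flank=1)
        assert len(tpl.sequence) == 2 and tpl.junction_offset == 1

    def test_oversized_flank_names_the_side(self):
        ref = "AACCGGTT"
        call = IndelCall("r", "a", "deletion", 4, 2, "GG")
        with pytest.raises(ValueError, match="left"):
            make_junction_template(ref, call, flank=10)

    def test_insertion_templates_join_host_and_element_ends(self, quartet,
                                                            te_alleles):
        calls, _ = align_alleles(te_alleles["caco"], te_alleles["full_trim"])
        ins = [c for c in calls if c.kind == "insertion"][0]
        left, right = make_insertion_templates(te_alleles["caco"], ins,
                                               flank=80)
        host = te_alleles["caco"].sequence
        p, seg = ins.position, ins.segment
        assert left.sequence == host[p - 80:p] + seg[:80]
        assert right.sequence == seg[-80:] + host[p:p + 80]

    def test_template_ids_are_deterministic(self, quartet):
        a, _, _ = element_templates("el426", seed=0)
        b, _, _ = element_templates("el426", seed=0)
        assert a.template_id == b.template_id


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=160))
    return JunctionTemplate("toy", seq, 80, "deletion-junction")


class TestCrossingReads:

    def test_empty_read_set_gives_zero(self, template):
        ev = count_crossing_reads(template, [])
        assert ev.n_aligned == ev.n_crossing == 0

    def test_read_spanning_the_window_crosses(self, template):
        read = template.sequence[40:120]          # 1-based 41..120
        ev = count_crossing_reads(template, [read])
        assert (ev.n_aligned, ev.n_crossing) == (1, 1)

    def test_read_stopping_at_the_junction_aligns_but_does_not_cross(
            self, template):
        read = template.sequence[0:80]            # 1-based 1..80
        ev = count_crossing_reads(template, [read])
        assert (ev.n_aligned, ev.n_crossing) == (1, 0)

    def test_window_is_61_to_100_with_default_flanks(self, template):
        ev = count_crossing_reads(template, [])
        assert ev.window == (60, 99)              # 0-based == 1-based 61..100

    def test_reverse_complement_reads_count_identically(self, template):
        reads = [template.sequence[i:i + 90] for i in (0, 20, 35, 60)]
        fwd = count_crossing_reads(template, reads)
        rev = count_crossing_reads(template, [revcomp(r) for r in reads])
        assert (fwd.n_aligned, fwd.n_crossing) == (rev.n_aligned,
                                                   rev.n_crossing)

    def test_mismatch_tolerance_boundary(self, template):
        read = list(template.sequence[40:120])
        for i in (5, 30, 60):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        read = "".join(read)
        assert count_crossing_reads(template, [read],
                                    max_mismatch=2).n_crossing == 0
        assert count_crossing_reads(template, [read],
                                    max_mismatch=3).n_crossing == 1

    def test_crossing_count_grows_with_coverage(self):
        tpl, _, _ = element_templates("el426", seed=0)
        lows, highs = [], []
        for seed in range(3):
            d = build_diploid("x", "concord", "concord", seed=0)
            lows.append(count_crossing_reads(
                tpl, simulate_reads(d, coverage=10, seed=seed)).n_crossing)
            highs.append(count_crossing_reads(
                tpl, simulate_reads(d, coverage=40, seed=seed)).n_crossing)
        assert sum(highs) > sum(lows)


class TestGenotypeInference:
    def _ev(self, n):
        return CrossingEvidence("426:x:aaaa", max(n, 0) + 10, n, (60, 99))

    def test_presence_threshold_boundary(self):
        assert call_allele_presence(self._ev(0)) == "absent"
        assert call_allele_presence(self._ev(1)) == "absent"
        assert call_allele_presence(self._ev(2)) == "present"

    @pytest.mark.parametrize("junction,internal,expected", [
        (5, 5, "0/426"), (5, 0, "0/0"), (0, 5, "426/426"), (0, 0, "-/-"),
    ])
    def test_decision_table(self, junction, internal, expected):
        call = infer_diploid_genotype(self._ev(junction), self._ev(internal),
                                      "426")
        assert call.genotype_string == expected

    def test_dosage_demotes_homozygous_to_single_copy(self):
        call = infer_diploid_genotype(self._ev(0), self._ev(5), "426",
                                      dosage_ratio=0.4)
        assert call.genotype_string == "426/-"
        call = infer_diploid_genotype(self._ev(5), self._ev(0), "426",
                                      dosage_ratio=0.4)
        assert call.genotype_string == "0/-"

    def test_conflicting_dosage_is_an_error(self):
        with pytest.raises(ConflictingDosageError):
            infer_diploid_genotype(self._ev(5), self._ev(5), "426",
                                   dosage_ratio=0.4)

    def test_heterozygote_called_from_simulated_reads(self, het_reads):
        d, reads = het_reads
        call = genotype_element(reads, "el426", accession="het", seed=0)
        assert call.genotype_string == "0/426"


class TestPCRGenotype:
    def test_junction_and_internal_positive_is_heterozygous(self):
        assays = [("junction", True, 300), ("internal", True, 350)]
        assert pcr_genotype(assays, "426") == "0/426"

    def test_full_span_band_only_confirms_homozygous_presence(self):
        assays = [("junction", False, None), ("internal", True, 350),
                  ("span", True, 900)]
        assert pcr_genotype(assays, "426", indel_length=426,
                            span_ref_size=900) == "426/426"

    def test_all_negative_means_locus_not_detected(self):
        assays = [("junction", False, None), ("internal", False, None),
                  ("span", False, None)]
        assert pcr_genotype(assays, "426") == "-/-"

    def test_assay_outcome_table_against_all_genotype_classes(self):
        # enumerate (junction, internal, span bands) for each true genotype
        full, short = 900, 900 - 426
        cases = {
            "0/0": (True, False, {short}),
            "0/426": (True, True, {full, short}),
            "426/426": (False, True, {full}),
            "-/-": (False, False, set()),
        }
        for expected, (j, i, bands) in cases.items():
            assays = [("junction", j, None), ("internal", i, None)]
            assays += [("span", True, b) for b in sorted(bands)]
            if not bands:
                assays.append(("span", False, None))
            assert pcr_genotype(assays, "426", indel_length=426,
                                span_ref_size=full) == expected

    def test_inconsistent_band_sizes_are_uninterpretable_not_an_error(self):
        assays = [("junction", True, None), ("internal", False, None),
                  ("span", True, 900)]      # deletion-only call but full band
        assert pcr_genotype(assays, "426", indel_length=426,
                            span_ref_size=900) == "uninterpretable"

    def test_missing_required_assays_rejected(self):
        with pytest.raises(ValueError, match="required"):
            pcr_genotype([("span", True, 500)], "426")


class TestInsertionAmbiguity:
    def test_solo_and_full_insertions_yield_identical_presence_calls(self):
        left, right = insertion_templates(seed=0)
        calls = {}
        for kind in ("solo_ltr", "full_trim"):
            d = build_diploid("x", kind, kind, seed=0)
            reads = simulate_reads(d, coverage=30, seed=11)
            calls[kind] = tuple(
                call_allele_presence(count_crossing_reads(t, reads))
                for t in (left, right))
        assert calls["solo_ltr"] == calls["full_trim"] == ("present",
                                                           "present")
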