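"""End-to-end orchestration: simulate -> genotype -> signatures -> te ->
associate, with deterministic artifacts and a checksum manifest.

The default panel mirrors the germplasm survey's genotype classes: juice-
grape-like accessions lacking the 426-bp element, wine-grape-like carriers,
a whole-locus-loss accession, promoter-deletion heterozygotes, exonic
retroelement carriers, and one high-expression/low-metabolite discordant
accession.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from foxyloci import association as assoc
from foxyloci import indel_detection as indet
from foxyloci import junction_genotyping as jg
from foxyloci import repeat_signature as rs
from foxyloci import te_classifier as tec
from foxyloci import synthetic_locus as sl

DEFAULT_PANEL: list[tuple[str, str, str]] = [
    ("Concord", "concord", "concord"),
    ("Catawba", "concord", "del3kb"),
    ("Semillon", "semillon", "semillon"),
    ("Merlot", "caco", "del3kb"),
    ("Caco", "caco", "caco"),
    ("Alba", "alba", "alba"),
    ("PinotNoir", "caco", "solo_ltr"),
    ("Chardonnay", "del3kb", "full_trim"),
    ("Hybrid1", "concord", "caco"),
    ("Hubbard", "concord", "concord"),
]
DEFAULT_DISCORDANT = frozenset({"Hubbard"})


@dataclass
class RunConfig:
    panel: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_PANEL))
    baseline: str = "Merlot"
    coverage: float = 30.0
    read_len: int = 150
    error_rate: float = 0.0
    ct_noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 1
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "genotype": True, "signatures": True,
        "te": True, "associate": True})
    discordant: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_DISCORDANT))
    outdir: str = "foxyloci_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["panel"] = [tuple(p) for p in data.get("panel", [])]
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, accession: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {accession!r}: {cause}")
        self.stage, self.accession = stage, accession


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute enabled stages in order; returns the per-accession summary.

    Artifacts (FASTA/FASTQ/TSV) are written under ``config.outdir`` together
    with a sha256 checksum manifest; reruns with the same config are
    byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict[str, dict] = {}

    diploids = [sl.build_diploid(acc, a, b, seed=config.seed)
                for acc, a, b in config.panel]
    reads_by_acc: dict[str, list] = {}

    if config.stages.get("simulate", True):
        for i, d in enumerate(diploids):
            try:
                alleles = [al for al in (d.allele_a, d.allele_b)
                           if al.sequence]
                if alleles:
                    fa = out / f"{d.accession}.alleles.fasta"
                    sl.write_fasta(alleles, fa)
                    written.append(fa)
                reads = sl.simulate_reads(
                    d, coverage=config.coverage, read_len=config.read_len,
                    error_rate=config.error_rate,
                    seed=(config.seed * 1000 + i) & 0x7FFFFFFF)
                reads_by_acc[d.accession] = reads
                fq = out / f"{d.accession}.reads.fastq"
                sl.write_fastq(reads, fq)
                written.append(fq)
            except Exception as exc:
                raise StageError("simulate", d.accession, exc) from exc
        truth = pd.DataFrame(
            [(d.accession, d.genotype_string("el426"),
              d.genotype_string("el42")) for d in diploids],
            columns=["accession", "genotype_426", "genotype_42"])
        p = out / "genotype_truth.tsv"
        truth.to_csv(p, sep="\t", index=False)
        written.append(p)

    if config.stages.get("genotype", True):
        rows = []
        for d in diploids:
            try:
                reads = reads_by_acc.get(d.accession, [])
                call426 = jg.genotype_element(reads, "el426",
                                              accession=d.accession,
                                              seed=config.seed)
                call42 = jg.genotype_element(reads, "el42",
                                             accession=d.accession,
                                             seed=config.seed)
                rows.append((d.accession, call426.genotype_string,
                             call42.genotype_string))
                summary.setdefault(d.accession, {})["genotype_426"] = \
                    call426.genotype_string
                summary[d.accession]["genotype_42"] = call42.genotype_string
            except Exception as exc:
                raise StageError("genotype", d.accession, exc) from exc
        p = out / "genotype_calls.tsv"
        pd.DataFrame(rows, columns=["accession", "genotype_426",
                                    "genotype_42"]).to_csv(
            p, sep="\t", index=False)
        written.append(p)

    if config.stages.get("signatures", True):
        rows = []
        for element in ("el426", "el26", "el42", "del3kb"):
            bearing, lacking, label = jg._ELEMENT_PAIRS[element]
            ref = sl.build_promoter_haplotype(
                sl.canonical_spec(bearing, config.seed))
            alt = sl.build_promoter_haplotype(
                sl.canonical_spec(lacking, config.seed))
            calls, _ = indet.align_alleles(ref, alt)
            for c in calls:
                if c.kind != "deletion":
                    continue
                sig = rs.signature_for_indel(ref, c, indel_id=label)
                rows.append((label, c.length, sig.direct_repeat.sequence,
                             sig.direct_repeat.length,
                             len(sig.inverted_repeats),
                             sig.slippage_compatible))
        p = out / "repeat_signatures.tsv"
        pd.DataFrame(rows, columns=["indel", "length", "dr_seq", "dr_len",
                                    "n_inverted_repeats",
                                    "slippage_compatible"]).to_csv(
            p, sep="\t", index=False)
        written.append(p)
        for acc in summary:
            summary[acc]["signatures_ok"] = all(r[5] for r in rows)

    te_class_by_acc: dict[str, str] = {}
    if config.stages.get("te", True):
        host = sl.build_promoter_haplotype(sl.canonical_spec("caco",
                                                             config.seed))
        rows = []
        for d in diploids:
            for al in (d.allele_a, d.allele_b):
                if al.spec.exon2_insertion == "none" or not al.sequence:
                    continue
                te = tec.decompose_insertion(al, host)
                te_class_by_acc[d.accession] = te.te_class
                rows.append((d.accession, al.spec.name, te.tsd[0], te.tsd[1],
                             te.te_class, te.apparent_locus_size))
        p = out / "te_insertions.tsv"
        pd.DataFrame(rows, columns=["accession", "allele", "tsd_seq",
                                    "tsd_len", "te_class",
                                    "apparent_locus_size"]).to_csv(
            p, sep="\t", index=False)
        written.append(p)

    if config.stages.get("associate", True):
        model = sl.ExpressionEffectModel(baseline=config.baseline,
                                         ct_noise_sd=config.ct_noise_sd,
                                         replicates=config.replicates)
        ct = sl.simulate_expression_panel(diploids, model,
                                          seed=config.seed + 17)
        p = out / "ct_table.tsv"
        ct.to_csv(p, sep="\t", index=False)
        written.append(p)
        folds = assoc.ddct_fold(ct, config.baseline)
        fold_df = pd.DataFrame([(f.accession, f.fold, *f.fold_range)
                                for f in folds],
                               columns=["accession", "fold", "fold_lo",
                                        "fold_hi"])
        p = out / "expression_folds.tsv"
        fold_df.to_csv(p, sep="\t", index=False)
        written.append(p)
        ma = sl.simulate_ma_panel(
            fold_df, sl.MAConcordanceModel(
                discordant=frozenset(config.discordant)),
            seed=config.seed + 23)
        p = out / "ma_table.tsv"
        ma.to_csv(p, sep="\t", index=False)
        written.append(p)
        genos = [jg.GenotypeCall(accession=d.accession, indel_id="426",
                                 genotype_string=d.genotype_string("el426"))
                 for d in diploids]
        groups = assoc.group_stats(folds, genos)
        p = out / "genotype_groups.tsv"
        pd.DataFrame([(g.label, ";".join(g.members), g.mean_fold, g.se)
                      for g in groups],
                     columns=["group", "members", "mean_fold",
                              "se"]).to_csv(p, sep="\t", index=False)
        written.append(p)
        rho, discordant, violating = assoc.concordance(folds, ma)
        p = out / "concordance.json"
        p.write_text(json.dumps({"spearman_rho": rho,
                                 "discordant": discordant,
                                 "model_violating": violating},
                                indent=1, sort_keys=True))
        written.append(p)
        group_of = {m: g.label for g in groups for m in g.members}
        for f in folds:
            summary.setdefault(f.accession, {})["fold"] = round(f.fold, 4)
            summary[f.accession]["group"] = group_of.get(f.accession, "")

    for acc, klass in te_class_by_acc.items():
        summary.setdefault(acc, {})["te_class"] = klass

    report = pd.DataFrame(
        [{"accession": acc, **vals} for acc, vals in sorted(summary.items())])
    if not report.empty:
        p = out / "summary.tsv"
        report.to_csv(p, sep="\t", index=False)
        written.append(p)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return report


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> Path:
    """Small worked-example inputs: the canonical allele quartet, a toy read
    set and a noise-free Ct table, with a checksum manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    alleles = [sl.build_promoter_haplotype(sl.canonical_spec(k, seed))
               for k in ("caco", "pn40024", "concord", "alba")]
    sl.write_fasta(alleles, out / "quartet.fasta")
    d = sl.build_diploid("toy", "concord", "caco", seed=seed)
    reads = sl.simulate_reads(d, coverage=5, read_len=100, seed=seed)
    sl.write_fastq(reads, out / "toy.reads.fastq")
    panel = [sl.build_diploid(a, x, y, seed=seed) for a, x, y in
             [("Merlot", "caco", "del3kb"), ("Concord", "concord", "concord")]]
    model = sl.ExpressionEffectModel(baseline="Merlot")
    ct = sl.simulate_expression_panel(panel, model, seed=seed)
    ct.to_csv(out / "toy.ct.tsv", sep="\t", index=False)
    files = ["quartet.fasta", "toy.reads.fastq", "toy.ct.tsv"]
    manifest = {f: _sha256(out / f) for f in files}
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out
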