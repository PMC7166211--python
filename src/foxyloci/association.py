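"""Relative-expression analysis and genotype-group association.

Implements the comparative ddCt method (fold = 2**(-ddCt) against a
baseline accession, with a fold range from the replicate ΔCt standard
deviation), genotype-group summaries (mean fold and standard error across
accessions), expression/metabolite concordance with one-sided discordance
flags, and the transcriptome pre-filters (TPM and fold-change thresholds)
used to shortlist developmentally regulated, genotype-differential genes.
Amplification efficiency is fixed at exact doubling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from foxyloci.junction_genotyping import GenotypeCall


@dataclass(frozen=True)
class FoldResult:
    accession: str
    fold: float
    fold_range: tuple[float, float]


@dataclass
class GenotypeGroup:
    label: str
    members: list[str]
    mean_fold: float
    se: float


def _check_ct_table(ct: pd.DataFrame) -> None:
    required = {"accession", "replicate", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    missing = []
    for acc, grp in ct.groupby("accession"):
        genes = set(grp["gene"])
        if not {"target", "reference"}.issubset(genes):
            missing.append(acc)
    if missing:
        raise ValueError(f"missing reference- or target-gene rows for: "
                         f"{sorted(missing)}")


def ddct_fold(ct: pd.DataFrame, baseline: str) -> list[FoldResult]:
    """Per-accession fold change vs the baseline accession.

    ΔCt = Ct_target - Ct_reference per replicate; ΔΔCt = mean ΔCt(accession)
    - mean ΔCt(baseline); fold = 2**(-ΔΔCt); the fold range spans
    2**(-(ΔΔCt ± sd(ΔCt))). The baseline's fold is exactly 1.
    """
    _check_ct_table(ct)
    if baseline not in set(ct["accession"]):
        raise ValueError(f"baseline accession {baseline!r} not in table")
    wide = ct.pivot_table(index=["accession", "replicate"], columns="gene",
                          values="ct")
    dct = (wide["target"] - wide["reference"]).rename("dct").reset_index()
    base_mean = dct.loc[dct["accession"] == baseline, "dct"].mean()
    out = []
    for acc, grp in dct.groupby("accession", sort=False):
        ddct = grp["dct"].mean() - base_mean
        sd = grp["dct"].std(ddof=1) if len(grp) > 1 else 0.0
        if acc == baseline:
            ddct = 0.0
        fold = float(2.0 ** (-ddct))
        lo = float(2.0 ** (-(ddct + sd)))
        hi = float(2.0 ** (-(ddct - sd)))
        out.append(FoldResult(accession=acc, fold=fold, fold_range=(lo, hi)))
    return out


# ---------------------------------------------------------------------------
# genotype grouping

# Table-style default grouping over the large-element genotype: accessions
# lacking the element on one/both detected alleles vs carrying it on all.
def default_grouping(call_426: str) -> str:
    alleles = [a for a in call_426.split("/")]
    present = sum(a not in ("0", "-") for a in alleles)
    absent = sum(a == "0" for a in alleles)
    if absent == 2:
        return "element absent (0/0)"
    if absent == 1 and present == 1:
        return "heterozygous (0/X)"
    if absent == 1:
        return "element absent (0/-)"
    if present >= 1:
        return "element present (X/X or X/-)"
    return "locus not detected"


def group_stats(folds: list[FoldResult], genotypes: list[GenotypeCall],
                grouping_scheme=None) -> list[GenotypeGroup]:
    """Mean fold and SE per genotype group.

    ``grouping_scheme`` maps a genotype string to a group label (defaults to
    the element-present/absent scheme). SE is across accessions, not
    replicates. Accessions with no matching group land in 'ungrouped';
    empty groups are simply not emitted.
    """
    scheme = grouping_scheme or default_grouping
    fold_by_acc = {f.accession: f.fold for f in folds}
    geno_by_acc = {g.accession: g.genotype_string for g in genotypes}
    missing = set(fold_by_acc) ^ set(geno_by_acc)
    if missing:
        raise ValueError(f"accessions without both fold and genotype: "
                         f"{sorted(missing)}")
    buckets: dict[str, list[str]] = {}
    for acc, geno in geno_by_acc.items():
        label = scheme(geno)
        if label is None:
            label = "ungrouped"
        buckets.setdefault(label, []).append(acc)
    groups = []
    for label, members in buckets.items():
        vals = np.array([fold_by_acc[m] for m in sorted(members)])
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        groups.append(GenotypeGroup(label=label, members=sorted(members),
                                    mean_fold=float(vals.mean()), se=se))
    groups.sort(key=lambda g: g.label)
    return groups


# ---------------------------------------------------------------------------
# expression / metabolite concordance


def concordance(folds: list[FoldResult], ma: pd.DataFrame,
                expr_high: float = 10.0, ma_low: float = 2.0,
                expr_low: float = 2.0, ma_high: float = 10.0):
    """Rank correlation between expression folds and MA values.

    Returns (spearman rho or None with <3 pairs, discordant accessions,
    model-violating accessions). Discordant = high expression but low MA —
    the tolerated direction. Low expression with high MA violates the
    expression-drives-metabolite model and is flagged separately.
    """
    ma_by_acc = dict(zip(ma["accession"], ma["ma"]))
    paired = [(f.accession, f.fold, ma_by_acc[f.accession])
              for f in folds if f.accession in ma_by_acc]
    if len(paired) < 3:
        rho = None
    else:
        rho = float(stats.spearmanr([p[1] for p in paired],
                                    [p[2] for p in paired]).statistic)
    discordant = [a for a, f, m in paired if f >= expr_high and m <= ma_low]
    violating = [a for a, f, m in paired if f <= expr_low and m >= ma_high]
    return rho, discordant, violating


# ---------------------------------------------------------------------------
# transcriptome pre-filters


STAGES = ("fruit_set", "veraison", "ripening")


def deg_filter(tpm: pd.DataFrame, padj: pd.DataFrame | None = None,
               tpm_min: float = 50.0, fold_min: float = 5.0,
               padj_max: float = 0.05) -> dict[str, list[str]]:
    """Developmental and genotype-differential gene shortlists.

    ``tpm``: columns gene, genotype_class, fruit_set, veraison, ripening.
    List A (developmental): genes reaching ``tpm_min`` TPM at fruit set or
    veraison in either class AND >= ``fold_min`` between those stages (in a
    class where the TPM floor holds). List B (requires ``padj``: columns
    gene, stage, padj): genes with between-class fold >= ``fold_min`` and
    padj <= ``padj_max`` at BOTH veraison and ripening, split by direction.
    Thresholds are inclusive.
    """
    for col in ("gene", "genotype_class", *STAGES):
        if col not in tpm.columns:
            raise ValueError(f"tpm table missing column {col!r}")

    def _fold(a: float, b: float) -> float:
        lo, hi = min(a, b), max(a, b)
        return np.inf if lo == 0 else hi / lo

    list_a = []
    for gene, grp in tpm.groupby("gene", sort=False):
        ok = False
        for _, row in grp.iterrows():
            fs, ver = row["fruit_set"], row["veraison"]
            if max(fs, ver) >= tpm_min and _fold(fs, ver) >= fold_min:
                ok = True
        if ok:
            list_a.append(gene)

    result = {"developmental": list_a}
    if padj is not None:
        classes = sorted(tpm["genotype_class"].unique())
        if len(classes) != 2:
            raise ValueError("between-class filter needs exactly two classes")
        up, down = [], []
        pv = padj.set_index(["gene", "stage"])["padj"]
        wide = tpm.set_index(["gene", "genotype_class"])
        for gene in tpm["gene"].unique():
            dirs = []
            passed = True
            for stage in ("veraison", "ripening"):
                try:
                    a = wide.loc[(gene, classes[0]), stage]
                    b = wide.loc[(gene, classes[1]), stage]
                    p = pv.loc[(gene, stage)]
                except KeyError:
                    passed = False
                    break
                if _fold(a, b) < fold_min or p > padj_max:
                    passed = False
                    break
                dirs.append(a >= b)
            if passed and len(set(dirs)) == 1:
                (up if dirs[0] else down).append(gene)
        result["higher_in_first_class"] = up
        result["higher_in_second_class"] = down
    return result
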