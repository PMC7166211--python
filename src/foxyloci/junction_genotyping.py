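"""Junction-template construction and presence/absence genotyping.

A deletion is detected by a 160-bp template (80 bp of flank on each side of
the joined deletion boundary, i.e. the sequence of the deletion-carrying
allele) and the element's presence by a template centered on the element's
5' boundary in the element-bearing allele. Reads whose ungapped alignment
covers the central crossing window (>=20 bp each side of the junction;
template positions 61-100 with default flanks) support the corresponding
allele. Insertions use a mirrored pair of templates, one per insertion
boundary — which, deliberately, cannot tell a solo LTR from a full
terminal-repeat element, since both produce the same junction sequences.

The same presence/absence decision table also drives the PCR-assay
interpreter (junction-crossing primer pair, indel-internal pair, and a
flanking span assay whose shortened band confirms a deletion allele).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from foxyloci.indel_detection import IndelCall, align_alleles
from foxyloci.synthetic_locus import (
    Allele,
    SimRead,
    build_promoter_haplotype,
    canonical_spec,
    revcomp,
)

DEFAULT_FLANK = 80
DEFAULT_WINDOW_MARGIN = 20     # bases required on each side of the junction
DEFAULT_MIN_READS = 2
DEFAULT_MAX_MISMATCH = 2
MIN_OVERLAP = 24               # smallest read/template overlap considered aligned


@dataclass(frozen=True)
class JunctionTemplate:
    indel_id: str
    sequence: str
    junction_offset: int       # junction lies between offset-1 and offset
    side: str                  # deletion-junction | insertion-left |
                               # insertion-right | element-internal

    @property
    def template_id(self) -> str:
        h = hashlib.sha1(f"{self.indel_id}:{self.side}".encode()).hexdigest()
        return f"{self.indel_id}:{self.side}:{h[:8]}"

    def crossing_window(self, margin: int = DEFAULT_WINDOW_MARGIN
                        ) -> tuple[int, int]:
        """Inclusive 0-based template interval a crossing read must cover."""
        return (self.junction_offset - margin, self.junction_offset + margin - 1)


@dataclass(frozen=True)
class CrossingEvidence:
    template_id: str
    n_aligned: int
    n_crossing: int
    window: tuple[int, int]

    def __post_init__(self):
        assert 0 <= self.n_crossing <= self.n_aligned


@dataclass(frozen=True)
class GenotypeCall:
    accession: str
    indel_id: str
    genotype_string: str
    evidence: tuple[CrossingEvidence, CrossingEvidence] | None = None


class ConflictingDosageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# template construction


def make_junction_template(ref: Allele | str, indel: IndelCall,
                           flank: int = DEFAULT_FLANK,
                           side: str = "deletion-junction") -> JunctionTemplate:
    """Deletion-junction or element-internal template from the element-bearing
    reference and a normalized deletion call against it."""
    seq = ref.sequence if hasattr(ref, "sequence") else ref
    if flank < 1:
        raise ValueError("flank must be >= 1")
    p, L = indel.position, indel.length
    if p - flank < 0:
        raise ValueError("flank exceeds available sequence on the left side")
    if side == "deletion-junction":
        if p + L + flank > len(seq):
            raise ValueError("flank exceeds available sequence on the right side")
        tpl = seq[p - flank:p] + seq[p + L:p + L + flank]
    elif side == "element-internal":
        if p + flank > len(seq):
            raise ValueError("flank exceeds available sequence on the right side")
        tpl = seq[p - flank:p + flank]
    else:
        raise ValueError(f"unknown side {side!r}")
    return JunctionTemplate(indel_id=f"{indel.ref_name}:{p}:{L}",
                            sequence=tpl, junction_offset=flank, side=side)


def make_insertion_templates(ref: Allele | str, indel: IndelCall,
                             flank: int = DEFAULT_FLANK
                             ) -> tuple[JunctionTemplate, JunctionTemplate]:
    """Left/right boundary templates on the insertion-bearing allele:
    host flank joined to the insertion's 5' end, and the insertion's 3' end
    joined to the host's right flank."""
    seq = ref.sequence if hasattr(ref, "sequence") else ref
    p, seg = indel.position, indel.segment
    if indel.kind != "insertion":
        raise ValueError("expected an insertion call")
    if len(seg) < flank:
        raise ValueError("flank exceeds the insertion length")
    if p - flank < 0:
        raise ValueError("flank exceeds available sequence on the left side")
    if p + flank > len(seq):
        raise ValueError("flank exceeds available sequence on the right side")
    iid = f"{indel.ref_name}:{p}:ins{len(seg)}"
    left = JunctionTemplate(iid, seq[p - flank:p] + seg[:flank], flank,
                            "insertion-left")
    right = JunctionTemplate(iid, seg[-flank:] + seq[p:p + flank], flank,
                             "insertion-right")
    return left, right


# ---------------------------------------------------------------------------
# read counting


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _best_ungapped(read: str, tpl: str, idx: dict[str, list[int]], k: int,
                   stride: int) -> tuple[int, int, int] | None:
    """Best (mismatches, start, end) of an ungapped read/template overlay.

    Candidate offsets come from shared k-mers sampled along the read; the
    covered template interval is [start, end) and must be >= MIN_OVERLAP.
    """
    n, m = len(read), len(tpl)
    positions = list(range(0, n - k + 1, stride))
    if positions and positions[-1] != n - k:
        positions.append(n - k)
    offsets = set()
    for rp in positions:
        for tp in idx.get(read[rp:rp + k], ()):
            offsets.add(tp - rp)
    best = None
    for off in offsets:
        t0 = max(0, off)
        t1 = min(m, off + n)
        if t1 - t0 < MIN_OVERLAP:
            continue
        mism = sum(1 for t in range(t0, t1) if tpl[t] != read[t - off])
        if best is None or mism < best[0]:
            best = (mism, t0, t1)
    return best


def count_crossing_reads(template: JunctionTemplate,
                         reads: list[SimRead] | list[str],
                         max_mismatch: int = DEFAULT_MAX_MISMATCH,
                         window_margin: int = DEFAULT_WINDOW_MARGIN,
                         kmer: int = 16, stride: int = 8) -> CrossingEvidence:
    """Count reads aligned to the template and those crossing the junction.

    A read crosses iff its best ungapped alignment (either strand) has at
    most ``max_mismatch`` mismatches and covers the whole crossing window.
    """
    w0, w1 = template.crossing_window(window_margin)
    idx = _kmer_index(template.sequence, kmer)
    n_aligned = n_crossing = 0
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        best = None
        for oriented in (seq, revcomp(seq)):
            cand = _best_ungapped(oriented, template.sequence, idx, kmer,
                                  stride)
            if cand is not None and (best is None or cand[0] < best[0]):
                best = cand
        if best is None or best[0] > max_mismatch:
            continue
        n_aligned += 1
        if best[1] <= w0 and best[2] >= w1 + 1:
            n_crossing += 1
    return CrossingEvidence(template_id=template.template_id,
                            n_aligned=n_aligned, n_crossing=n_crossing,
                            window=(w0, w1))


def call_allele_presence(ev: CrossingEvidence,
                         min_reads: int = DEFAULT_MIN_READS) -> str:
    return "present" if ev.n_crossing >= min_reads else "absent"


# ---------------------------------------------------------------------------
# genotype inference


def infer_diploid_genotype(junction_ev: CrossingEvidence,
                           internal_ev: CrossingEvidence,
                           indel_label: str,
                           accession: str = "",
                           min_reads: int = DEFAULT_MIN_READS,
                           dosage_ratio: float | None = None,
                           dosage_threshold: float = 0.65) -> GenotypeCall:
    """Decision table over (deletion-junction, element-internal) evidence.

    junction present & internal present -> heterozygous 0/X;
    junction only -> 0/0; internal only -> X/X; neither -> -/-.
    A sub-unity locus dosage (depth at the locus over a control region,
    below ``dosage_threshold``) demotes the homozygous calls to single-copy
    (0/- or X/-); dosage evidence conflicting with a heterozygous call is
    an error.
    """
    j = call_allele_presence(junction_ev, min_reads) == "present"
    i = call_allele_presence(internal_ev, min_reads) == "present"
    single = dosage_ratio is not None and dosage_ratio < dosage_threshold
    if j and i:
        if single:
            raise ConflictingDosageError(
                "both alleles observed but locus dosage indicates one copy")
        g = f"0/{indel_label}"
    elif j:
        g = "0/-" if single else "0/0"
    elif i:
        g = f"{indel_label}/-" if single else f"{indel_label}/{indel_label}"
    else:
        g = "-/-"
    return GenotypeCall(accession=accession,
                        indel_id=junction_ev.template_id.split(":")[0],
                        genotype_string=g,
                        evidence=(junction_ev, internal_ev))


def pcr_genotype(assays, indel_label: str, indel_length: int | None = None,
                 span_ref_size: int | None = None) -> str:
    """Interpret PCR assay outcomes into a genotype string.

    ``assays``: iterable of (kind, band_observed, band_size) with kind in
    {'junction', 'internal', 'span'}; band_size may be None. The junction
    assay is positive when the indel is absent in at least one allele, the
    internal assay when it is present in at least one allele; a span assay
    band shorter by the indel length confirms the deletion allele.
    Inconsistent band sizes yield 'uninterpretable' rather than an error.
    """
    kinds = {a[0] for a in assays}
    if "junction" not in kinds or "internal" not in kinds:
        raise ValueError("junction-crossing and indel-internal assays required")
    j = any(a[1] for a in assays if a[0] == "junction")
    i = any(a[1] for a in assays if a[0] == "internal")
    if j and i:
        base = f"0/{indel_label}"
    elif j:
        base = "0/0"
    elif i:
        base = f"{indel_label}/{indel_label}"
    else:
        base = "-/-"

    span = [a for a in assays if a[0] == "span"]
    if span and span_ref_size is not None and indel_length is not None:
        sizes = {a[2] for a in span if a[1] and a[2] is not None}
        if base == "-/-":
            return base if not sizes else "uninterpretable"
        has_full = span_ref_size in sizes
        has_short = (span_ref_size - indel_length) in sizes
        if sizes - {span_ref_size, span_ref_size - indel_length}:
            return "uninterpretable"
        if j and i and not (has_full and has_short):
            return "uninterpretable"
        if j and not i and (has_full or not has_short):
            return "uninterpretable"
        if i and not j and (has_short or not has_full):
            return "uninterpretable"
    return base


# ---------------------------------------------------------------------------
# end-to-end convenience: element templates and diploid genotyping


_ELEMENT_PAIRS = {
    # element -> (bearing archetype, lacking archetype, size label)
    "el426": ("caco", "concord", "426"),
    "el400": ("pn40024", "concord", "400"),
    "el26": ("caco", "pn40024", "26"),
    "el42": ("caco", "alba", "42"),
    "del3kb": ("caco", "del3kb", "3kb"),
}


def element_templates(element: str, seed: int = 0,
                      flank: int = DEFAULT_FLANK
                      ) -> tuple[JunctionTemplate, JunctionTemplate, str]:
    """(deletion-junction template, element-internal template, size label)
    for one promoter element, built from archetype alleles that share the
    given background seed."""
    bearing, lacking, label = _ELEMENT_PAIRS[element]
    ref = build_promoter_haplotype(canonical_spec(bearing, seed))
    alt = build_promoter_haplotype(canonical_spec(lacking, seed))
    calls, _ = align_alleles(ref, alt)
    dels = [c for c in calls if c.kind == "deletion"]
    if len(dels) != 1:
        raise RuntimeError(f"expected one deletion between {bearing} and "
                           f"{lacking}, got {len(dels)}")
    call = dels[0]
    junction = make_junction_template(ref, call, flank, "deletion-junction")
    internal = make_junction_template(ref, call, flank, "element-internal")
    return junction, internal, label


def insertion_templates(seed: int = 0, flank: int = DEFAULT_FLANK
                        ) -> tuple[JunctionTemplate, JunctionTemplate]:
    """Exon-2 insertion boundary templates (solo LTR and full TRIM share them
    up to the template length, so either archetype serves)."""
    without = build_promoter_haplotype(canonical_spec("caco", seed))
    with_te = build_promoter_haplotype(canonical_spec("full_trim", seed))
    calls, _ = align_alleles(without, with_te)
    ins = [c for c in calls if c.kind == "insertion"]
    if len(ins) != 1:
        raise RuntimeError("expected a single insertion call")
    return make_insertion_templates(without, ins[0], flank)


def genotype_element(reads, element: str, accession: str = "",
                     seed: int = 0, flank: int = DEFAULT_FLANK,
                     min_reads: int = DEFAULT_MIN_READS,
                     max_mismatch: int = DEFAULT_MAX_MISMATCH,
                     dosage_ratio: float | None = None) -> GenotypeCall:
    """Genotype one promoter element from a read collection."""
    junction, internal, label = element_templates(element, seed, flank)
    jev = count_crossing_reads(junction, reads, max_mismatch)
    iev = count_crossing_reads(internal, reads, max_mismatch)
    return infer_diploid_genotype(jev, iev, label, accession=accession,
                                  min_reads=min_reads,
                                  dosage_ratio=dosage_ratio)
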