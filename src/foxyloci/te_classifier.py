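"""Decomposition of exonic retroelement insertions.

An LTR retroelement integrates with a short target-site duplication (TSD);
a full terminal-repeat retrotransposon in miniature (TRIM) is two
near-identical long terminal repeats around a short internal region, and
intra-element recombination between the two LTRs collapses it to a solo
LTR at the same site, keeping the TSD. The classifier detects the TSD from
an allele pair, finds near-identical terminal repeats inside the insertion
by banded alignment, classes the insertion (soloLTR / fullTRIM / unknown),
and predicts the locus footprint of the LTR-LTR recombination product.

``apparent_locus_size`` is the number of inserted bases seen at the locus:
the element plus one TSD copy (a 499-bp solo LTR with a 5-bp TSD appears
as 504 inserted bases; a 499+188+496 TRIM as 1188).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from foxyloci.indel_detection import IndelCall, align_alleles
from foxyloci.synthetic_locus import Allele

DEFAULT_MAX_TSD = 10
DEFAULT_MIN_LTR = 50
DEFAULT_MIN_IDENTITY = 0.9
BAND = 10
SOLO_LENGTH_RANGE = (400, 700)     # heuristic when no LTR reference is given


@dataclass
class TEInsertion:
    insertion_sequence: str               # element only, without the TSD copy
    locus_flanks: tuple[str, str]
    tsd: tuple[str, int]
    ltr5: tuple[int, int] | None = None   # [start, end) within the insertion
    internal: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    te_class: str = "unknown"

    @property
    def apparent_locus_size(self) -> int:
        return len(self.insertion_sequence) + self.tsd[1]


def _single_insertion(with_ins: Allele | str, without: Allele | str
                      ) -> IndelCall:
    calls, _ = align_alleles(without, with_ins)
    ins = [c for c in calls if c.kind == "insertion"]
    if len(ins) != 1 or len(calls) != len(ins):
        raise ValueError(
            "alleles must differ by exactly one insertion "
            f"(got {len(ins)} insertions among {len(calls)} indels)")
    return ins[0]


def detect_tsd(with_insertion: Allele | str, without_insertion: Allele | str,
               max_tsd: int = DEFAULT_MAX_TSD) -> tuple[str, int]:
    """Target-site duplication from an insertion-bearing/insertion-free pair.

    With the insertion left-aligned, the duplicated k bases are the segment's
    leading k bases repeated immediately 3' of the insertion point in the
    insertion-free allele (equivalently, right-aligned: the flank's trailing
    k bases equal the segment's terminal k bases). Returns ('', 0) when no
    duplication exists.
    """
    call = _single_insertion(with_insertion, without_insertion)
    host = (without_insertion.sequence
            if isinstance(without_insertion, Allele) else without_insertion)
    p, seg = call.position, call.segment
    k = 0
    while (k < max_tsd and k < len(seg) and p + k < len(host)
           and seg[k] == host[p + k]):
        k += 1
    return (seg[:k], k)


def decompose_insertion(with_insertion: Allele | str,
                        without_insertion: Allele | str,
                        max_tsd: int = DEFAULT_MAX_TSD,
                        min_ltr: int = DEFAULT_MIN_LTR,
                        min_identity: float = DEFAULT_MIN_IDENTITY,
                        ltr_reference: str | None = None) -> TEInsertion:
    """Full decomposition: TSD, terminal repeats, class."""
    call = _single_insertion(with_insertion, without_insertion)
    host = (without_insertion.sequence
            if isinstance(without_insertion, Allele) else without_insertion)
    tsd_seq, tsd_len = detect_tsd(with_insertion, without_insertion, max_tsd)
    # element = inserted bases minus the duplicated copy at the segment start
    element = call.segment[tsd_len:]
    p = call.position
    te = TEInsertion(insertion_sequence=element,
                     locus_flanks=(host[max(0, p - 80):p + tsd_len],
                                   host[p + tsd_len:p + tsd_len + 80]),
                     tsd=(tsd_seq, tsd_len))
    arms = detect_terminal_repeats(element, min_ltr, min_identity)
    if arms is not None:
        te.ltr5, te.ltr3 = arms
        te.internal = (te.ltr5[1], te.ltr3[0])
    te.te_class = classify_insertion(te, ltr_reference, min_identity)
    return te


def detect_terminal_repeats(insertion: str, min_len: int = DEFAULT_MIN_LTR,
                            min_identity: float = DEFAULT_MIN_IDENTITY
                            ) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Highest-identity near-identical prefix/suffix pair, or None.

    The leading ``min_len`` bases seed an infix search over the insertion's
    second half to locate the 3' arm; the 5' arm end is then refined within
    a +-BAND bases window by global alignment. Tolerates the few-base length
    difference real LTR pairs show.
    """
    n = len(insertion)
    if n < 2 * min_len:
        return None
    seed = insertion[:min_len]
    tail_off = n // 2
    res = edlib.align(seed, insertion[tail_off:], task="locations", mode="HW")
    if res["editDistance"] < 0 or res["editDistance"] > min_len * (1 - min_identity):
        return None
    q = tail_off + res["locations"][0][0]
    arm3 = insertion[q:]
    best = None
    for a_len in range(len(arm3) - BAND, len(arm3) + BAND + 1):
        if a_len < min_len or a_len > q:     # 5' arm must not reach the 3' arm
            continue
        arm5 = insertion[:a_len]
        d = edlib.align(arm5, arm3, mode="NW")["editDistance"]
        ident = 1.0 - d / max(len(arm5), len(arm3))
        if best is None or ident > best[0]:
            best = (ident, a_len)
    if best is None or best[0] < min_identity:
        return None
    return (0, best[1]), (q, n)


def classify_insertion(te: TEInsertion, ltr_reference: str | None = None,
                       min_identity: float = DEFAULT_MIN_IDENTITY) -> str:
    """fullTRIM (terminal repeats + internal region), soloLTR (whole
    insertion is a single LTR), or unknown."""
    if (te.ltr5 is not None and te.ltr3 is not None
            and te.internal is not None and te.internal[1] > te.internal[0]):
        return "fullTRIM"
    seq = te.insertion_sequence
    if ltr_reference is not None:
        d = edlib.align(seq, ltr_reference, mode="NW")["editDistance"]
        ident = 1.0 - d / max(len(seq), len(ltr_reference))
        if ident >= min_identity:
            return "soloLTR"
        return "unknown"
    if SOLO_LENGTH_RANGE[0] <= len(seq) <= SOLO_LENGTH_RANGE[1]:
        return "soloLTR"
    return "unknown"


def predict_solo_ltr_product(full: TEInsertion) -> int:
    """Apparent locus insertion size after LTR-LTR recombination of a full
    TRIM: one LTR plus the retained TSD."""
    if full.te_class != "fullTRIM":
        raise ValueError("recombination product is defined for fullTRIM only")
    ltr_len = full.ltr5[1] - full.ltr5[0]
    return ltr_len + full.tsd[1]


def recombine_to_solo(full: TEInsertion) -> TEInsertion:
    """The recombinant insertion itself: the 5' LTR with the original TSD."""
    if full.te_class != "fullTRIM":
        raise ValueError("recombination product is defined for fullTRIM only")
    solo_seq = full.insertion_sequence[full.ltr5[0]:full.ltr5[1]]
    return replace(full, insertion_sequence=solo_seq, ltr5=None, ltr3=None,
                   internal=None, te_class="soloLTR")
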