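"""Boundary repeat signatures and promoter motif scanning.

Replication slippage between short homologous repeats is the mechanism the
locus' indels are compatible with: every indel carries a direct repeat at
its boundary (one copy inside the indel, one in the flank — the same
homology that makes the indel's placement ambiguous) and an inverted repeat
near the boundary, one arm of which typically lies inside the indel and the
other overlapping a direct-repeat copy. This module measures both, classes
indels as homology-induced, and scans IUPAC motifs (the TATAWAW TATA-box
consensus and the TTGCTTA CBNAC repressor site), including the spacing
between the two consensus TATA boxes that the 42-bp element stretches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from foxyloci.coords import index_to_coord
from foxyloci.indel_detection import IndelCall
from foxyloci.synthetic_locus import Allele, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class DirectRepeat:
    sequence: str
    length: int
    copy_positions: tuple[int, int]    # 0-based start of each exact copy


@dataclass(frozen=True)
class InvertedRepeat:
    arm: str
    length: int
    arm_positions: tuple[int, int]     # 0-based starts; second arm = revcomp
    overlaps_direct_repeat: bool = False
    one_arm_inside_indel: bool = False


@dataclass
class RepeatSignature:
    indel_id: str
    direct_repeat: DirectRepeat
    inverted_repeats: list[InvertedRepeat] = field(default_factory=list)
    slippage_compatible: bool = False


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    position: int          # promoter coordinate for Allele input, else 0-based
    strand: str
    matched: str


def _is_homopolymer(s: str) -> bool:
    return len(set(s)) <= 1


# ---------------------------------------------------------------------------
# direct repeats


def find_boundary_direct_repeats(ref: Allele | str, indel: IndelCall,
                                 max_len: int = 12,
                                 allow_low_complexity: bool = False
                                 ) -> DirectRepeat:
    """Longest exact repeat with one copy at each indel boundary.

    Operationally the larger of the indel segment's 5' and 3' homology
    extensions into its flanks; for a left-aligned call the 3' extension is
    the ambiguity range. Homopolymer repeats are suppressed by default.
    """
    seq = ref.sequence if isinstance(ref, Allele) else ref
    p, L, seg = indel.position, indel.length, indel.segment

    if indel.kind == "deletion":
        right_flank_start = p + L
    else:
        right_flank_start = p      # insertion: flank resumes at p in ref

    # homology may run past the segment itself when the region is periodic
    # (deleting "TG" from "TGTGTG" can slide 4 bases), hence the modular index
    r = 0
    while (r < max_len and right_flank_start + r < len(seq)
           and seg[r % L] == seq[right_flank_start + r]):
        r += 1
    l = 0
    while (l < max_len and p - 1 - l >= 0
           and seg[L - 1 - (l % L)] == seq[p - 1 - l]):
        l += 1

    if r >= l:
        length = r
        repeat = (seg * (r // L + 1))[:r]
        copies = (p, right_flank_start) if indel.kind == "deletion" else (p, p)
    else:
        length = l
        repeat = (seg * (l // L + 1))[-l:]
        copies = (p - l, p + L - l) if indel.kind == "deletion" else (p - l, p - l)
    if length == 0 or (_is_homopolymer(repeat) and not allow_low_complexity):
        return DirectRepeat("", 0, (p, p))
    return DirectRepeat(repeat, length, copies)


# ---------------------------------------------------------------------------
# inverted repeats


_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_inverted_repeats(ref: Allele | str, indel: IndelCall,
                          window: int = 30, min_len: int = 4,
                          max_len: int = 8,
                          direct_repeat: DirectRepeat | None = None
                          ) -> list[InvertedRepeat]:
    """All maximal reverse-complement arm pairs near the indel boundaries.

    A pair is two disjoint arms ``seq[i:i+l]`` and ``seq[j:j+l]`` with the
    second the reverse complement of the first; the relation anchors at the
    pair's outer ends, so maximality means no inward mismatch and no outward
    complementary extension. Both arms must lie within ``window`` of an
    indel boundary; arm lengths outside [min_len, max_len] and homopolymer
    arms are dropped. Pairs are annotated with whether an arm overlaps a
    boundary direct-repeat copy and whether an arm lies inside the indel.
    """
    seq = ref.sequence if isinstance(ref, Allele) else ref
    if window < max_len:
        raise ValueError("window must be >= max_len")
    p, L = indel.position, indel.length
    b1, b2 = (p, p + L) if indel.kind == "deletion" else (p, p)
    zones = [(max(0, b - window), min(len(seq), b + window))
             for b in sorted({b1, b2})]

    def in_zone(start: int, length: int) -> bool:
        return any(lo <= start and start + length <= hi for lo, hi in zones)

    if direct_repeat is None:
        direct_repeat = find_boundary_direct_repeats(seq, indel)
    dr_spans = [(c, c + direct_repeat.length)
                for c in direct_repeat.copy_positions
                if direct_repeat.length > 0]

    positions = sorted({x for lo, hi in zones for x in range(lo, hi)})
    pos_set = set(positions)
    found: list[InvertedRepeat] = []
    for a in positions:                      # left arm start
        for b in positions:                  # right arm end (exclusive-1)
            bend = b + 1                     # exclusive right end
            if bend - a < 2 * min_len:
                continue
            # outward extension possible -> a longer pair supersedes this one
            if (a - 1 >= 0 and bend < len(seq)
                    and a - 1 in pos_set and bend in pos_set
                    and seq[a - 1] == _COMPL.get(seq[bend], "?")):
                continue
            l = 0
            half = (bend - a) // 2
            while l < half and seq[a + l] == _COMPL.get(seq[bend - 1 - l], "?"):
                l += 1
            if l < min_len or l > max_len:
                continue
            i, j = a, bend - l
            arm1 = seq[i:i + l]
            if _is_homopolymer(arm1):
                continue
            if not (in_zone(i, l) and in_zone(j, l)):
                continue
            overlaps_dr = any((i < e and s < i + l) or (j < e and s < j + l)
                              for s, e in dr_spans)
            inside = False
            if indel.kind == "deletion":
                inside = (b1 <= i and i + l <= b2) or (b1 <= j and j + l <= b2)
            found.append(InvertedRepeat(arm=arm1, length=l,
                                        arm_positions=(i, j),
                                        overlaps_direct_repeat=overlaps_dr,
                                        one_arm_inside_indel=inside))
    found.sort(key=lambda ir: (ir.arm_positions[0], ir.arm_positions[1]))
    return found


def classify_homology_induced(sig: RepeatSignature, dr_min: int = 5,
                              ir_min: int = 4) -> bool:
    """Slippage-compatible iff the boundary direct repeat reaches ``dr_min``
    and some near-boundary inverted repeat reaches ``ir_min``."""
    return (sig.direct_repeat.length >= dr_min
            and any(ir.length >= ir_min for ir in sig.inverted_repeats))


def signature_for_indel(ref: Allele | str, indel: IndelCall,
                        indel_id: str | None = None,
                        dr_min: int = 5, ir_min: int = 4,
                        window: int = 30) -> RepeatSignature:
    dr = find_boundary_direct_repeats(ref, indel)
    irs = find_inverted_repeats(ref, indel, window=window, direct_repeat=dr)
    sig = RepeatSignature(indel_id=indel_id or f"{indel.kind}:{indel.position}",
                          direct_repeat=dr, inverted_repeats=irs)
    sig.slippage_compatible = classify_homology_induced(sig, dr_min, ir_min)
    return sig


# ---------------------------------------------------------------------------
# motif scanning


def iupac_regex(pattern: str) -> re.Pattern:
    if not pattern:
        raise ValueError("pattern must be non-empty")
    try:
        body = "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r}") from None
    return re.compile(f"(?=({body}))")


def scan_motif(seq: Allele | str, pattern: str,
               both_strands: bool = False) -> list[MotifHit]:
    """All (by default forward-strand) matches of an IUPAC pattern.

    Positions are promoter coordinates for Allele input, 0-based indices for
    plain strings. Overlapping matches are all reported.
    """
    is_allele = isinstance(seq, Allele)
    s = seq.sequence if is_allele else seq
    rx = iupac_regex(pattern)
    hits = []
    for m in rx.finditer(s.upper()):
        pos = index_to_coord(m.start(), seq.atg_index) if is_allele else m.start()
        hits.append(MotifHit(pattern=pattern, position=pos, strand="+",
                             matched=m.group(1)))
    if both_strands:
        rc = revcomp(s.upper())
        n = len(s)
        for m in rx.finditer(rc):
            i = n - m.start() - len(pattern)     # index on the forward strand
            pos = index_to_coord(i, seq.atg_index) if is_allele else i
            hits.append(MotifHit(pattern=pattern, position=pos, strand="-",
                                 matched=m.group(1)))
    return hits


def tata_spacing(allele: Allele, pattern: str = "TATAWAW",
                 region: str = "tata_region") -> tuple[int, int | None]:
    """(number of consensus TATA hits in the configured TATA region, bases
    strictly between the outermost two hits; None with fewer than two)."""
    if region not in allele.element_intervals:
        raise ValueError(f"allele has no {region!r} interval")
    lo, hi = allele.element_intervals[region]
    i0 = allele.index(lo)
    i1 = allele.index(hi) + 1
    sub = allele.sequence[i0:i1]
    rx = iupac_regex(pattern)
    starts = [m.start() for m in rx.finditer(sub.upper())]
    n = len(starts)
    if n < 2:
        return n, None
    spacer = starts[-1] - (starts[0] + len(pattern))
    return n, spacer
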