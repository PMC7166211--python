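"""Indel calling and canonicalization between promoter alleles.

Calls are made by chaining k-mers that are unique in both sequences and
base-level aligning the inter-anchor gaps, then left-aligning every indel
to its most 5' equivalent placement (the VCF convention). The right-minus-
left placement span is reported as ``ambiguity_range`` — for a boundary
tandem repeat it equals the repeat length, the quantity the repeat-signature
module measures independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from foxyloci.synthetic_locus import Allele


@dataclass(frozen=True)
class IndelCall:
    """One deletion/insertion transforming ref into alt.

    ``position`` is the 0-based ref index of the first affected base (for an
    insertion, the ref index the segment is inserted before), left-aligned.
    """

    ref_name: str
    alt_name: str
    kind: str                  # "deletion" | "insertion"
    position: int
    length: int
    segment: str
    ambiguity_range: int = 0

    def end(self) -> int:
        return self.position + (self.length if self.kind == "deletion" else 0)


@dataclass(frozen=True)
class SubstitutionCall:
    ref_name: str
    alt_name: str
    position: int
    ref_base: str
    alt_base: str


class NoHomologyError(ValueError):
    """Alleles share no anchors at all."""


def apply_indel(call: IndelCall, ref_seq: str) -> str:
    """Apply a single call to the reference sequence."""
    p = call.position
    if call.kind == "deletion":
        if ref_seq[p:p + call.length] != call.segment:
            raise ValueError("deletion segment does not match reference")
        return ref_seq[:p] + ref_seq[p + call.length:]
    return ref_seq[:p] + call.segment + ref_seq[p:]


def apply_calls(calls: list[IndelCall], ref_seq: str) -> str:
    """Apply sorted non-overlapping calls 3'→5' so positions stay valid."""
    out = ref_seq
    for call in sorted(calls, key=lambda c: -c.position):
        out = apply_indel(call, out)
    return out


# ---------------------------------------------------------------------------
# normalization


def _left_align(kind: str, pos: int, seg: str, ref: str) -> tuple[int, str]:
    while pos > 0:
        prev = ref[pos - 1]
        if seg[-1] != prev:
            break
        pos -= 1
        seg = prev + seg[:-1]
    return pos, seg


def _right_shift_count(kind: str, pos: int, seg: str, ref: str) -> int:
    """Number of single-base right shifts available from a left-aligned call."""
    n = 0
    p, s = pos, seg
    while True:
        j = p + len(s) if kind == "deletion" else p
        if j >= len(ref) or s[0] != ref[j]:
            break
        p += 1
        s = s[1:] + ref[j]
        n += 1
    return n


def normalize_indel(call: IndelCall, ref: Allele | str) -> IndelCall:
    """Shift a call to its most 5' equivalent placement; idempotent."""
    ref_seq = ref.sequence if isinstance(ref, Allele) else ref
    if call.kind == "deletion" and ref_seq[call.position:call.position
                                           + call.length] != call.segment:
        raise ValueError("call inconsistent with reference")
    pos, seg = _left_align(call.kind, call.position, call.segment, ref_seq)
    amb = _right_shift_count(call.kind, pos, seg, ref_seq)
    return replace(call, position=pos, segment=seg, ambiguity_range=amb)


# ---------------------------------------------------------------------------
# anchoring and alignment


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _chain_anchors(ref: str, alt: str, k: int) -> list[tuple[int, int]]:
    """Co-linear chain of (ref_pos, alt_pos) anchors, unique in both."""
    kr = _unique_kmers(ref, k)
    ka = _unique_kmers(alt, k)
    shared = sorted((kr[km], ka[km]) for km in kr.keys() & ka.keys())
    if not shared:
        raise NoHomologyError("alleles share no homology")
    # longest increasing subsequence on alt positions (patience style)
    import bisect
    tails: list[int] = []
    backptr: list[int] = []
    idx_at: list[int] = []
    for i, (_, ap) in enumerate(shared):
        j = bisect.bisect_left(tails, ap)
        if j == len(tails):
            tails.append(ap)
            idx_at.append(i)
        else:
            tails[j] = ap
            idx_at[j] = i
        backptr.append(idx_at[j - 1] if j > 0 else -1)
    chain = []
    i = idx_at[len(tails) - 1]
    while i != -1:
        chain.append(shared[i])
        i = backptr[i]
    return chain[::-1]


def _pure_indel(ref_gap: str, alt_gap: str):
    """If the two gap strings differ by one contiguous indel, return
    (kind, offset, segment); else None. Chooses the most 5' placement."""
    if len(ref_gap) == len(alt_gap):
        return None
    short, long = (ref_gap, alt_gap) if len(ref_gap) < len(alt_gap) else (
        alt_gap, ref_gap)
    lcp = 0
    while lcp < len(short) and short[lcp] == long[lcp]:
        lcp += 1
    lcs = 0
    while (lcs < len(short)
           and short[len(short) - 1 - lcs] == long[len(long) - 1 - lcs]):
        lcs += 1
    if lcp + lcs < len(short):
        return None
    d = len(long) - len(short)
    p = max(0, len(short) - lcs)     # most 5' split point
    seg = long[p:p + d]
    kind = "deletion" if len(ref_gap) > len(alt_gap) else "insertion"
    return kind, p, seg


def _cigar_calls(ref_gap: str, alt_gap: str, ref_off: int,
                 ref_name: str, alt_name: str):
    """General path: edlib global alignment of a gap region."""
    indels: list[IndelCall] = []
    subs: list[SubstitutionCall] = []
    if not ref_gap and not alt_gap:
        return indels, subs
    if not ref_gap:
        indels.append(IndelCall(ref_name, alt_name, "insertion", ref_off,
                                len(alt_gap), alt_gap))
        return indels, subs
    if not alt_gap:
        indels.append(IndelCall(ref_name, alt_name, "deletion", ref_off,
                                len(ref_gap), ref_gap))
        return indels, subs
    res = edlib.align(alt_gap, ref_gap, task="path", mode="NW")
    import re as _re
    ri = ai = 0
    for n, op in _re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op in "=M":
            ri += n
            ai += n
        elif op == "X":
            for t in range(n):
                subs.append(SubstitutionCall(ref_name, alt_name,
                                             ref_off + ri + t,
                                             ref_gap[ri + t], alt_gap[ai + t]))
            ri += n
            ai += n
        elif op == "D":          # consumes target (= ref): deletion from ref
            indels.append(IndelCall(ref_name, alt_name, "deletion",
                                    ref_off + ri, n, ref_gap[ri:ri + n]))
            ri += n
        elif op == "I":          # consumes query (= alt): insertion into ref
            indels.append(IndelCall(ref_name, alt_name, "insertion",
                                    ref_off + ri, n, alt_gap[ai:ai + n]))
            ai += n
    return indels, subs


def align_alleles(ref: Allele | str, alt: Allele | str, k: int = 16,
                  ref_name: str | None = None, alt_name: str | None = None
                  ) -> tuple[list[IndelCall], list[SubstitutionCall]]:
    """Call indels (and substitutions, reported separately) between alleles.

    Returns left-aligned, non-overlapping calls sorted 5'→3'. Raises
    NoHomologyError when the sequences share no unique anchors.
    """
    ref_seq = ref.sequence if isinstance(ref, Allele) else ref
    alt_seq = alt.sequence if isinstance(alt, Allele) else alt
    ref_name = ref_name or (ref.spec.name if isinstance(ref, Allele) else "ref")
    alt_name = alt_name or (alt.spec.name if isinstance(alt, Allele) else "alt")
    if not ref_seq or not alt_seq:
        raise ValueError("sequences must be non-empty")
    if ref_seq == alt_seq:
        return [], []

    chain = _chain_anchors(ref_seq, alt_seq, k)
    # segment boundaries: (ref_end_of_prev_anchor, alt_end_of_prev_anchor)
    points = [(0, 0)]
    for rp, ap in chain:
        points.append((rp, ap))
        points.append((rp + k, ap + k))
    points.append((len(ref_seq), len(alt_seq)))

    indels: list[IndelCall] = []
    subs: list[SubstitutionCall] = []
    for (r0, a0), (r1, a1) in zip(points[::2], points[1::2]):
        # anchors may overhang the next segment (boundary homology); slide
        # the gap start back along the previous anchor's exact-match diagonal
        shift = max(0, r0 - r1, a0 - a1)
        r0 -= shift
        a0 -= shift
        ref_gap = ref_seq[r0:r1]
        alt_gap = alt_seq[a0:a1]
        if ref_gap == alt_gap:
            continue
        pure = _pure_indel(ref_gap, alt_gap)
        if pure is not None:
            kind, off, seg = pure
            indels.append(IndelCall(ref_name, alt_name, kind, r0 + off,
                                    len(seg), seg))
        elif len(ref_gap) == len(alt_gap):
            for t, (x, y) in enumerate(zip(ref_gap, alt_gap)):
                if x != y:
                    subs.append(SubstitutionCall(ref_name, alt_name, r0 + t,
                                                 x, y))
        else:
            ind, sb = _cigar_calls(ref_gap, alt_gap, r0, ref_name, alt_name)
            indels.extend(ind)
            subs.extend(sb)

    indels = [normalize_indel(c, ref_seq) for c in indels]
    indels.sort(key=lambda c: c.position)
    return indels, subs


def compare_to_references(query: Allele, refs: list[Allele]):
    """Per-reference deletion/insertion sizes for a query allele.

    Returns a DataFrame with one row per reference: sizes of indels the
    query lacks relative to that reference (deletions) and carries extra
    (insertions). Rows where alignment fails report the error.
    """
    import pandas as pd

    if not refs:
        raise ValueError("refs is empty")
    rows = []
    for ref in refs:
        try:
            calls, _ = align_alleles(ref, query)
            dels = [c.length for c in calls if c.kind == "deletion"]
            ins = [c.length for c in calls if c.kind == "insertion"]
            rows.append((ref.spec.name, query.spec.name, dels, ins, ""))
        except (ValueError, NoHomologyError) as exc:
            rows.append((ref.spec.name, query.spec.name, [], [], str(exc)))
    return pd.DataFrame(rows, columns=["ref_name", "query_name",
                                       "deletion_sizes", "insertion_sizes",
                                       "error"])


# ---------------------------------------------------------------------------
# writers


def calls_to_tsv(calls: list[IndelCall], path) -> None:
    import pandas as pd
    pd.DataFrame(
        [(c.ref_name, c.alt_name, c.kind, c.position + 1, c.length,
          c.ambiguity_range, c.segment) for c in calls],
        columns=["ref", "alt", "kind", "pos_1based", "length",
                 "ambiguity_range", "segment"],
    ).to_csv(path, sep="\t", index=False)


def calls_to_vcf(calls: list[IndelCall], ref_seq: str, path) -> None:
    """Minimal VCF-style records: CHROM = allele name, 1-based anchored POS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            p = c.position
            if c.kind == "deletion":
                pos = p          # anchor base before the event
                ref_f = ref_seq[p - 1:p + c.length] if p > 0 else (
                    ref_seq[:c.length + 1])
                alt_f = ref_seq[p - 1] if p > 0 else ref_seq[c.length]
            else:
                pos = p
                ref_f = ref_seq[p - 1] if p > 0 else ref_seq[0]
                alt_f = (ref_seq[p - 1] + c.segment) if p > 0 else (
                    c.segment + ref_seq[0])
            fh.write(f"{c.ref_name}\t{max(pos, 1)}\t.\t{ref_f}\t{alt_f}"
                     f"\t.\tPASS\tSVLEN={c.length}\n")
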