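"""Independent brute-force oracles used by the test suite.

Deliberately naive: placement enumeration by string surgery, full
Needleman-Wunsch DP, and exhaustive substring scans. None of these share
code with the package's aligner or repeat finder.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def deletion_placements(ref: str, alt: str) -> list[int]:
    """All positions p where deleting len(ref)-len(alt) bases from ref at p
    reproduces alt exactly."""
    L = len(ref) - len(alt)
    assert L > 0
    return [p for p in range(len(alt) + 1) if ref[:p] + ref[p + L:] == alt]


def insertion_placements(ref: str, alt: str) -> list[int]:
    """All ref positions p where alt equals ref with alt's extra bases
    inserted before ref[p]."""
    L = len(alt) - len(ref)
    assert L > 0
    return [p for p in range(len(ref) + 1)
            if alt[:p] == ref[:p] and alt[p + L:] == ref[p:]]


def nw_edit_path(ref: str, alt: str) -> list[str]:
    """Unit-cost global alignment ops ('M','X','D','I'), ties preferring
    diagonal, then deletion. Small inputs only."""
    n, m = len(ref), len(alt)
    INF = 10 ** 9
    dp = [[INF] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = i
    for j in range(m + 1):
        dp[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1][j - 1] + (ref[i - 1] != alt[j - 1])
            dp[i][j] = min(sub, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    ops = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and dp[i][j] == dp[i - 1][j] + 1:
            ops.append("D")
            i -= 1
        elif i > 0 and j > 0 and dp[i][j] == dp[i - 1][j - 1] + (
                ref[i - 1] != alt[j - 1]):
            ops.append("M" if ref[i - 1] == alt[j - 1] else "X")
            i, j = i - 1, j - 1
        else:
            ops.append("I")
            j -= 1
    return ops[::-1]


def nw_indel_runs(ref: str, alt: str) -> list[tuple[str, int]]:
    """(kind, run length) for each gap run of the NW path."""
    runs = []
    for op in nw_edit_path(ref, alt):
        kind = {"D": "deletion", "I": "insertion"}.get(op)
        if kind is None:
            runs.append(None)
        elif runs and runs[-1] is not None and runs[-1][0] == kind:
            runs[-1] = (kind, runs[-1][1] + 1)
        else:
            runs.append((kind, 1))
    return [r for r in runs if r is not None]


def boundary_direct_repeat_len(ref: str, pos: int, length: int) -> int:
    """Direct-repeat length at a deletion boundary == placement freedom."""
    alt = ref[:pos] + ref[pos + length:]
    ps = deletion_placements(ref, alt)
    return max(ps) - min(ps)


def exhaustive_inverted_repeats(seq: str, zones: list[tuple[int, int]],
                                min_len: int, max_len: int
                                ) -> set[tuple[int, int, int]]:
    """All maximal revcomp arm pairs (i, j, l): seq[j:j+l] == rc(seq[i:i+l]),
    arms disjoint, each arm inside a zone, homopolymers excluded.

    Maximality follows the outer-anchor convention: the pair (a, b) anchored
    at arm1 start and arm2 end grows inward to the first mismatch (or arm
    contact), and is dropped when an outward complementary extension exists
    whose anchors still lie in the zone union.
    """
    pos = sorted({x for lo, hi in zones for x in range(lo, hi)})
    pos_set = set(pos)

    def in_zone(start, l):
        return any(lo <= start and start + l <= hi for lo, hi in zones)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    for a in pos:
        for b in pos:
            bend = b + 1
            if bend - a < 2 * min_len:
                continue
            if (a - 1 in pos_set and bend in pos_set and 0 <= a - 1
                    and bend < len(seq)
                    and seq[a - 1] == comp.get(seq[bend], "?")):
                continue
            l = 0
            while (l < (bend - a) // 2
                   and seq[a + l] == comp.get(seq[bend - 1 - l], "?")):
                l += 1
            if not (min_len <= l <= max_len):
                continue
            i, j = a, bend - l
            if len(set(seq[i:i + l])) <= 1:
                continue
            if in_zone(i, l) and in_zone(j, l):
                out.add((i, j, l))
    return out


def iupac_match(seq: str, pattern: str) -> list[int]:
    """Positional IUPAC check by hand (subset of codes the tests use)."""
    table = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "N": "ACGT"}
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + k] in table[p] for k, p in enumerate(pattern)):
            hits.append(i)
    return hits
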