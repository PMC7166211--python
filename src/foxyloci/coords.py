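"""Promoter coordinate system.

Coordinates are anchored on the translation start: the 'A' of the ATG start
codon is position +1, the base immediately upstream is -1, and there is no
position 0. Intervals are inclusive on both ends and always written
5'→3' (so an upstream interval is (-2589, -2164), not (-2164, -2589)).
"""

from __future__ import annotations


def coord_to_index(coord: int, atg_index: int) -> int:
    """Convert a promoter coordinate to a 0-based sequence index.

    ``atg_index`` is the 0-based index of the 'A' of ATG in the sequence.
    """
    if coord == 0:
        raise ValueError("position 0 does not exist in promoter coordinates")
    if coord > 0:
        return atg_index + coord - 1
    return atg_index + coord


def index_to_coord(index: int, atg_index: int) -> int:
    """Convert a 0-based sequence index to a promoter coordinate."""
    if index >= atg_index:
        return index - atg_index + 1
    return index - atg_index


def interval_to_slice(interval: tuple[int, int], atg_index: int) -> slice:
    """Inclusive promoter-coordinate interval -> python slice."""
    lo, hi = interval
    return slice(coord_to_index(lo, atg_index), coord_to_index(hi, atg_index) + 1)


def interval_length(interval: tuple[int, int]) -> int:
    lo, hi = interval
    n = hi - lo + 1
    # an interval straddling the (absent) origin spans one base fewer
    if lo < 0 < hi:
        n -= 1
    return n
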