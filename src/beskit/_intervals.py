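"""Half-open interval arithmetic on read coordinates.

Mask annotations throughout the package are lists of 0-based half-open
``(start, end)`` tuples, kept sorted, merged and within sequence bounds.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def normalize(intervals: Iterable[Interval], length: int | None = None) -> list[Interval]:
    """Sort, clip to ``[0, length)`` and merge overlapping/adjacent intervals."""
    ivs = []
    for s, e in intervals:
        if length is not None:
            s, e = max(0, s), min(length, e)
        if e > s:
            ivs.append((s, e))
    ivs.sort()
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def complement(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Unmasked runs: the gaps between normalized ``intervals`` within [0, length)."""
    out: list[Interval] = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if length > prev:
        out.append((prev, length))
    return out


def overlap_length(intervals: Sequence[Interval], start: int, end: int) -> int:
    """Total bases of ``intervals`` falling inside [start, end)."""
    return sum(max(0, min(e, end) - max(s, start)) for s, e in intervals)
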