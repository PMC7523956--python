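"""Exact interval arithmetic on 0-based half-open (start, end) pairs.

The composition ledgers promise exact integer bp accounting, so the merge
and union-length primitives live here as plain, auditable code.
"""

from __future__ import annotations

from .types import Interval


def merge(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals; returns a sorted list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: list[Interval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(e - s for s, e in merge(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def expand(iv: Interval, pad: int) -> Interval:
    """Pad an interval on both sides, clamping the start at zero."""
    return (max(0, iv[0] - pad), iv[1] + pad)
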