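"""Minimal half-open interval arithmetic used for tracts and evaluation."""

from __future__ import annotations

__all__ = ["merge_intervals", "total_length", "intersect_length"]


def merge_intervals(intervals, gap: int = 0):
    """Union of half-open intervals; intervals closer than ``gap`` bp merge.

    ``gap=0`` merges overlapping and book-ended intervals.
    """
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def total_length(intervals) -> int:
    return sum(b - a for a, b in merge_intervals(intervals))


def intersect_length(a, b) -> int:
    """Total bp shared by two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = 0
    out = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out
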