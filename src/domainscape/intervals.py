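"""Small interval-algebra helpers shared across modules.

All coordinates are 0-based half-open on a single sequence; callers group
by seq_id before using these.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint intervals.

    Abutting intervals ([0,5),[5,9)) are coalesced.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two interval unions (inputs need not be disjoint)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Bases in the union of ``a`` not covered by the union of ``b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Iterable[tuple[int, int]], window: tuple[int, int]) -> list[tuple[int, int]]:
    """Clip intervals to a window, dropping empty results."""
    ws, we = window
    out = []
    for s, e in intervals:
        s2, e2 = max(s, ws), min(e, we)
        if s2 < e2:
            out.append((s2, e2))
    return out
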