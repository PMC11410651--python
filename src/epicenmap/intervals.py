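"""Small utilities on 0-based half-open intervals grouped by chromosome.

The operations needed here (union, k-way intersection, membership
partition) are deliberately implemented on plain sorted lists so that the
bp-level brute-force oracles in the test suite exercise exactly this code.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals; intervals closer than or touching within ``gap`` merge."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if end <= start:
            continue
        if out and start <= out[-1][1] + gap:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def intersect_two(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two interval unions (both sorted, non-overlapping)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    result = merge_intervals(sets[0])
    for other in sets[1:]:
        result = intersect_two(result, merge_intervals(other))
        if not result:
            break
    return result


def by_chrom(intervals: Iterable[tuple[str, int, int]]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = defaultdict(list)
    for chrom, start, end in intervals:
        out[chrom].append((start, end))
    return {c: merge_intervals(v) for c, v in out.items()}


def partition_membership(
    named_sets: Mapping[str, Sequence[Interval]],
) -> list[tuple[int, int, frozenset]]:
    """Split the combined span into maximal pieces of constant membership.

    Returns ``(start, end, members)`` pieces, members being the labels whose
    union covers the piece; pieces with empty membership are dropped.
    """
    bounds = sorted(
        {x for ivs in named_sets.values() for s, e in ivs for x in (s, e)}
    )
    merged = {label: merge_intervals(ivs) for label, ivs in named_sets.items()}
    pieces = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        members = frozenset(
            label
            for label, ivs in merged.items()
            if any(s <= lo and hi <= e for s, e in ivs)
        )
        if members:
            if pieces and pieces[-1][1] == lo and pieces[-1][2] == members:
                pieces[-1] = (pieces[-1][0], hi, members)
            else:
                pieces.append((lo, hi, members))
    return pieces
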