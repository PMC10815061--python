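"""Genomic-interval arithmetic shared by the IBD and SV stages.

Intervals are 0-based half-open ``(start, end)`` tuples grouped per
chromosome in plain dicts (``{chrom: [(start, end), ...]}``).  Reports and
BED exports keep this convention; VCF positions remain 1-based at the
record level.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

Interval = tuple[int, int]
IntervalMap = dict[str, list[Interval]]

__all__ = [
    "merge_intervals",
    "intersect_pair",
    "intersect_many",
    "subtract",
    "total_length",
    "jaccard",
    "overlaps",
]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and coalesce overlapping or touching half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect_pair(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two merged, sorted interval lists (two-pointer sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(maps: Sequence[IntervalMap]) -> IntervalMap:
    """Per-chromosome intersection across several interval maps."""
    if not maps:
        return {}
    chroms = set(maps[0])
    for m in maps[1:]:
        chroms &= set(m)
    out: IntervalMap = {}
    for chrom in sorted(chroms):
        acc = merge_intervals(maps[0][chrom])
        for m in maps[1:]:
            acc = intersect_pair(acc, merge_intervals(m[chrom]))
            if not acc:
                break
        if acc:
            out[chrom] = acc
    return out


def subtract(a: IntervalMap, b: IntervalMap) -> IntervalMap:
    """Remove every interval of ``b`` from ``a`` (per chromosome)."""
    out: IntervalMap = {}
    for chrom, ivs in a.items():
        keep = merge_intervals(ivs)
        cut = merge_intervals(b.get(chrom, []))
        result: list[Interval] = []
        j = 0
        for s, e in keep:
            cur = s
            while j < len(cut) and cut[j][1] <= cur:
                j += 1
            k = j
            while k < len(cut) and cut[k][0] < e:
                cs, ce = cut[k]
                if cs > cur:
                    result.append((cur, cs))
                cur = max(cur, ce)
                if ce >= e:
                    break
                k += 1
            if cur < e:
                result.append((cur, e))
        if result:
            out[chrom] = result
    return out


def total_length(m: Mapping[str, Sequence[Interval]]) -> int:
    return sum(e - s for ivs in m.values() for s, e in ivs)


def jaccard(a: IntervalMap, b: IntervalMap) -> float:
    """Jaccard index (intersection bp / union bp) of two interval maps."""
    am = {c: merge_intervals(v) for c, v in a.items()}
    bm = {c: merge_intervals(v) for c, v in b.items()}
    inter = total_length(intersect_many([am, bm])) if am and bm else 0
    union: IntervalMap = defaultdict(list)
    for m in (am, bm):
        for c, v in m.items():
            union[c].extend(v)
    union_len = total_length({c: merge_intervals(v) for c, v in union.items()})
    if union_len == 0:
        return 1.0
    return inter / union_len


def overlaps(a: Interval, b: Interval) -> bool:
    """Half-open overlap of at least one base."""
    return a[0] < b[1] and b[0] < a[1]
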