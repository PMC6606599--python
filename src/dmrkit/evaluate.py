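"""Recovery metrics against planted truth: reciprocal-overlap matching,
sensitivity/precision, and base-pair Jaccard of interval sets."""
from __future__ import annotations

from typing import Sequence

import numpy as np


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """Reciprocal overlap of (chrom, start, end) intervals: the smaller of
    the two overlap fractions; 0 for different chromosomes."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))


def match_sensitivity(planted: Sequence[tuple], called: Sequence[tuple],
                      min_ro: float = 0.5) -> float:
    """Fraction of planted intervals matched by some call at >= min_ro."""
    if not planted:
        return float("nan")
    hit = sum(1 for p in planted
              if any(reciprocal_overlap(p, c) >= min_ro for c in called))
    return hit / len(planted)


def match_precision(called: Sequence[tuple], planted: Sequence[tuple],
                    min_ro: float = 0.5) -> float:
    """Fraction of calls matching some planted interval at >= min_ro."""
    if not called:
        return float("nan")
    hit = sum(1 for c in called
              if any(reciprocal_overlap(c, p) >= min_ro for p in planted))
    return hit / len(called)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def interval_jaccard(a: Sequence[tuple], b: Sequence[tuple]) -> float:
    """Base-pair Jaccard index between two interval sets (chrom, start, end)."""
    chroms = {x[0] for x in a} | {x[0] for x in b}
    inter = union = 0
    for chrom in chroms:
        ma = _merge([(s, e) for c, s, e in a if c == chrom])
        mb = _merge([(s, e) for c, s, e in b if c == chrom])
        union += sum(e - s for s, e in _merge(ma + mb))
        i = j = 0
        while i < len(ma) and j < len(mb):
            s = max(ma[i][0], mb[j][0])
            e = min(ma[i][1], mb[j][1])
            if e > s:
                inter += e - s
            if ma[i][1] < mb[j][1]:
                i += 1
            else:
                j += 1
    return inter / union if union else float("nan")
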