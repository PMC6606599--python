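"""MethylSeekR-style methylome segmentation.

Each group's pooled methylation track is segmented into hypomethylated
runs; runs are kept at a minimum CpG count chosen so that a site-permuted
null track would yield at most ``fdr_target`` as many runs, then split by
CpG count into UMRs (promoter-like, >= 30 CpGs) and LMRs (enhancer-like).
DNA methylation valleys (DMVs) are extended (>= 5 kb) low-methylation
spans obtained by merging nearby UMRs.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .types import ConfigurationError, MethTrack, Segment


def _low_runs(low: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, end) index pairs."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def call_segments(track: MethTrack, meth_cutoff: float = 0.5,
                  fdr_target: float = 0.05, umr_min_cpg: int = 30,
                  lmr_min_cpg: int = 4, n_permutations: int = 100,
                  seed: int = 0) -> list[Segment]:
    """Call UMR/LMR segments on a pooled group methylation track.

    A candidate is a maximal run of consecutive CpGs with pooled
    methylation below ``meth_cutoff``. The effective minimum run length
    starts at ``lmr_min_cpg`` and is raised until the expected number of
    equally long runs in within-chromosome site permutations of the track,
    divided by the observed count, is at most ``fdr_target``.
    """
    if len(track.pos) == 0:
        raise ConfigurationError("empty methylation track")
    rng = np.random.default_rng(seed)
    chroms = np.unique(track.chrom.astype(str))
    value = track.value

    obs_lengths: list[int] = []
    obs_runs: list[tuple[str, int, int]] = []   # (chrom, start idx, end idx) global
    perm_lengths: list[list[int]] = [[] for _ in range(n_permutations)]
    for chrom in chroms:
        idx = track.chrom_slice(chrom)
        v = value[idx]
        low = (v < meth_cutoff) & np.isfinite(v)
        for a, b in _low_runs(low):
            obs_lengths.append(b - a)
            obs_runs.append((chrom, idx[0] + a, idx[0] + b))
        finite = v[np.isfinite(v)]
        n_low = int(((finite < meth_cutoff)).sum())
        nf = len(finite)
        for bi in range(n_permutations):
            # permutation of site values == random placement of low sites
            mask = np.zeros(nf, dtype=bool)
            mask[rng.choice(nf, size=n_low, replace=False)] = True
            perm_lengths[bi].extend(b - a for a, b in _low_runs(mask))

    obs_arr = np.array(obs_lengths) if obs_lengths else np.empty(0, int)
    min_cpg = lmr_min_cpg
    max_try = max(umr_min_cpg, lmr_min_cpg) + 1
    while min_cpg <= max_try:
        observed = int((obs_arr >= min_cpg).sum())
        if observed == 0:
            break
        expected = float(np.mean([sum(1 for L in pl if L >= min_cpg)
                                  for pl in perm_lengths])) if n_permutations else 0.0
        if expected / observed <= fdr_target:
            break
        min_cpg += 1

    segments: list[Segment] = []
    for (chrom, a, b) in obs_runs:
        n = b - a
        if n < min_cpg:
            continue
        mean_meth = float(np.nanmean(value[a:b]))
        if not mean_meth < meth_cutoff:
            continue
        seg_class = "UMR" if n >= umr_min_cpg else "LMR"
        segments.append(Segment(chrom, int(track.pos[a]), int(track.pos[b - 1]) + 1,
                                int(n), mean_meth, seg_class))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def call_dmvs(umrs: list[Segment], track: MethTrack, min_len_bp: int = 5000,
              max_mean_meth: float = 0.15, merge_gap_bp: int = 1000) -> list[Segment]:
    """Merge UMRs across short gaps; keep extended spans that stay lowly
    methylated over their whole length."""
    dmvs: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for u in umrs:
        if u.seg_class != "UMR":
            continue
        by_chrom.setdefault(u.chrom, []).append(u)
    for chrom, us in by_chrom.items():
        us = sorted(us, key=lambda u: u.start)
        merged = [[us[0].start, us[0].end]]
        for u in us[1:]:
            if u.start - merged[-1][1] <= merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], u.end)
            else:
                merged.append([u.start, u.end])
        idx = track.chrom_slice(chrom)
        pos = track.pos[idx]
        val = track.value[idx]
        for s, e in merged:
            if e - s < min_len_bp:
                continue
            lo = np.searchsorted(pos, s, "left")
            hi = np.searchsorted(pos, e, "left")
            if hi <= lo:
                continue
            mm = float(np.nanmean(val[lo:hi]))
            if mm <= max_mean_meth:
                dmvs.append(Segment(chrom, int(s), int(e), int(hi - lo), mm, "DMV"))
    dmvs.sort(key=lambda d: (d.chrom, d.start))
    return dmvs


def _reciprocal_overlap(a: Segment, b: Segment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def compare_feature_sets(sets: dict[str, list[Segment]],
                         min_reciprocal_overlap: float = 0.3) -> dict[tuple, int]:
    """Partition features into shared/specific membership cells.

    A feature is "shared" with another group when it has a partner there
    with reciprocal overlap >= the threshold (greedy best-overlap per
    feature; each feature is counted exactly once, in the cell given by the
    set of groups it is shared with).
    """
    groups = sorted(sets)
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups to compare")
    counts: dict[tuple, int] = {}
    for g in groups:
        for f in sets[g]:
            cell = {g}
            for h in groups:
                if h == g:
                    continue
                best = max((_reciprocal_overlap(f, x) for x in sets[h]), default=0.0)
                if best >= min_reciprocal_overlap:
                    cell.add(h)
            key = tuple(sorted(cell))
            counts[key] = counts.get(key, 0) + 1
    return counts
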