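"""BSmooth-style differential methylation: local-likelihood smoothing of
per-sample methylation fractions, a t-like group-difference statistic, and
region calling with a pooled-count ΔMe filter.

ΔMe is defined once, everywhere: the signed difference of coverage-pooled
methylation fractions (sum meth / sum total per group), averaged over the
region's CpGs — never the mean of smoothed values.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import CpGMethylomeMatrix, ConfigurationError, DMR, SmoothedTrack

VARIANCE_FLOOR = 1e-4
FINE_BINS = ("0.1-0.2", "0.2-0.3", "0.3-0.4", ">=0.4")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _local_linear(dx: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted local-linear fit evaluated at dx == 0.

    dx: (k,) offsets; y, w: (k, m) responses and weights (m fits at once).
    Constant and linear signals are reproduced exactly.
    """
    s0 = w.sum(axis=0)
    s1 = (w * dx[:, None]).sum(axis=0)
    s2 = (w * dx[:, None] ** 2).sum(axis=0)
    t0 = (w * y).sum(axis=0)
    t1 = (w * y * dx[:, None]).sum(axis=0)
    det = s0 * s2 - s1 * s1
    out = np.full(y.shape[1], np.nan)
    ok = det > 1e-12
    out[ok] = (s2[ok] * t0[ok] - s1[ok] * t1[ok]) / det[ok]
    # degenerate window (all weight at one offset): weighted mean
    deg = (~ok) & (s0 > 0)
    out[deg] = t0[deg] / s0[deg]
    return out


def smooth_methylation(m: CpGMethylomeMatrix, half_window_bp: int = 1000,
                       min_cpgs_in_window: int = 70,
                       min_cov: int = 1) -> SmoothedTrack:
    """Coverage-weighted tricube local-linear smoothing per sample.

    The window around each CpG spans at least ±half_window_bp and at least
    min_cpgs_in_window CpGs, whichever is larger. Smoothed values are only
    defined (non-NaN) at sites with total >= min_cov in that sample.
    """
    if m.n_sites == 0:
        raise ConfigurationError("empty methylome matrix")
    S, n = m.meth.shape
    smooth = np.full((S, n), np.nan)
    frac = np.where(m.total > 0, m.meth / np.maximum(m.total, 1), 0.0)
    cov_ok = m.total >= min_cov

    for chrom in np.unique(m.chrom.astype(str)):
        idx = np.flatnonzero(m.chrom.astype(str) == chrom)
        pos = m.pos[idx].astype(float)
        f = frac[idx]
        cov = m.total[idx].astype(float)
        k = len(idx)
        half = min(min_cpgs_in_window // 2, (k - 1) // 2) if k > 1 else 0
        for i in range(k):
            lo = np.searchsorted(pos, pos[i] - half_window_bp, "left")
            hi = np.searchsorted(pos, pos[i] + half_window_bp, "right")
            # widen symmetrically (by CpG count) if the bp window is too sparse
            if hi - lo < min(min_cpgs_in_window, k):
                lo = min(lo, max(0, i - half))
                hi = max(hi, min(k, i + half + 1))
                while hi - lo < min(min_cpgs_in_window, k):
                    if lo > 0:
                        lo -= 1
                    if hi < k and hi - lo < min(min_cpgs_in_window, k):
                        hi += 1
            dx = pos[lo:hi] - pos[i]
            bw = max(np.abs(dx).max(), 1.0)
            w = _tricube(dx / (bw * 1.0001))[:, None] * cov[lo:hi]
            smooth[idx[i]] = _local_linear(dx, f[lo:hi], w)
    smooth = np.clip(smooth, 0.0, 1.0)
    smooth[~cov_ok] = np.nan
    return SmoothedTrack(m.chrom, m.pos, list(m.samples), dict(m.groups), smooth)


def group_difference_stat(s: SmoothedTrack, groups: Optional[Sequence[str]] = None,
                          variance_floor: float = VARIANCE_FLOOR) -> np.ndarray:
    """Per-CpG t-like statistic: (mean g1 − mean g2) / sqrt(pooled within-group
    variance + floor). Sites lacking a smoothed value in any sample are NaN."""
    if groups is None:
        groups = s.group_labels()
    if len(groups) != 2:
        raise ConfigurationError("exactly two groups required")
    i1, i2 = s.sample_index(groups[0]), s.sample_index(groups[1])
    if len(i1) < 2 or len(i2) < 2:
        raise ConfigurationError("each group needs >= 2 samples")
    x1, x2 = s.smooth[:, i1], s.smooth[:, i2]
    mask = np.isnan(x1).any(axis=1) | np.isnan(x2).any(axis=1)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    n1, n2 = len(i1), len(i2)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    stat = (m1 - m2) / np.sqrt(pooled + variance_floor)
    stat[mask] = np.nan
    return stat


def _pooled_delta(m: CpGMethylomeMatrix, idx: np.ndarray,
                  groups: Sequence[str]) -> tuple[float, float, float]:
    """Region ΔMe from raw pooled counts: per CpG the coverage-pooled group
    fraction, averaged over the region's CpGs."""
    me1, t1 = m.pooled_counts(groups[0])
    me2, t2 = m.pooled_counts(groups[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = me1[idx] / t1[idx]
        f2 = me2[idx] / t2[idx]
    g1 = float(np.nanmean(f1))
    g2 = float(np.nanmean(f2))
    return g1, g2, g1 - g2


def call_dmrs(stat: np.ndarray, s: SmoothedTrack, m: CpGMethylomeMatrix,
              cutoff_quantiles: tuple = (0.025, 0.975), min_cpg: int = 3,
              min_abs_delta: float = 0.1, max_gap_bp: int = 300,
              groups: Optional[Sequence[str]] = None) -> list[DMR]:
    """Call DMRs as maximal runs of CpGs whose statistic lies beyond the
    empirical quantile cutoffs, merged across short gaps, then kept only if
    the raw pooled-count |ΔMe| over the run is at least min_abs_delta."""
    if groups is None:
        groups = s.group_labels()
    valid = ~np.isnan(stat)
    if valid.sum() == 0:
        return []
    lo_cut, hi_cut = np.quantile(stat[valid], cutoff_quantiles)
    chrom_str = m.chrom.astype(str)
    dmrs: list[DMR] = []
    for sign, mask in (("g1_hyper", valid & (stat > hi_cut)),
                       ("g2_hyper", valid & (stat < lo_cut))):
        for chrom in np.unique(chrom_str):
            cidx = np.flatnonzero((chrom_str == chrom) & mask)
            if len(cidx) == 0:
                continue
            # merge consecutive flagged CpGs across gaps <= max_gap_bp
            runs = []
            run_start = cidx[0]
            prev = cidx[0]
            for j in cidx[1:]:
                if m.pos[j] - m.pos[prev] <= max_gap_bp:
                    prev = j
                else:
                    runs.append((run_start, prev))
                    run_start = prev = j
            runs.append((run_start, prev))
            for a, b in runs:
                if int(mask[a:b + 1].sum()) < min_cpg:
                    continue
                # ΔMe and n_cpg cover every CpG in the emitted interval,
                # including any bridged by the gap merge
                idx = np.arange(a, b + 1)
                g1, g2, delta = _pooled_delta(m, idx, groups)
                if not np.isfinite(delta) or abs(delta) < min_abs_delta:
                    continue
                dmrs.append(DMR(chrom, int(m.pos[a]), int(m.pos[b]) + 1,
                                int(len(idx)), g1, g2, delta,
                                "g1_hyper" if delta > 0 else "g2_hyper",
                                float(np.nansum(stat[a:b + 1]))))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    for i, d in enumerate(dmrs):
        d.dmr_id = f"dmr_{i + 1:05d}"
    return dmrs


def stratify_dmrs(dmrs: list[DMR]) -> tuple[list[DMR], dict]:
    """Attach Low/High and fine ΔMe strata; return (dmrs, count table).

    Low: 0.1 <= |ΔMe| < 0.3; High: |ΔMe| >= 0.3; fine bins
    [0.1,0.2), [0.2,0.3), [0.3,0.4), >= 0.4 (closed-left).
    """
    counts = {"low": 0, "high": 0}
    fine_counts = {b: 0 for b in FINE_BINS}
    for d in dmrs:
        a = abs(d.delta_me)
        if a < 0.1:
            raise ConfigurationError(
                f"DMR {d.dmr_id or ''} |delta_me|={a:.4f} < 0.1 violates the contract")
        d.stratum = "high" if a >= 0.3 else "low"
        if a < 0.2:
            d.fine_stratum = FINE_BINS[0]
        elif a < 0.3:
            d.fine_stratum = FINE_BINS[1]
        elif a < 0.4:
            d.fine_stratum = FINE_BINS[2]
        else:
            d.fine_stratum = FINE_BINS[3]
        d.direction = "g1_hyper" if d.delta_me > 0 else "g2_hyper"
        counts[d.stratum] += 1
        fine_counts[d.fine_stratum] += 1
    return dmrs, {"stratum": counts, "fine_stratum": fine_counts}
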