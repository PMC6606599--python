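"""Overlap-based enrichment statistics and profile summaries.

Hypergeometric peak enrichment (exact upper tail), High/Low log2 overlap
ratios, the Cochran–Armitage trend test, TSS-anchored loess metaplots,
feature-anchored signal matrices, classical multidimensional scaling of
methylomes, and hierarchical co-occurrence clustering of binary
feature × TF matrices.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .types import (ConfigurationError, CpGMethylomeMatrix, EnrichmentResult,
                    GenomicFeature, MethTrack, TrendTestResult)


def _peak_trees(peaks: Sequence[GenomicFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _contains_peak(f, trees: dict[str, IntervalTree]) -> bool:
    t = trees.get(f.chrom)
    return bool(t and t.overlap(f.start, f.end))


def overlap_enrichment(features: Sequence[GenomicFeature],
                       peaks: Sequence[GenomicFeature],
                       universe_features: Sequence[GenomicFeature],
                       tf_name: str = "",
                       feature_class: str = "") -> EnrichmentResult:
    """Exact upper-tail hypergeometric test of peak-containing features.

    Success = the feature shares >= 1 bp with >= 1 peak. With N universe
    features of which K contain peaks, and n tested features of which k
    contain peaks, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    n, N = len(features), len(universe_features)
    if n > N:
        raise ConfigurationError("feature set larger than its universe")
    trees = _peak_trees(peaks)
    k = sum(_contains_peak(f, trees) for f in features)
    K = sum(_contains_peak(f, trees) for f in universe_features)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(feature_class or (features[0].feature_class if features else ""),
                            tf_name, n, int(k), N, int(K), min(p, 1.0))


def high_low_ratio(dmrs: Sequence, peaks_by_tf: dict[str, Sequence[GenomicFeature]]
                   ) -> list[dict]:
    """Per-TF log2 of (% High DMRs with a peak) / (% Low DMRs with a peak).

    Zero numerator or denominator yields an infinite sentinel with a flag,
    never a silent drop.
    """
    high = [d for d in dmrs if d.stratum == "high"]
    low = [d for d in dmrs if d.stratum == "low"]
    if not high or not low:
        raise ConfigurationError("need >= 1 DMR in each of the High/Low strata")
    out = []
    for tf, peaks in sorted(peaks_by_tf.items()):
        trees = _peak_trees(peaks)
        k_high = sum(_contains_peak(d, trees) for d in
                     (x.to_feature() for x in high))
        k_low = sum(_contains_peak(d, trees) for d in
                    (x.to_feature() for x in low))
        f_high = k_high / len(high)
        f_low = k_low / len(low)
        if k_high == 0 and k_low == 0:
            ratio, flag = float("nan"), "undefined"
        elif k_low == 0:
            ratio, flag = float("inf"), "infinite"
        elif k_high == 0:
            ratio, flag = float("-inf"), "infinite"
        else:
            ratio, flag = float(np.log2(f_high / f_low)), "finite"
        out.append({"tf_name": tf, "k_high": k_high, "n_high": len(high),
                    "k_low": k_low, "n_low": len(low),
                    "log2_ratio_high_low": ratio, "flag": flag})
    return out


def trend_chi2(strata: Sequence[tuple[int, int]],
               scores: Optional[Sequence[float]] = None,
               labels: Optional[Sequence[str]] = None) -> TrendTestResult:
    """Cochran–Armitage 1-df chi-squared test for trend in proportions.

    ``strata``: ordered (successes, totals) pairs; default scores 1..k.
    chi2 = [Σ s_i (k_i − n_i p̄)]² / [p̄(1−p̄)(Σ n_i s_i² − (Σ n_i s_i)²/N)].
    """
    if len(strata) < 2:
        raise ConfigurationError("need >= 2 strata")
    succ = np.array([int(s) for s, _ in strata], dtype=float)
    tot = np.array([int(t) for _, t in strata], dtype=float)
    if np.any(succ < 0) or np.any(succ > tot):
        raise ConfigurationError("successes must satisfy 0 <= k <= n")
    s = np.asarray(scores if scores is not None
                   else np.arange(1, len(strata) + 1), dtype=float)
    N = tot.sum()
    pbar = succ.sum() / N
    if pbar in (0.0, 1.0):
        chi2, p = 0.0, 1.0
    else:
        num = (s * (succ - tot * pbar)).sum() ** 2
        den = pbar * (1 - pbar) * ((tot * s ** 2).sum() - (tot * s).sum() ** 2 / N)
        chi2 = float(num / den) if den > 0 else 0.0
        p = float(sps.chi2.sf(chi2, df=1))
    lab = list(labels) if labels is not None else [str(i + 1) for i in range(len(strata))]
    return TrendTestResult(lab, succ.astype(int), tot.astype(int), chi2, p)


# ---------------------------------------------------------------------------
# profiles


def _loess_grid(x: np.ndarray, y: np.ndarray, w: np.ndarray, grid: np.ndarray,
                span: float) -> np.ndarray:
    """Tricube-weighted local-linear regression on a fixed grid with a
    nearest-neighbour bandwidth of ceil(span * n) points."""
    order = np.argsort(x, kind="stable")
    x, y, w = x[order], y[order], w[order]
    n = len(x)
    k = max(int(np.ceil(span * n)), 3)
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        j = np.searchsorted(x, g)
        lo = max(0, j - k)
        hi = min(n, j + k)
        dx = x[lo:hi] - g
        ad = np.abs(dx)
        if hi - lo > k:
            cut = np.partition(ad, k - 1)[k - 1]
            sel = ad <= cut
            dx, ad = dx[sel], ad[sel]
            yy, ww = y[lo:hi][sel], w[lo:hi][sel]
        else:
            yy, ww = y[lo:hi], w[lo:hi]
        bw = max(ad.max(), 1e-9) * 1.0001
        tri = (1 - (ad / bw) ** 3) ** 3
        wt = tri * ww
        s0, s1, s2 = wt.sum(), (wt * dx).sum(), (wt * dx ** 2).sum()
        t0, t1 = (wt * yy).sum(), (wt * yy * dx).sum()
        det = s0 * s2 - s1 * s1
        out[i] = (s2 * t0 - s1 * t1) / det if det > 1e-12 else t0 / max(s0, 1e-12)
    return out


def tss_metaplot(track: MethTrack, genes: Sequence, flank_bp: int = 4000,
                 n_bins: int = 200, loess_span: float = 0.2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Loess-smoothed methylation profile around TSSs.

    CpGs within ±flank of each TSS are pooled as (strand-oriented distance,
    methylation) pairs, coverage-weighted, and smoothed on a fixed grid.
    Returns (grid positions, smoothed values).
    """
    if not len(genes):
        raise ConfigurationError("no genes supplied")
    xs, ys, ws = [], [], []
    cs = track.chrom.astype(str)
    for g in genes:
        idx = np.flatnonzero(cs == g.chrom)
        pos = track.pos[idx]
        lo = np.searchsorted(pos, g.tss - flank_bp, "left")
        hi = np.searchsorted(pos, g.tss + flank_bp, "right")
        if hi <= lo:
            continue
        d = (pos[lo:hi] - g.tss).astype(float)
        if g.strand == "-":
            d = -d
        v = track.value[idx[lo:hi]]
        w = track.weight[idx[lo:hi]]
        ok = np.isfinite(v)
        xs.append(d[ok]); ys.append(v[ok]); ws.append(w[ok])
    if not xs or not len(np.concatenate(xs)):
        raise ConfigurationError("no covered CpGs in any TSS window")
    x = np.concatenate(xs); y = np.concatenate(ys); w = np.concatenate(ws)
    grid = np.linspace(-flank_bp, flank_bp, n_bins)
    return grid, _loess_grid(x, y, w, grid, loess_span)


def anchored_signal_matrix(signal: MethTrack, features: Sequence[GenomicFeature],
                           flank_bp: int = 2000, n_bins: int = 100,
                           order_by: Optional[np.ndarray] = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature-centred signal matrix (rows = features, columns = bins).

    Each row averages the signal per bin across [centre − flank,
    centre + flank); rows are sorted ascending by ``order_by`` (default:
    the row's mean signal). Returns (matrix, row order, column means).
    """
    if not len(features):
        raise ConfigurationError("no features supplied")
    cs = signal.chrom.astype(str)
    mat = np.full((len(features), n_bins), np.nan)
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    for fi, f in enumerate(features):
        centre = (f.start + f.end) // 2
        idx = np.flatnonzero(cs == f.chrom)
        pos = signal.pos[idx]
        lo = np.searchsorted(pos, centre - flank_bp, "left")
        hi = np.searchsorted(pos, centre + flank_bp, "right")
        if hi <= lo:
            continue
        d = pos[lo:hi] - centre
        v = signal.value[idx[lo:hi]]
        which = np.digitize(d, edges) - 1
        ok = (which >= 0) & (which < n_bins) & np.isfinite(v)
        for b in range(n_bins):
            sel = ok & (which == b)
            if sel.any():
                mat[fi, b] = float(np.mean(v[sel]))
    if order_by is None:
        with np.errstate(invalid="ignore"):
            order_by = np.nanmean(mat, axis=1)
    order = np.argsort(np.asarray(order_by), kind="stable")
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(mat[order], axis=0)
    return mat[order], order, col_means


# ---------------------------------------------------------------------------
# sample-level structure


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson double-centering MDS of a distance matrix, with a
    deterministic sign convention (first nonzero loading positive)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)[None, :]
    for d in range(coords.shape[1]):
        col = coords[:, d]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, d] = -col
    return coords


def mds_methylation(m: CpGMethylomeMatrix, min_cov: int = 5, k: int = 2
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of samples.

    Distance: mean absolute difference of per-site methylation fractions
    over sites with coverage >= min_cov in every sample.
    """
    if len(m.samples) < 3:
        raise ConfigurationError("need >= 3 samples")
    keep = np.all(m.total >= min_cov, axis=1)
    if not keep.any():
        raise ConfigurationError("no sites covered >= min_cov in all samples")
    frac = m.meth[keep] / m.total[keep]
    n = frac.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = float(np.mean(np.abs(frac[:, i] - frac[:, j])))
    return classical_mds(D, k), D


def cluster_binary_matrix(matrix: np.ndarray, n_clusters: Optional[int] = None,
                          distance_threshold: float = 0.999
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-linkage hierarchical clustering of a binary matrix on
    Jaccard distance, for rows and columns. Returns (row order, column
    order, row cluster labels); leaf order is deterministic (scipy ties
    resolve by index)."""
    mat = np.asarray(matrix, dtype=bool)
    if mat.size == 0:
        raise ConfigurationError("empty matrix")
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ConfigurationError("need >= 2 rows and columns")

    def _order(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = pdist(x, metric="jaccard")
        Z = sch.linkage(d, method="complete")
        return sch.leaves_list(Z), Z

    row_order, zr = _order(mat)
    col_order, _ = _order(mat.T)
    if n_clusters is not None:
        labels = sch.fcluster(zr, t=n_clusters, criterion="maxclust")
    else:
        labels = sch.fcluster(zr, t=distance_threshold, criterion="distance")
    return row_order, col_order, labels
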