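"""Joining methylation features to genes and expression.

Covers promoter definition (TSS ± 2 kb), nearest protein-coding gene
assignment, negative-binomial Wald differential expression, DE × DM
quadrant records with inverse/concordant labels, methylation "cliff"
detection, DMV association, and the D-LMR construction (lowest-quartile
LMRs of one cell type overlapping DMRs hypermethylated in the other).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import (ConfigurationError, CpGMethylomeMatrix, DEDMRecord,
                    DEResult, DMR, ExpressionCounts, GeneModel, GenomicFeature,
                    Segment)


# ---------------------------------------------------------------------------
# promoters and nearest genes


def define_promoters(genes: Sequence[GeneModel], flank_bp: int = 2000,
                     chrom_sizes: Optional[dict] = None) -> list[GenomicFeature]:
    """Strand-independent window [tss - flank, tss + flank) clipped to the
    chromosome; a zero flank degenerates to the single TSS base."""
    out = []
    for g in genes:
        start = max(0, g.tss - flank_bp)
        end = g.tss + flank_bp
        if chrom_sizes and g.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.chrom])
        if end <= start:
            start, end = g.tss, g.tss + 1
        out.append(GenomicFeature(g.chrom, start, end, "PROMOTER",
                                  {"gene_id": g.gene_id, "strand": g.strand}))
    return out


def nearest_protein_coding_gene(feature: GenomicFeature,
                                genes: Sequence[GeneModel]
                                ) -> tuple[Optional[str], Optional[float]]:
    """Nearest protein-coding gene by |feature midpoint − TSS|; ties broken
    by lexicographically smaller gene id. (None, None) when the feature's
    chromosome has no protein-coding gene."""
    cand = [g for g in genes
            if g.biotype == "protein_coding" and g.chrom == feature.chrom]
    if not cand:
        return None, None
    mid = feature.midpoint
    best = min(cand, key=lambda g: (abs(mid - g.tss), g.gene_id))
    return best.gene_id, abs(mid - best.tss)


# ---------------------------------------------------------------------------
# differential expression


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.astype(float))
    usable = np.all(np.isfinite(logc), axis=1)
    if not usable.any():
        return np.ones(counts.shape[1])
    ref = logc[usable].mean(axis=1)
    sf = np.exp(np.median(logc[usable] - ref[:, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def call_de(counts: ExpressionCounts, groups: Optional[Sequence[str]] = None,
            alpha: float = 0.001, lfc_min: float = 0.0,
            dispersion_floor: float = 0.01) -> list[DEResult]:
    """Per-gene NB Wald test of group 1 vs group 2.

    Counts are library-size normalised (median of ratios); the log2 fold
    change uses a 0.5 pseudocount; the Wald standard error uses a
    method-of-moments NB dispersion pooled across genes (median of the
    per-gene moment estimates, floored), which keeps the test calibrated
    with few replicates. Benjamini–Hochberg FDR across genes.
    """
    if groups is None:
        seen: list[str] = []
        for s in counts.samples:
            g = counts.groups[s]
            if g not in seen:
                seen.append(g)
        groups = seen
    if len(groups) != 2:
        raise ConfigurationError("exactly two groups required")
    i1, i2 = counts.sample_index(groups[0]), counts.sample_index(groups[1])
    n1, n2 = len(i1), len(i2)
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs >= 2 replicates")
    if len(counts.gene_ids) == 0:
        return []

    sf = _size_factors(counts.counts)
    norm = counts.counts / sf[None, :]
    x1, x2 = norm[:, i1], norm[:, i2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = np.log2((m1 + 0.5) / (m2 + 0.5))

    # method-of-moments dispersion, pooled across genes
    v = ((x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1))
         / (n1 + n2 - 2))
    mu = (m1 * n1 + m2 * n2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = (v - mu) / mu ** 2
    ok = np.isfinite(alpha_mom) & (mu > 0)
    # mean (not median) of the moment estimates: per-gene estimates with few
    # replicates are right-skewed, and the median underestimates dispersion,
    # which anti-conservatively shrinks the Wald standard error
    disp = float(np.mean(alpha_mom[ok])) if ok.any() else dispersion_floor
    disp = max(disp, dispersion_floor)

    eps = 1e-8
    se2 = (1.0 / np.log(2) ** 2) * (
        (1.0 / np.maximum(m1, eps) + disp) / n1
        + (1.0 / np.maximum(m2, eps) + disp) / n2)
    z = lfc / np.sqrt(se2)
    p = 2.0 * sps.norm.sf(np.abs(z))
    zero = (counts.counts.sum(axis=1) == 0)
    p[zero] = 1.0
    lfc[zero] = 0.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return [DEResult(g, float(lfc[i]), float(p[i]), float(fdr[i]),
                     bool(fdr[i] < alpha and abs(lfc[i]) >= lfc_min))
            for i, g in enumerate(counts.gene_ids)]


# ---------------------------------------------------------------------------
# DE × DM integration


QUADRANTS = ("meth-up/expr-up", "meth-up/expr-down",
             "meth-down/expr-up", "meth-down/expr-down")


def dedm_quadrants(de: Sequence[DEResult], dmrs: Sequence[DMR],
                   promoters: Sequence[GenomicFeature],
                   min_abs_delta: float = 0.2
                   ) -> tuple[list[DEDMRecord], dict]:
    """One record per (DE gene, promoter-overlapping DMR with |ΔMe| >=
    min_abs_delta) pair. Quadrants are w.r.t. group 1; concordant means the
    methylation and expression differences share a sign. A gene with DMRs
    in both directions yields records in two quadrants."""
    de_by_gene = {r.gene_id: r for r in de if r.is_de}
    prom_by_gene: dict[str, GenomicFeature] = {}
    for p in promoters:
        gid = p.attributes.get("gene_id")
        if gid is not None:
            prom_by_gene[gid] = p
    records: list[DEDMRecord] = []
    for gid, der in sorted(de_by_gene.items()):
        prom = prom_by_gene.get(gid)
        if prom is None:
            continue
        for d in dmrs:
            if abs(d.delta_me) < min_abs_delta:
                continue
            if d.chrom != prom.chrom or d.start >= prom.end or d.end <= prom.start:
                continue
            meth = "meth-up" if d.delta_me > 0 else "meth-down"
            expr = "expr-up" if der.log2fc > 0 else "expr-down"
            conc = ("concordant"
                    if (d.delta_me > 0) == (der.log2fc > 0) else "inverse")
            records.append(DEDMRecord(gid, d.dmr_id or "", f"{meth}/{expr}",
                                      conc, d.delta_me, der.log2fc))
    table = {q: 0 for q in QUADRANTS}
    gene_table = {q: set() for q in QUADRANTS}
    for r in records:
        table[r.quadrant] += 1
        gene_table[r.quadrant].add(r.gene_id)
    summary = {
        "records": table,
        "genes": {q: len(s) for q, s in gene_table.items()},
        "n_records": len(records),
        "n_genes": len({r.gene_id for r in records}),
        "n_inverse": sum(r.concordance == "inverse" for r in records),
        "n_concordant": sum(r.concordance == "concordant" for r in records),
    }
    return records, summary


def region_group_means(m: CpGMethylomeMatrix, chrom: str, start: int, end: int,
                       groups: Sequence[str]) -> Optional[tuple[float, float]]:
    """Per-group pooled methylation averaged over the region's CpGs."""
    cs = m.chrom.astype(str)
    idx = np.flatnonzero((cs == chrom) & (m.pos >= start) & (m.pos < end))
    if len(idx) == 0:
        return None
    out = []
    for g in groups:
        me, t = m.pooled_counts(g)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = me[idx] / t[idx]
        out.append(float(np.nanmean(f)))
    return tuple(out)  # type: ignore[return-value]


def detect_cliffs(records: list[DEDMRecord], dmrs: Sequence[DMR],
                  m: CpGMethylomeMatrix, low_meth_cutoff: float = 0.25,
                  groups: Optional[Sequence[str]] = None
                  ) -> tuple[list[DEDMRecord], dict]:
    """Flag records whose DMR sits on a methylation cliff: the less
    methylated cell type averages <= low_meth_cutoff over the region."""
    if groups is None:
        groups = m.group_labels()
    by_id = {d.dmr_id: d for d in dmrs if d.dmr_id}
    n_undefined = 0
    for r in records:
        d = by_id.get(r.dmr_id)
        if d is None:
            r.cliff = None
            n_undefined += 1
            continue
        means = region_group_means(m, d.chrom, d.start, d.end, groups)
        if means is None or not all(np.isfinite(means)):
            r.cliff = None
            n_undefined += 1
            continue
        r.cliff = bool(min(means) <= low_meth_cutoff)
    def _frac(rs):
        flags = [r.cliff for r in rs if r.cliff is not None]
        return float(np.mean(flags)) if flags else float("nan")
    high = [r for r in records if abs(r.delta_me) >= 0.3]
    other = [r for r in records if abs(r.delta_me) < 0.3]
    summary = {"cliff_fraction_high": _frac(high),
               "cliff_fraction_other": _frac(other),
               "n_high": len(high), "n_other": len(other),
               "n_undefined": n_undefined}
    return records, summary


def dmv_association(records: list[DEDMRecord], dmrs: Sequence[DMR],
                    dmvs_by_group: dict[str, list[Segment]]
                    ) -> tuple[list[DEDMRecord], dict]:
    """Flag records whose DMR overlaps any group's DMV; emit a contingency
    table of High/cliff status × DMV membership for trend testing."""
    by_id = {d.dmr_id: d for d in dmrs if d.dmr_id}
    all_dmvs = [s for segs in dmvs_by_group.values() for s in segs]
    for r in records:
        d = by_id.get(r.dmr_id)
        if d is None:
            r.in_dmv = False
            continue
        r.in_dmv = any(d.chrom == v.chrom and d.start < v.end and v.start < d.end
                       for v in all_dmvs)
    def cell(pred):
        sel = [r for r in records if pred(r)]
        return (sum(bool(r.in_dmv) for r in sel), len(sel))
    summary = {
        "high": cell(lambda r: abs(r.delta_me) >= 0.3),
        "low": cell(lambda r: abs(r.delta_me) < 0.3),
        "cliff": cell(lambda r: r.cliff is True),
        "non_cliff": cell(lambda r: r.cliff is False),
    }
    return records, summary


def call_dlmrs(lmrs_by_group: dict[str, list[Segment]], dmrs: Sequence[DMR],
               meth_quantile: float = 0.25,
               group_order: Optional[Sequence[str]] = None
               ) -> dict[str, list[GenomicFeature]]:
    """Candidate differential enhancers: for each group, its LMRs in the
    lowest ``meth_quantile`` of that group's LMR methylation distribution
    that overlap (>= 1 bp) a DMR hypermethylated in the other group."""
    if group_order is None:
        group_order = sorted(lmrs_by_group)
    if len(group_order) != 2:
        raise ConfigurationError("D-LMR construction needs exactly two groups")
    out: dict[str, list[GenomicFeature]] = {}
    for gi, g in enumerate(group_order):
        lmrs = [s for s in lmrs_by_group[g] if s.seg_class == "LMR"]
        if len(lmrs) < 4:
            raise ConfigurationError(
                f"group {g!r} has {len(lmrs)} LMRs; quantile undefined")
        meths = np.array([s.mean_meth for s in lmrs])
        thr = float(np.quantile(meths, meth_quantile))
        opposite = "g2_hyper" if gi == 0 else "g1_hyper"
        picked = []
        for s in lmrs:
            if s.mean_meth > thr:
                continue
            support = [d for d in dmrs
                       if d.direction == opposite and d.chrom == s.chrom
                       and d.start < s.end and s.start < d.end]
            if support:
                picked.append(GenomicFeature(
                    s.chrom, s.start, s.end, "DLMR",
                    {"group": g, "mean_meth": round(s.mean_meth, 6),
                     "n_cpg": s.n_cpg,
                     "support_dmr": ",".join(d.dmr_id or "?" for d in support)}))
        out[g] = picked
    return out
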