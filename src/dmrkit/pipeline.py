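"""End-to-end pipeline on synthetic data: simulate → DMR call → segment →
integrate → enrich. Returns an in-memory bundle of every stage's output."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import dmr as dmrmod
from . import enrich as enrichmod
from . import integrate as integmod
from . import segments as segmod
from .simulate import (SimConfig, SyntheticReference, build_reference,
                       simulate_expression, simulate_methylomes, simulate_peaks)
from .types import (CpGMethylomeMatrix, DEDMRecord, DEResult, DMR,
                    ExpressionCounts, GenomicFeature, MethTrack, Segment,
                    SmoothedTrack)


@dataclass
class PipelineResult:
    ref: SyntheticReference
    methylome: CpGMethylomeMatrix
    smoothed: SmoothedTrack
    stat: np.ndarray
    dmrs: list[DMR]
    stratum_table: dict
    segments_by_group: dict[str, list[Segment]]
    dmvs_by_group: dict[str, list[Segment]]
    expression: ExpressionCounts
    de_results: list[DEResult]
    promoters: list[GenomicFeature]
    dedm_records: list[DEDMRecord]
    dedm_summary: dict
    cliff_summary: dict
    dmv_summary: dict
    dlmrs: dict[str, list[GenomicFeature]]
    peaks: dict[str, list[GenomicFeature]]
    tracks: dict[str, MethTrack] = field(default_factory=dict)

    def lmrs(self, group: str) -> list[Segment]:
        return [s for s in self.segments_by_group[group] if s.seg_class == "LMR"]

    def umrs(self, group: str) -> list[Segment]:
        return [s for s in self.segments_by_group[group] if s.seg_class == "UMR"]


DEFAULT_TF_SPECS = (
    ("PPARG", 400, "lmr_biased"),
    ("CEBPB", 400, "lmr_biased"),
    ("CTCF", 1000, "uniform"),
    ("EZH2", 60, "high_dmr_promoter_biased"),
)


def run_pipeline(config: Optional[SimConfig] = None, seed: int = 0,
                 tf_specs=DEFAULT_TF_SPECS) -> PipelineResult:
    cfg = config or SimConfig()
    ref = build_reference(cfg, seed=seed)
    g1, g2 = cfg.group_names

    methylome = simulate_methylomes(ref, n_per_group=cfg.n_per_group,
                                    mean_coverage=cfg.mean_coverage, seed=seed)
    expression = simulate_expression(ref, n_per_group=cfg.n_per_group, seed=seed)
    peaks = simulate_peaks(ref, tf_specs, seed=seed)

    smoothed = dmrmod.smooth_methylation(methylome)
    stat = dmrmod.group_difference_stat(smoothed)
    dmrs = dmrmod.call_dmrs(stat, smoothed, methylome)
    dmrs, stratum_table = dmrmod.stratify_dmrs(dmrs)

    tracks = {g: MethTrack.pooled(methylome, g) for g in (g1, g2)}
    segments_by_group: dict[str, list[Segment]] = {}
    dmvs_by_group: dict[str, list[Segment]] = {}
    for g in (g1, g2):
        segs = segmod.call_segments(tracks[g])
        segments_by_group[g] = segs
        dmvs_by_group[g] = segmod.call_dmvs(
            [s for s in segs if s.seg_class == "UMR"], tracks[g])

    de_results = integmod.call_de(expression, groups=[g1, g2])
    promoters = integmod.define_promoters(ref.genes, chrom_sizes=ref.chrom_sizes)
    records, dedm_summary = integmod.dedm_quadrants(de_results, dmrs, promoters)
    records, cliff_summary = integmod.detect_cliffs(records, dmrs, methylome,
                                                    groups=[g1, g2])
    records, dmv_summary = integmod.dmv_association(records, dmrs, dmvs_by_group)

    lmrs_by_group = {g: [s for s in segments_by_group[g] if s.seg_class == "LMR"]
                     for g in (g1, g2)}
    dlmrs = integmod.call_dlmrs(lmrs_by_group, dmrs, group_order=[g1, g2])

    return PipelineResult(ref, methylome, smoothed, stat, dmrs, stratum_table,
                          segments_by_group, dmvs_by_group, expression,
                          de_results, promoters, records, dedm_summary,
                          cliff_summary, dmv_summary, dlmrs, peaks, tracks)


def promoter_stratum_peak_trend(result: PipelineResult, tf_name: str
                                ) -> "enrichmod.TrendTestResult":
    """Peak presence in promoter DMRs across the four ΔMe strata."""
    prom_dmrs = []
    for d in result.dmrs:
        for p in result.promoters:
            if d.chrom == p.chrom and d.start < p.end and p.start < d.end:
                prom_dmrs.append(d)
                break
    peaks = result.peaks[tf_name]
    trees = enrichmod._peak_trees(peaks)
    bins = ("0.1-0.2", "0.2-0.3", "0.3-0.4", ">=0.4")
    strata = []
    for b in bins:
        sel = [d for d in prom_dmrs if d.fine_stratum == b]
        k = sum(enrichmod._contains_peak(d.to_feature(), trees) for d in sel)
        strata.append((k, len(sel)))
    return enrichmod.trend_chi2(strata, labels=list(bins))
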