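"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere. CpG sites are the C of the
CpG dinucleotide on the + strand; both-strand counts are assumed pre-merged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class DmrkitError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(DmrkitError):
    pass


class ParseError(DmrkitError):
    pass


@dataclass
class CpGMethylomeMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``chrom``/``pos`` are parallel arrays of length S, sorted by
    (chrom, pos). ``meth`` and ``total`` are (S, n_samples) integer arrays.
    """

    chrom: np.ndarray          # (S,) str
    pos: np.ndarray            # (S,) int64, 0-based
    samples: list[str]
    groups: dict[str, str]     # sample id -> group label
    meth: np.ndarray           # (S, n) int
    total: np.ndarray          # (S, n) int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        if self.meth.shape != self.total.shape:
            raise ConfigurationError("meth and total shapes differ")
        if self.meth.shape != (len(self.pos), len(self.samples)):
            raise ConfigurationError("count matrix shape does not match sites × samples")
        if np.any(self.meth > self.total):
            raise ConfigurationError("methylated reads exceed total reads")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ConfigurationError("negative read counts")
        for s in self.samples:
            if s not in self.groups:
                raise ConfigurationError(f"sample {s!r} has no group label")
        # sorted by (chrom, pos)
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            raise ConfigurationError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.groups[s] == group], dtype=int)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def pooled_fraction(self, group: str) -> np.ndarray:
        """Pooled methylation fraction per site: sum(meth)/sum(total) over
        the group's samples. NaN where the pooled total is zero."""
        idx = self.sample_index(group)
        m = self.meth[:, idx].sum(axis=1).astype(float)
        t = self.total[:, idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / t, np.nan)

    def pooled_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.sample_index(group)
        return (self.meth[:, idx].sum(axis=1), self.total[:, idx].sum(axis=1))


@dataclass
class MethTrack:
    """Pooled methylation values along CpG sites of one group (or any
    per-site scalar signal with weights)."""

    chrom: np.ndarray
    pos: np.ndarray
    value: np.ndarray
    weight: np.ndarray

    @classmethod
    def pooled(cls, m: "CpGMethylomeMatrix", group: str) -> "MethTrack":
        idx = m.sample_index(group)
        meth = m.meth[:, idx].sum(axis=1).astype(float)
        total = m.total[:, idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(total > 0, meth / total, np.nan)
        return cls(m.chrom, m.pos, val, total)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom.astype(str) == chrom)


@dataclass
class SmoothedTrack:
    """Per-sample smoothed methylation fractions at the matrix's sites.

    ``smooth`` is (S, n_samples) float with NaN where the sample's coverage
    was below the smoothing min_cov.
    """

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    groups: dict[str, str]
    smooth: np.ndarray

    def sample_index(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.groups[s] == group], dtype=int)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if not self.start < self.end:
            raise ParseError(f"gene {self.gene_id}: start >= end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomicFeature:
    """Generic labelled interval: DMR, UMR, LMR, DMV, PEAK, PROMOTER, DLMR."""

    chrom: str
    start: int
    end: int
    feature_class: str
    attributes: dict = field(default_factory=dict)

    VALID_CLASSES = ("DMR", "UMR", "LMR", "DMV", "PEAK", "PROMOTER", "DLMR")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ParseError(
                f"feature {self.feature_class} {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.feature_class not in self.VALID_CLASSES:
            raise ParseError(f"unknown feature class {self.feature_class!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth_g1: float
    mean_meth_g2: float
    delta_me: float            # mean_meth_g1 - mean_meth_g2, pooled counts
    direction: str             # "g1_hyper" | "g2_hyper"
    area_stat: float
    stratum: Optional[str] = None       # "low" | "high"
    fine_stratum: Optional[str] = None  # "0.1-0.2" | "0.2-0.3" | "0.3-0.4" | ">=0.4"
    dmr_id: Optional[str] = None

    def to_feature(self) -> GenomicFeature:
        attrs = {
            "n_cpg": self.n_cpg,
            "mean_meth_g1": round(self.mean_meth_g1, 6),
            "mean_meth_g2": round(self.mean_meth_g2, 6),
            "delta_me": round(self.delta_me, 6),
            "direction": self.direction,
            "area_stat": round(self.area_stat, 4),
        }
        if self.stratum is not None:
            attrs["stratum"] = self.stratum
        if self.fine_stratum is not None:
            attrs["fine_stratum"] = self.fine_stratum
        if self.dmr_id is not None:
            attrs["id"] = self.dmr_id
        return GenomicFeature(self.chrom, self.start, self.end, "DMR", attrs)


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth: float
    seg_class: str             # "UMR" | "LMR" | "DMV"

    def to_feature(self) -> GenomicFeature:
        return GenomicFeature(
            self.chrom, self.start, self.end, self.seg_class,
            {"n_cpg": self.n_cpg, "mean_meth": round(self.mean_meth, 6)})


@dataclass
class ExpressionCounts:
    gene_ids: list[str]
    samples: list[str]
    counts: np.ndarray         # (genes, samples) int
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ConfigurationError("count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ConfigurationError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConfigurationError("duplicated gene id")
        for s in self.samples:
            if s not in self.groups:
                raise ConfigurationError(f"sample {s!r} has no group label")

    def sample_index(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.groups[s] == group], dtype=int)


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    p: float
    fdr: float
    is_de: bool


@dataclass
class DEDMRecord:
    gene_id: str
    dmr_id: str
    quadrant: str      # e.g. "meth-up/expr-down" w.r.t. group 1
    concordance: str   # "inverse" | "concordant"
    delta_me: float
    log2fc: float
    cliff: Optional[bool] = None
    in_dmv: Optional[bool] = None


@dataclass
class EnrichmentResult:
    feature_class: str
    tf_name: str
    n_features: int
    k_with_peak: int
    universe_N: int
    universe_K: int
    p_value: float
    log2_ratio_high_low: Optional[float] = None


@dataclass
class TrendTestResult:
    strata: list[str]
    successes: np.ndarray
    totals: np.ndarray
    chi2: float
    p: float
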