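"""Synthetic WGBS-like data with the statistical structure the pipeline assumes.

The generator lays out a two-chromosome genome of gene loci (CpG island +
shores + gene model), plants differentially methylated patches with graded
effect sizes, unmethylated/low-methylated segments, methylation valleys,
promoter "cliffs" and group-specific enhancer-like patches, then draws
read counts, expression counts and TF ChIP-like peaks on top.  Every
planted signal is recorded in a machine-readable truth object so that
recovery can be measured.

Randomness is organised as one independent stream per operation, derived
from the master seed plus an operation tag, so adding operations never
perturbs existing outputs.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (CpGMethylomeMatrix, ConfigurationError, ExpressionCounts,
                    GeneModel, GenomicFeature)

PEAK_WIDTH_DEFAULT = 300
FINE_BINS = ("0.1-0.2", "0.2-0.3", "0.3-0.4", ">=0.4")


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream per (seed, operation tag)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def fine_bin(abs_delta: float) -> str:
    if abs_delta < 0.1:
        raise ValueError("|delta| below 0.1 has no stratum")
    if abs_delta < 0.2:
        return FINE_BINS[0]
    if abs_delta < 0.3:
        return FINE_BINS[1]
    if abs_delta < 0.4:
        return FINE_BINS[2]
    return FINE_BINS[3]


@dataclass
class SimConfig:
    """Default parameters define the study conditions emulated in miniature."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    # CpG spacing (bp) by context
    island_spacing: tuple = (10, 20)
    shore_spacing: tuple = (25, 45)
    open_sea_spacing: tuple = (80, 120)
    patch_spacing: tuple = (40, 60)      # enhancer-like (LMR) patches
    dmr_spacing: tuple = (24, 40)        # planted DMR patches (CpG-dense)
    # landscape levels and Beta concentrations
    open_sea_level: float = 0.8
    island_level: float = 0.05
    conc_open_sea: float = 20.0
    conc_island: float = 50.0
    conc_patch: float = 150.0
    island_half_len: tuple = (350, 600)
    shore_width: int = 600
    # planted feature counts
    n_dedm: int = 40            # DE genes with a promoter DMR (10 of them cliffs)
    n_cliffs: int = 10
    n_promoter_dmr_only: int = 24
    n_intergenic_dmr: int = 40
    n_dmv: int = 6
    n_dmv_cliffs: int = 4       # DMV loci that also carry a dedm cliff
    n_shared_lmr: int = 60
    n_dlmr_per_group: int = 10
    n_extra_de: int = 40
    # effect-size mix
    inverse_fraction: float = 0.62
    # expression model
    expr_mean_log: float = np.log(300.0)
    expr_mean_sd: float = 0.8
    dispersion: float = 0.05
    lfc_range: tuple = (1.5, 3.0)
    # sequencing
    mean_coverage: float = 25.0
    n_per_group: int = 3
    group_names: tuple = ("SA", "VA")
    lncrna_fraction: float = 0.15
    tf_base_rate: float = 0.08
    tf_rate_by_stratum: tuple = (0.10, 0.20, 0.40, 0.65)

    def validate(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ConfigurationError("non-positive genome size")
        if self.n_genes < 0:
            raise ConfigurationError("negative gene count")
        if self.mean_coverage <= 0:
            raise ConfigurationError("non-positive coverage")

    def expected_island_cpg_share(self) -> float:
        """Analytic expectation of the fraction of CpGs inside islands."""
        if self.n_genes == 0:
            return 0.0
        isl_len = float(np.mean(self.island_half_len)) * 2
        isl_cpg = isl_len / np.mean(self.island_spacing)
        shore_cpg = 2 * self.shore_width / np.mean(self.shore_spacing)
        open_len = self.n_chroms * self.chrom_length - self.n_genes * (isl_len + 2 * self.shore_width)
        open_cpg = open_len / np.mean(self.open_sea_spacing)
        n_isl = self.n_genes
        total = n_isl * (isl_cpg + shore_cpg) + open_cpg
        return n_isl * isl_cpg / total


@dataclass
class PlantedDMR:
    dmr_id: str
    chrom: str
    start: int
    end: int
    delta_me: float       # signed, group1 - group2
    direction: str        # "g1_hyper" | "g2_hyper"
    fine_stratum: str
    n_cpg: int
    kind: str             # "promoter" | "intergenic" | "cliff" | "dlmr_support"


@dataclass
class PlantedSegment:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth: float


@dataclass
class PlantedCliff:
    chrom: str
    start: int
    end: int              # promoter span (island + shores)
    gene_id: str
    raised_group: str     # group methylated on the raised shore
    low_group: str
    raised_start: int
    raised_end: int


@dataclass
class SyntheticTruth:
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    planted_umrs: dict = field(default_factory=dict)   # group -> [PlantedSegment]
    planted_lmrs: dict = field(default_factory=dict)
    planted_dmvs: dict = field(default_factory=dict)
    planted_cliffs: list[PlantedCliff] = field(default_factory=list)
    de_genes: dict = field(default_factory=dict)       # gene_id -> true log2FC
    dedm_links: dict = field(default_factory=dict)     # gene_id -> (dmr_id, concordance)
    peak_truth: dict = field(default_factory=dict)     # tf name -> [(chrom,start,end)]

    def dmr_by_id(self, dmr_id: str) -> PlantedDMR:
        for d in self.planted_dmrs:
            if d.dmr_id == dmr_id:
                return d
        raise KeyError(dmr_id)


@dataclass
class SyntheticReference:
    chrom_sizes: dict
    cpg_positions: dict          # chrom -> int64 array, strictly increasing
    island_intervals: dict       # chrom -> [(start, end)]
    shore_intervals: dict
    genes: list[GeneModel]
    truth: SyntheticTruth
    config: SimConfig
    # latent methylation design, parallel to cpg_positions
    mean_base: dict = field(default_factory=dict)   # chrom -> float array
    shift: dict = field(default_factory=dict)       # chrom -> (S, 2) per-group additive shift
    conc: dict = field(default_factory=dict)        # chrom -> Beta concentration

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_sizes)

    def n_cpgs(self) -> int:
        return sum(len(self.cpg_positions[c]) for c in self.chroms)

    def group_mean(self, chrom: str, group_idx: int) -> np.ndarray:
        return np.clip(self.mean_base[chrom] + self.shift[chrom][:, group_idx], 0.0, 1.0)


# ---------------------------------------------------------------------------
# genome layout


class _Zone:
    """A contiguous stretch with its own CpG spacing and latent mean design."""

    __slots__ = ("start", "end", "spacing", "conc", "kind", "params")

    def __init__(self, start, end, spacing, conc, kind, params=None):
        self.start = int(start)
        self.end = int(end)
        self.spacing = spacing
        self.conc = conc
        self.kind = kind            # "flat" | "ramp" | "patch"
        self.params = params or {}

    def means(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (base mean, (n,2) shifts) at positions."""
        n = len(pos)
        shifts = np.zeros((n, 2))
        if self.kind == "flat":
            base = np.full(n, self.params["level"])
        elif self.kind == "ramp":
            # logistic rise from inner to outer level across the zone
            p = self.params
            d = (pos - self.start) if p["direction"] == "out" else (self.end - 1 - pos)
            frac = 1.0 / (1.0 + np.exp(-(d - p["mid"]) / p["scale"]))
            base = p["inner"] + (p["outer"] - p["inner"]) * frac
        elif self.kind == "patch":
            p = self.params
            base = np.full(n, p["base_level"])
            shifts[:, p["shift_group"]] = p["shift_value"]
        else:  # pragma: no cover
            raise ValueError(self.kind)
        return base, shifts


def _sample_delta(rng: np.random.Generator, bin_idx: int) -> float:
    """Effect size within a fine stratum, avoiding levels near the 0.5
    segmentation cutoff (see docs/methods.md)."""
    lo_hi = [(0.10, 0.20), (0.20, 0.27), (0.30, 0.40), (0.40, 0.50)]
    lo, hi = lo_hi[bin_idx]
    return float(rng.uniform(lo, hi))


def _dmr_levels(rng: np.random.Generator, delta: float,
                hypo_level: Optional[float] = None) -> tuple[float, int, float]:
    """Return (base_level, shift_group_is_hyper flag handled by caller).

    Top-anchored for small effects (hyper side at 0.85), bottom-anchored for
    large ones (hypo side low, enhancer/cliff-like), so neither group's
    latent level sits near 0.5.
    """
    if delta < 0.28:
        base = 0.85
        return base, -delta          # shift applied to the hypo group
    base = hypo_level if hypo_level is not None else 0.30
    return base, +delta              # shift applied to the hyper group


def build_reference(config: Optional[SimConfig] = None, seed: int = 0) -> SyntheticReference:
    """Deterministically lay out the synthetic genome and its planted truth."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = _rng(seed, "reference")
    g1, g2 = cfg.group_names

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    # --- allocate loci -----------------------------------------------------
    n_loci_per_chrom = cfg.n_genes // cfg.n_chroms
    remainder = cfg.n_genes - n_loci_per_chrom * cfg.n_chroms
    loci = []  # (chrom, center)
    for ci, c in enumerate(chroms):
        n_here = n_loci_per_chrom + (1 if ci < remainder else 0)
        if n_here == 0:
            continue
        step = cfg.chrom_length / (n_here + 1)
        for i in range(n_here):
            center = (i + 1) * step + rng.uniform(-4000, 4000)
            loci.append((c, int(center)))

    n_loci = len(loci)
    roles = []
    n_dedm_cliff = min(cfg.n_cliffs, cfg.n_dedm) - cfg.n_dmv_cliffs
    n_dedm_plain = cfg.n_dedm - cfg.n_cliffs
    roles += ["dmv_cliff"] * cfg.n_dmv_cliffs
    roles += ["dmv"] * max(0, cfg.n_dmv - cfg.n_dmv_cliffs)
    roles += ["dedm_cliff"] * max(0, n_dedm_cliff)
    roles += ["dedm"] * max(0, n_dedm_plain)
    roles += ["prom_dmr"] * cfg.n_promoter_dmr_only
    if len(roles) > n_loci:
        raise ConfigurationError("too few gene loci for the requested planted features")
    roles += ["null"] * (n_loci - len(roles))
    roles = list(rng.permutation(roles))

    truth = SyntheticTruth()
    genes: list[GeneModel] = []
    zones: dict[str, list[_Zone]] = {c: [] for c in chroms}
    islands: dict[str, list] = {c: [] for c in chroms}
    shores: dict[str, list] = {c: [] for c in chroms}
    patch_records = []  # deferred DMR truth: dicts with genomic interval + meta
    dmr_counter = [0]

    def new_dmr_id() -> str:
        dmr_counter[0] += 1
        return f"pdmr_{dmr_counter[0]:04d}"

    # fine-stratum assignment queues
    prom_only_bins = np.repeat(np.arange(4), int(np.ceil(cfg.n_promoter_dmr_only / 4)))[
        :cfg.n_promoter_dmr_only]
    prom_only_bins = list(rng.permutation(prom_only_bins))
    inter_bins = np.repeat(np.arange(4), int(np.ceil(cfg.n_intergenic_dmr / 4)))[
        :cfg.n_intergenic_dmr]
    inter_bins = list(rng.permutation(inter_bins))

    # exactly balanced hyper-group assignment per planted class, so the
    # two tails of the group-difference statistic carry equal signal mass
    def _dir_queue(n: int) -> list[int]:
        q = np.resize([0, 1], n)
        return list(rng.permutation(q))

    dir_queues = {
        "dmv_cliff": _dir_queue(cfg.n_dmv_cliffs),
        "dedm_cliff": _dir_queue(max(0, cfg.n_cliffs - cfg.n_dmv_cliffs)),
        "promoter": _dir_queue(cfg.n_dedm - cfg.n_cliffs + cfg.n_promoter_dmr_only),
        "intergenic": _dir_queue(cfg.n_intergenic_dmr),
    }

    def add_locus(chrom: str, center: int, role: str, gene_id: str) -> None:
        lvl_isl, lvl_sea = cfg.island_level, cfg.open_sea_level
        sw = cfg.shore_width
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.uniform(3000, 15000))
        tss = center
        if strand == "+":
            gstart, gend = tss, min(tss + span, cfg.chrom_length - 1)
        else:
            gstart, gend = max(0, tss - span), tss + 1
        biotype = "protein_coding"
        if role == "null" and rng.random() < cfg.lncrna_fraction:
            biotype = "lncRNA"
        genes.append(GeneModel(gene_id, chrom, gstart, gend, strand, biotype))

        if role in ("dmv", "dmv_cliff"):
            z0, z1 = center - 4500, center + 4500
            islands[chrom].append((center - 500, center + 500))
            if role == "dmv":
                zones[chrom].append(_Zone(z0, z1, (15, 35), cfg.conc_island,
                                          "flat", {"level": 0.03}))
            else:
                # a small methylated-in-one-group strip inside the valley
                ps, pe = center + 1200, center + 2600
                hyper = dir_queues["dmv_cliff"].pop()  # index of the raised group
                zones[chrom].append(_Zone(z0, ps, (15, 35), cfg.conc_island,
                                          "flat", {"level": 0.03}))
                zones[chrom].append(_Zone(pe, z1, (15, 35), cfg.conc_island,
                                          "flat", {"level": 0.03}))
                zones[chrom].append(_Zone(ps, pe, (22, 34), cfg.conc_patch, "patch",
                                          {"base_level": 0.2, "shift_group": hyper,
                                           "shift_value": 0.5}))
                patch_records.append(dict(dmr_id=new_dmr_id(), chrom=chrom, start=ps,
                                          end=pe, hyper_group=hyper, delta=0.5,
                                          kind="cliff", gene_id=gene_id))
                truth.planted_cliffs.append(PlantedCliff(
                    chrom, z0, z1, gene_id,
                    raised_group=cfg.group_names[hyper],
                    low_group=cfg.group_names[1 - hyper],
                    raised_start=ps, raised_end=pe))
            return

        half = int(rng.uniform(*cfg.island_half_len))
        i0, i1 = center - half, center + half
        islands[chrom].append((i0, i1))
        zones[chrom].append(_Zone(i0, i1, cfg.island_spacing, cfg.conc_island,
                                  "flat", {"level": lvl_isl}))

        if role == "dedm_cliff":
            # unmethylated island on a low "plain"; one shore raised in one group
            raised_right = rng.random() < 0.5
            hyper = dir_queues["dedm_cliff"].pop()
            for side, (s0, s1) in (("L", (i0 - 2 * sw, i0)), ("R", (i1, i1 + 2 * sw))):
                raised = (side == "R") == raised_right
                if raised:  # widen the raised flank so its core carries the stat
                    s0, s1 = (i1, i1 + 1600) if side == "R" else (i0 - 1600, i0)
                if raised:
                    zones[chrom].append(_Zone(s0, s1, (22, 34), cfg.conc_patch,
                                              "patch", {"base_level": 0.2,
                                                        "shift_group": hyper,
                                                        "shift_value": 0.5}))
                    patch_records.append(dict(dmr_id=new_dmr_id(), chrom=chrom,
                                              start=s0, end=s1, hyper_group=hyper,
                                              delta=0.5, kind="cliff",
                                              gene_id=gene_id))
                    truth.planted_cliffs.append(PlantedCliff(
                        chrom, i0 - sw, i1 + sw, gene_id,
                        raised_group=cfg.group_names[hyper],
                        low_group=cfg.group_names[1 - hyper],
                        raised_start=s0, raised_end=s1))
                else:
                    zones[chrom].append(_Zone(s0, s1, cfg.shore_spacing, cfg.conc_patch,
                                              "flat", {"level": 0.2}))
                shores[chrom].append((s0, s1))
            return

        # standard logistic shores; one side may carry a promoter DMR patch
        patch_side = None
        if role in ("dedm", "prom_dmr"):
            patch_side = "R" if rng.random() < 0.5 else "L"
        for side, (s0, s1) in (("L", (i0 - sw, i0)), ("R", (i1, i1 + sw))):
            if side == patch_side:
                # steep 250 bp ramp, then the planted promoter patch
                plen = int(rng.uniform(1200, 1700))
                if role == "dedm":
                    # ~60% cliff-like: a differential core rising from a
                    # methylation plain that stays low in both cell types
                    cliff_like = rng.random() < 0.6
                    if cliff_like:
                        delta = float(rng.uniform(0.42, 0.50))
                        hypo_lvl = 0.18
                    else:
                        delta = float(rng.uniform(0.33, 0.50))
                        hypo_lvl = 0.30
                else:
                    cliff_like = False
                    delta = _sample_delta(rng, prom_only_bins.pop())
                    hypo_lvl = None
                plain = 300 if cliff_like else 0
                if side == "R":
                    r0, r1 = i1, i1 + 250
                    p0 = r1 + plain
                    p1 = p0 + plen
                    plains = [(r1, p0), (p1, p1 + plain)]
                else:
                    r0, r1 = i0 - 250, i0
                    p1 = r0 - plain
                    p0 = p1 - plen
                    plains = [(p1, r0), (p0 - plain, p0)]
                zones[chrom].append(_Zone(r0, r1, cfg.shore_spacing, cfg.conc_island,
                                          "ramp", {"inner": lvl_isl, "outer": lvl_sea,
                                                   "mid": 125, "scale": 40,
                                                   "direction": "out" if side == "R" else "in"}))
                if cliff_like:
                    for q0, q1 in plains:
                        zones[chrom].append(_Zone(q0, q1, cfg.dmr_spacing,
                                                  cfg.conc_patch, "flat",
                                                  {"level": hypo_lvl}))
                shores[chrom].append((min(r0, p0 - plain), max(r1, p1 + plain)))
                base, shift_val = _dmr_levels(rng, delta, hypo_lvl)
                hyper = dir_queues["promoter"].pop()
                grp = hyper if shift_val > 0 else 1 - hyper
                zones[chrom].append(_Zone(p0, p1, cfg.dmr_spacing, cfg.conc_patch,
                                          "patch", {"base_level": base,
                                                    "shift_group": grp,
                                                    "shift_value": shift_val}))
                patch_records.append(dict(dmr_id=new_dmr_id(), chrom=chrom, start=p0,
                                          end=p1, hyper_group=hyper, delta=delta,
                                          kind="promoter", gene_id=gene_id,
                                          dedm=(role == "dedm")))
            else:
                zones[chrom].append(_Zone(s0, s1, cfg.shore_spacing, cfg.conc_island,
                                          "ramp", {"inner": lvl_isl, "outer": lvl_sea,
                                                   "mid": sw / 2, "scale": sw / 7.5,
                                                   "direction": "out" if side == "R" else "in"}))
                shores[chrom].append((s0, s1))

    for (chrom, center), role, gid in zip(
            loci, roles, (f"gene_{i + 1:04d}" for i in range(n_loci))):
        add_locus(chrom, center, role, gid)

    # --- intergenic slots --------------------------------------------------
    slots = []
    by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, center in loci:
        by_chrom[chrom].append(center)
    for chrom in chroms:
        centers = sorted(by_chrom[chrom]) + [cfg.chrom_length]
        for i, c in enumerate(centers[:-1]):
            nxt = centers[i + 1]
            for off in (8000, 14000, 20000, 26000):
                pos = c + off + int(rng.uniform(0, 1500))
                if pos + 4200 < nxt - 6000 and pos + 2500 < cfg.chrom_length:
                    slots.append((chrom, pos))
    slots = [slots[i] for i in rng.permutation(len(slots))]
    need = cfg.n_intergenic_dmr + cfg.n_shared_lmr + 2 * cfg.n_dlmr_per_group
    if len(slots) < need:
        raise ConfigurationError("genome too small for the requested planted features")

    def take_slot():
        return slots.pop()

    for _ in range(cfg.n_intergenic_dmr):
        chrom, pos = take_slot()
        length = int(rng.uniform(1800, 2600))
        delta = _sample_delta(rng, inter_bins.pop())
        base, shift_val = _dmr_levels(rng, delta)
        hyper = dir_queues["intergenic"].pop()
        grp = hyper if shift_val > 0 else 1 - hyper
        zones[chrom].append(_Zone(pos, pos + length, cfg.dmr_spacing, cfg.conc_patch,
                                  "patch", {"base_level": base, "shift_group": grp,
                                            "shift_value": shift_val}))
        patch_records.append(dict(dmr_id=new_dmr_id(), chrom=chrom, start=pos,
                                  end=pos + length, hyper_group=hyper, delta=delta,
                                  kind="intergenic", gene_id=None))

    for _ in range(cfg.n_shared_lmr):
        chrom, pos = take_slot()
        length = int(rng.uniform(500, 900))
        level = float(rng.uniform(0.20, 0.35))
        zones[chrom].append(_Zone(pos, pos + length, cfg.patch_spacing, cfg.conc_patch,
                                  "flat", {"level": level}))

    for own in (0, 1):
        for _ in range(cfg.n_dlmr_per_group):
            chrom, pos = take_slot()
            # LMR core (below the 30-CpG UMR boundary) flanked by dense
            # differential regions: the supporting DMR spans core + flanks
            sp = rng.uniform(62, 78)
            n_core = rng.integers(24, 29)
            core_len = int(sp * n_core)
            ext = 600
            other = 1 - own
            zones[chrom].append(_Zone(pos, pos + ext, cfg.dmr_spacing,
                                      cfg.conc_patch, "patch",
                                      {"base_level": 0.60, "shift_group": other,
                                       "shift_value": 0.40}))
            zones[chrom].append(_Zone(pos + ext, pos + ext + core_len,
                                      (int(sp) - 6, int(sp) + 6),
                                      cfg.conc_patch, "patch",
                                      {"base_level": 0.12, "shift_group": other,
                                       "shift_value": 0.5}))
            zones[chrom].append(_Zone(pos + ext + core_len, pos + 2 * ext + core_len,
                                      cfg.dmr_spacing, cfg.conc_patch, "patch",
                                      {"base_level": 0.60, "shift_group": other,
                                       "shift_value": 0.40}))
            patch_records.append(dict(dmr_id=new_dmr_id(), chrom=chrom, start=pos,
                                      end=pos + 2 * ext + core_len, hyper_group=other,
                                      delta=None, kind="dlmr_support", gene_id=None))

    # --- generate CpG positions and latent means ---------------------------
    cpg_positions: dict[str, np.ndarray] = {}
    mean_base: dict[str, np.ndarray] = {}
    shift: dict[str, np.ndarray] = {}
    conc: dict[str, np.ndarray] = {}
    for chrom in chroms:
        zs = sorted(zones[chrom], key=lambda z: z.start)
        for a, b in zip(zs, zs[1:]):
            if a.end > b.start:
                raise ConfigurationError("overlapping landscape zones")
        # fill gaps with open sea
        full: list[_Zone] = []
        cursor = 0
        for z in zs:
            if z.start > cursor:
                full.append(_Zone(cursor, z.start, cfg.open_sea_spacing,
                                  cfg.conc_open_sea, "flat",
                                  {"level": cfg.open_sea_level}))
            full.append(z)
            cursor = z.end
        if cursor < cfg.chrom_length:
            full.append(_Zone(cursor, cfg.chrom_length, cfg.open_sea_spacing,
                              cfg.conc_open_sea, "flat", {"level": cfg.open_sea_level}))
        pos_parts, base_parts, shift_parts, conc_parts = [], [], [], []
        prev = -1
        for z in full:
            width = z.end - z.start
            mean_sp = (z.spacing[0] + z.spacing[1]) / 2
            n_max = int(width / z.spacing[0]) + 2
            steps = rng.uniform(z.spacing[0], z.spacing[1], size=n_max)
            p = z.start + np.cumsum(steps) - steps[0] * rng.uniform(0, 1)
            p = p[p < z.end].astype(np.int64)
            p = p[p > prev]
            p = np.unique(p)
            if len(p) == 0:
                continue
            prev = int(p[-1])
            b, s = z.means(p)
            pos_parts.append(p)
            base_parts.append(b)
            shift_parts.append(s)
            conc_parts.append(np.full(len(p), z.conc))
        cpg_positions[chrom] = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        mean_base[chrom] = np.concatenate(base_parts) if base_parts else np.empty(0)
        shift[chrom] = np.vstack(shift_parts) if shift_parts else np.empty((0, 2))
        conc[chrom] = np.concatenate(conc_parts) if conc_parts else np.empty(0)
        if len(cpg_positions[chrom]) and not np.all(np.diff(cpg_positions[chrom]) > 0):
            raise ConfigurationError("CpG positions not strictly increasing")

    ref = SyntheticReference(chrom_sizes, cpg_positions, islands, shores, genes,
                             truth, cfg, mean_base, shift, conc)

    # --- snap planted DMRs to CpG spans and finalise truth -----------------
    for rec in patch_records:
        chrom = rec["chrom"]
        pos = cpg_positions[chrom]
        lo = np.searchsorted(pos, rec["start"], "left")
        hi = np.searchsorted(pos, rec["end"], "left")
        if hi - lo < 3:
            continue  # degenerate patch (should not happen at default sizes)
        m1 = ref.group_mean(chrom, 0)[lo:hi]
        m2 = ref.group_mean(chrom, 1)[lo:hi]
        delta_true = float(np.mean(m1 - m2))
        pd = PlantedDMR(rec["dmr_id"], chrom, int(pos[lo]), int(pos[hi - 1]) + 1,
                        delta_true,
                        "g1_hyper" if delta_true > 0 else "g2_hyper",
                        fine_bin(abs(delta_true)), hi - lo, rec["kind"])
        truth.planted_dmrs.append(pd)
        rec["planted"] = pd

    # --- truth segmentation from the latent design -------------------------
    for gi, gname in enumerate(cfg.group_names):
        umrs, lmrs = [], []
        for chrom in chroms:
            pos = cpg_positions[chrom]
            if len(pos) == 0:
                continue
            m = ref.group_mean(chrom, gi)
            low = m < 0.5
            # maximal runs of low sites
            edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
            for s_idx, e_idx in zip(edges[::2], edges[1::2]):
                n = e_idx - s_idx
                if n < 4:
                    continue
                seg = PlantedSegment(chrom, int(pos[s_idx]), int(pos[e_idx - 1]) + 1,
                                     int(n), float(np.mean(m[s_idx:e_idx])))
                (umrs if n >= 30 else lmrs).append(seg)
        truth.planted_umrs[gname] = umrs
        truth.planted_lmrs[gname] = lmrs
        # DMVs: merge UMRs over gaps <= 1 kb, keep spans >= 5 kb with low mean
        dmvs = []
        for chrom in chroms:
            cu = sorted([u for u in umrs if u.chrom == chrom], key=lambda u: u.start)
            if not cu:
                continue
            pos = cpg_positions[chrom]
            m = ref.group_mean(chrom, gi)
            merged = [[cu[0].start, cu[0].end]]
            for u in cu[1:]:
                if u.start - merged[-1][1] <= 1000:
                    merged[-1][1] = u.end
                else:
                    merged.append([u.start, u.end])
            for s, e in merged:
                if e - s < 5000:
                    continue
                lo = np.searchsorted(pos, s, "left")
                hi = np.searchsorted(pos, e, "left")
                mm = float(np.mean(m[lo:hi]))
                if mm <= 0.15:
                    dmvs.append(PlantedSegment(chrom, s, e, hi - lo, mm))
        truth.planted_dmvs[gname] = dmvs

    # --- DE genes, dedm links, TF flags ------------------------------------
    dedm_recs = [r for r in patch_records
                 if r.get("gene_id") and "planted" in r
                 and (r.get("dedm") or r["kind"] == "cliff")]
    dedm_recs.sort(key=lambda r: r["gene_id"])
    n_links = len(dedm_recs)
    n_inverse = int(round(cfg.inverse_fraction * n_links))
    order = rng.permutation(n_links)
    concord = np.empty(n_links, dtype=object)
    concord[order[:n_inverse]] = "inverse"
    concord[order[n_inverse:]] = "concordant"
    for rec, conc_label in zip(dedm_recs, concord):
        pd: PlantedDMR = rec["planted"]
        sign = 1.0 if pd.delta_me > 0 else -1.0
        lfc_sign = sign if conc_label == "concordant" else -sign
        lfc = lfc_sign * float(rng.uniform(*cfg.lfc_range))
        truth.de_genes[rec["gene_id"]] = lfc
        truth.dedm_links[rec["gene_id"]] = (pd.dmr_id, str(conc_label))

    null_pc = [g for g in genes
               if g.gene_id not in truth.de_genes and g.biotype == "protein_coding"]
    extra = [null_pc[i] for i in rng.permutation(len(null_pc))[:cfg.n_extra_de]]
    for g in extra:
        truth.de_genes[g.gene_id] = float(rng.choice([-1, 1]) * rng.uniform(1.0, 3.0))

    # TF flag: genes near high-|ΔMe| planted DMRs are preferentially TFs
    bin_index = {b: i for i, b in enumerate(FINE_BINS)}
    best_stratum: dict[str, int] = {}
    pc_genes = [g for g in genes if g.biotype == "protein_coding"]
    for pd in truth.planted_dmrs:
        cand = [g for g in pc_genes if g.chrom == pd.chrom]
        if not cand:
            continue
        mid = (pd.start + pd.end) / 2
        nearest = min(cand, key=lambda g: (abs(mid - g.tss), g.gene_id))
        s = bin_index[pd.fine_stratum]
        best_stratum[nearest.gene_id] = max(best_stratum.get(nearest.gene_id, -1), s)
    dmv_gene_ids = {c.gene_id for c in truth.planted_cliffs} | set()
    dmv_roles = {gid for (gid, r) in zip((g.gene_id for g in genes), roles)
                 if r in ("dmv", "dmv_cliff")}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if g.gene_id in dmv_roles:
            p = 0.9
        elif g.gene_id in best_stratum:
            p = cfg.tf_rate_by_stratum[best_stratum[g.gene_id]]
        else:
            p = cfg.tf_base_rate
        g.is_tf = bool(rng.random() < p)

    _check_truth(ref)
    return ref


def _check_truth(ref: SyntheticReference) -> None:
    for pd in ref.truth.planted_dmrs:
        if not (0.1 <= abs(pd.delta_me) <= 0.5 + 1e-9):
            raise ConfigurationError(
                f"planted DMR {pd.dmr_id} delta {pd.delta_me:.3f} outside [0.1, 0.5]")
    for segs in ref.truth.planted_dmvs.values():
        for s in segs:
            if s.end - s.start < 5000:
                raise ConfigurationError("planted DMV shorter than 5 kb")
    genes = {g.gene_id: g for g in ref.genes}
    for gid, (dmr_id, _) in ref.truth.dedm_links.items():
        pd = ref.truth.dmr_by_id(dmr_id)
        tss = genes[gid].tss
        if pd.end <= tss - 2000 or pd.start >= tss + 2000:
            raise ConfigurationError(f"dedm link {gid}->{dmr_id} outside ±2 kb of TSS")


# ---------------------------------------------------------------------------
# methylome / expression / peak simulation


def simulate_methylomes(ref: SyntheticReference, n_per_group: int = 3,
                        mean_coverage: float = 25.0, seed: int = 0) -> CpGMethylomeMatrix:
    """Draw per-CpG read counts: total ~ Poisson(coverage), methylated ~
    Binomial(total, p) with p a per-site Beta draw around the latent design,
    shifted (and clipped) in the designated group inside planted regions."""
    if ref.n_cpgs() == 0:
        raise ConfigurationError("empty reference")
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    if mean_coverage <= 0:
        raise ConfigurationError("non-positive coverage")
    rng = _rng(seed, "methylomes")
    g1, g2 = ref.config.group_names
    samples = [f"{g}_{i + 1}" for g in (g1, g2) for i in range(n_per_group)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    chrom_arrs, pos_arrs, meth_arrs, tot_arrs = [], [], [], []
    for chrom in ref.chroms:
        pos = ref.cpg_positions[chrom]
        S = len(pos)
        if S == 0:
            continue
        base = ref.mean_base[chrom]
        cc = ref.conc[chrom]
        a = np.clip(base * cc, 1e-3, None)
        b = np.clip((1 - base) * cc, 1e-3, None)
        p0 = rng.beta(a, b)                       # shared site-level draw
        p_group = np.empty((S, 2))
        for gi in range(2):
            p_group[:, gi] = np.clip(p0 + ref.shift[chrom][:, gi], 0.0, 1.0)
        total = rng.poisson(mean_coverage, size=(S, 2 * n_per_group))
        meth = np.empty_like(total)
        for si, s in enumerate(samples):
            gi = 0 if groups[s] == g1 else 1
            meth[:, si] = rng.binomial(total[:, si], p_group[:, gi])
        chrom_arrs.append(np.full(S, chrom, dtype=object))
        pos_arrs.append(pos)
        meth_arrs.append(meth)
        tot_arrs.append(total)
    return CpGMethylomeMatrix(np.concatenate(chrom_arrs), np.concatenate(pos_arrs),
                              samples, groups,
                              np.vstack(meth_arrs), np.vstack(tot_arrs))


def simulate_expression(ref: SyntheticReference, n_per_group: int = 3,
                        seed: int = 0) -> ExpressionCounts:
    """Negative-binomial expression counts; genes in the truth's DE set
    receive their planted log2 fold change (group 1 vs group 2)."""
    if n_per_group < 2:
        raise ConfigurationError("DE calling needs >= 2 replicates per group")
    cfg = ref.config
    rng = _rng(seed, "expression")
    g1, g2 = cfg.group_names
    samples = [f"{g}_{i + 1}" for g in (g1, g2) for i in range(n_per_group)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    gene_ids = [g.gene_id for g in ref.genes]
    if not gene_ids:
        return ExpressionCounts([], samples, np.zeros((0, len(samples)), int), groups)
    mu = np.exp(rng.normal(cfg.expr_mean_log, cfg.expr_mean_sd, size=len(gene_ids)))
    mu = np.clip(mu, 20.0, 5000.0)
    lfc = np.array([ref.truth.de_genes.get(g, 0.0) for g in gene_ids])
    mu1 = mu * 2.0 ** (lfc / 2)
    mu2 = mu * 2.0 ** (-lfc / 2)
    r = 1.0 / cfg.dispersion
    counts = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for si, s in enumerate(samples):
        m = mu1 if groups[s] == g1 else mu2
        counts[:, si] = rng.negative_binomial(r, r / (r + m))
    return ExpressionCounts(gene_ids, samples, counts, groups)


VALID_BIASES = ("uniform", "lmr_biased", "high_dmr_promoter_biased")


def simulate_peaks(ref: SyntheticReference, tf_specs: Sequence[tuple],
                   seed: int = 0, peak_width: int = PEAK_WIDTH_DEFAULT,
                   lmr_fraction: float = 0.7) -> dict[str, list[GenomicFeature]]:
    """Fixed-width TF peaks with configurable placement bias.

    tf_specs: iterable of (name, count, bias) with bias in
    {"uniform", "lmr_biased", "high_dmr_promoter_biased"}.
    """
    rng = _rng(seed, "peaks")
    cfg = ref.config
    chroms = ref.chroms
    sizes = np.array([ref.chrom_sizes[c] for c in chroms], dtype=float)
    all_lmrs = [s for grp in ref.truth.planted_lmrs.values() for s in grp]
    genes = {g.gene_id: g for g in ref.genes}
    bin_index = {b: i for i, b in enumerate(FINE_BINS)}
    promoter_dmrs = []
    for pd in ref.truth.planted_dmrs:
        for g in ref.genes:
            if g.chrom == pd.chrom and pd.start < g.tss + 2000 and pd.end > g.tss - 2000:
                promoter_dmrs.append(pd)
                break

    out: dict[str, list[GenomicFeature]] = {}
    for name, count, bias in tf_specs:
        if bias not in VALID_BIASES:
            raise ConfigurationError(f"unknown placement bias {bias!r}")
        peaks: list[GenomicFeature] = []

        def uniform_peak():
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            start = int(rng.uniform(0, sizes[ci] - peak_width))
            return GenomicFeature(chroms[ci], start, start + peak_width,
                                  "PEAK", {"tf_name": name})

        if bias == "uniform":
            peaks = [uniform_peak() for _ in range(count)]
        elif bias == "lmr_biased":
            if not all_lmrs:
                raise ConfigurationError("no planted LMRs to bias toward")
            n_in = int(round(lmr_fraction * count))
            for _ in range(n_in):
                seg = all_lmrs[rng.integers(len(all_lmrs))]
                if seg.end - seg.start <= peak_width:
                    s, e = seg.start, seg.end
                else:
                    s = int(rng.uniform(seg.start, seg.end - peak_width))
                    e = s + peak_width
                peaks.append(GenomicFeature(seg.chrom, s, e, "PEAK", {"tf_name": name}))
            peaks += [uniform_peak() for _ in range(count - n_in)]
        else:  # high_dmr_promoter_biased
            if not promoter_dmrs:
                raise ConfigurationError("no promoter DMRs to bias toward")
            w = np.array([6.0 ** bin_index[pd.fine_stratum] for pd in promoter_dmrs])
            probs = np.clip(count * w / w.sum(), 0.0, 0.95)
            # quota placement per stratum: the expected per-stratum fraction
            # is hit exactly, which keeps the planted monotone gradient stable
            for b in FINE_BINS:
                members = [i for i, pd in enumerate(promoter_dmrs)
                           if pd.fine_stratum == b]
                if not members:
                    continue
                quota = int(round(probs[members[0]] * len(members)))
                chosen = rng.choice(members, size=min(quota, len(members)),
                                    replace=False)
                for i in chosen:
                    pd = promoter_dmrs[i]
                    mid = (pd.start + pd.end) // 2
                    s = max(0, mid - peak_width // 2)
                    peaks.append(GenomicFeature(pd.chrom, s, s + peak_width,
                                                "PEAK", {"tf_name": name}))
        peaks.sort(key=lambda f: (f.chrom, f.start))
        out[name] = peaks
        ref.truth.peak_truth[name] = [(f.chrom, f.start, f.end) for f in peaks]
    return out
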