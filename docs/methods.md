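# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

All coordinates are 0-based half-open (BED-native); one convention
everywhere removes a whole class of off-by-one errors. CpG counts are
assumed pre-merged onto the + strand C of each CpG; the generator emits
merged counts. The central container is a site × sample matrix of
(methylated, total) read counts with a sample → group map.

ΔMe has a single definition used by every stage: the signed difference of
coverage-pooled methylation fractions (Σ meth / Σ total per group),
averaged over a region's CpGs, group 1 minus group 2. Pooling counts
before dividing is robust at low per-sample coverage; smoothed values are
never used for ΔMe.

## DMR calling

Per-sample methylation fractions are smoothed by a coverage-weighted
tricube local-linear fit. The window around each CpG spans at least
±1,000 bp and at least 70 CpGs, whichever is larger (defaults exposed).
Local-linear fitting reproduces constant and linear signal exactly and
tracks steps with less smearing than a kernel average.

The per-CpG statistic is (mean smoothed group 1 − mean smoothed group 2) /
sqrt(pooled within-group variance + 10⁻⁴). The variance floor matters: with
three samples per group the raw variance estimate is degenerate and would
otherwise blow up the statistic at quiet sites. Candidate regions are
maximal runs of CpGs beyond the empirical 2.5%/97.5% quantiles of the
statistic, merged across gaps ≤ 300 bp (typical shore spacing); a run is
kept if it has ≥ 3 CpGs above the cutoff and the pooled-count |ΔMe| over
the emitted interval is ≥ 0.1. Empirical-quantile cutoffs make the caller
adaptive: when a meaningful fraction of sites carries signal, the cutoff
rises into the signal halo and the calls hug the differential cores.

Strata are closed-left: Low = [0.1, 0.3), High = [0.3, ∞), fine bins
[0.1,0.2), [0.2,0.3), [0.3,0.4), ≥ 0.4. ΔMe and the CpG count of an
emitted DMR cover every CpG inside its interval, including CpGs bridged by
the gap merge, so the stored ΔMe always equals a pooled-count
recomputation over the interval.

## Segmentation

Each group's pooled track is segmented into hypomethylated runs
(consecutive CpGs < 0.5). The minimum run length starts at 4 CpGs and is
raised until within-chromosome site permutations of the track (100 draws,
seeded) would reproduce at most 5% as many runs — a transparent,
testable stand-in for a model-based FDR. Runs with ≥ 30 CpGs are UMRs
(promoter-like), shorter runs LMRs (enhancer-like). DMVs are merged UMRs
(gaps ≤ 1 kb) spanning ≥ 5 kb with pooled methylation ≤ 0.15 across the
whole span. Partially methylated domains are not modelled; the synthetic
methylomes are PMD-free by construction.

## Differential expression

Counts are normalised by median-of-ratios size factors. The log2 fold
change uses a 0.5 pseudocount on group means. The Wald standard error uses
a method-of-moments NB dispersion **pooled across genes** (the mean of the
per-gene moment estimates, floored at 0.01): per-gene moment estimates
with 2 × 3 replicates are right-skewed, and taking their median (or using
them per gene) underestimates dispersion and inflates the type-I error
well beyond nominal, while the cross-gene mean keeps the label-permuted
null close to its nominal level. p-values are two-sided normal, FDR is
Benjamini–Hochberg, and the DE threshold defaults to FDR < 0.001.

## Integration rules

Promoters are strand-independent TSS ± 2 kb windows clipped to the
chromosome. A DE-DM record is any (DE gene, DMR) pair where the DMR has
|ΔMe| ≥ 0.2 and shares ≥ 1 bp with the gene's promoter window ("any
overlap" rather than containment — the simplest defensible reading of
"within 2 kb of the TSS"). Quadrants are taken w.r.t. group 1; a gene with
DMRs in both directions contributes records in two quadrants, so the
record table and the unique-gene table are reported separately. A record
is a cliff when the less-methylated group's pooled mean over the DMR is
≤ 0.25 (boundary inclusive). D-LMRs take, per cell type, the LMRs in the
lowest quartile of that type's own LMR methylation distribution
(per-type, not pooled — the two types are selected separately) and keep
those overlapping (≥ 1 bp) a DMR hypermethylated in the other type.

## Enrichment and profiles

Peak enrichment is an exact upper-tail hypergeometric test
(P(X ≥ k); "contains a peak" = shares ≥ 1 bp with ≥ 1 peak). The universe
defaults to the full called feature set of the relevant class and is a
caller-supplied argument. The trend test is Cochran–Armitage with equally
spaced integer scores (the captions this emulates do not state scores) and
a 1-df χ² reference; a pooled success fraction of 0 or 1 returns χ² = 0,
p = 1. Loess (metaplots) is tricube local-linear regression with a
nearest-neighbour span of 0.2 and no robustness iterations. MDS is
classical (Torgerson double-centering) on the mean absolute per-site
methylation difference over sites with ≥ 5x coverage in every sample;
classical MDS reproduces any Euclidean rank-2 configuration exactly, which
is the correctness check used in the tests. Binary co-occurrence
clustering is complete linkage on Jaccard distance with scipy's
deterministic tie-breaking.

## Synthetic study design

The generator emulates a two-depot adipocyte comparison in miniature:
two 5 Mb chromosomes, 300 gene loci, three samples per group, read depth
Poisson(25) per CpG and sample. Island spacing is 10–20 bp, shores 25–45 bp,
open sea 80–120 bp; with those densities the default genome carries
~130,000 CpGs. Site-level methylation is a Beta draw around the designed
mean (concentration 50 in islands, 20 in open sea, 150 in planted
patches), shared across samples and groups, with the planted group shift
added and clipped to [0, 1] — so within-group variation is read noise
while between-group differences are the planted effects.

Planted features (default counts): 40 DE genes with promoter DMRs
(|ΔMe| in 0.33–0.5; 10 of them cliffs), 24 promoter-only DMRs and 40
intergenic DMRs spread evenly over the four fine ΔMe bins, 6 DMVs
(~9 kb valleys, 4 carrying a cliff), 60 shared LMR patches and 10
group-specific D-LMR composites per group. Hyper-direction is assigned
exactly half-half within each class so the two tails of the statistic
carry equal signal mass; an imbalanced mix makes the two empirical
quantile cutoffs asymmetric and destabilises boundary precision.

Level scheme: planted DMR levels avoid the neighbourhood of the 0.5
segmentation cutoff. Small effects (|ΔMe| < 0.28) are "top-anchored"
(hyper side at 0.85); large effects are "bottom-anchored" (hypo side at
0.18–0.37, enhancer/cliff-like, consistent with high-ΔMe regions sitting
where one cell type is lowly methylated). The fine bin [0.2, 0.3) is
sampled from [0.20, 0.27] to respect this scheme. Planted DMR patches are
CpG-dense (24–40 bp spacing, 1.2–2.6 kb) so that the 70-CpG smoothing
window resolves their interiors; the planting mass is sized so the
adaptive quantile cutoffs land just below the weakest High cores —
low-stratum DMRs are then partially missed (by design the sensitivity
gradient across ΔMe strata is monotone), while High DMRs are recovered
with tight boundaries.

Cliffs follow the "cliff rising from a methylation plain" geometry: an
unmethylated island flanked by a low plain (0.18–0.2 in both groups) with
one flank raised to ~0.7 in exactly one group over ≥ 600 bp (ΔMe = 0.5,
which also keeps planted effects within the generator's declared
[0.1, 0.5] range). D-LMR composites are an LMR core (24–28 CpGs at 0.12
in the own group) flanked by dense differential regions, so the
supporting DMR is wider than the LMR it validates.

Truth intervals for UMRs/LMRs/DMVs are derived from the designed latent
means (runs below 0.5), not from any caller, so recovery comparisons are
caller-independent. Expression is negative-binomial (dispersion 0.05,
log-normal baseline means), with DE genes receiving their planted log2
fold change; among promoter-linked DE genes the inverse:concordant split
is assigned deterministically at 62:38. TF peak sets are 300-bp intervals
placed uniformly, biased into planted LMRs (70% by default), or biased
toward promoters with probability increasing in the planted ΔMe stratum;
the biased mode fills a per-stratum quota (round(pₛ·nₛ)) at randomly
chosen promoters so the planted monotone gradient is stable across seeds.

Randomness uses one stream per operation, derived from the master seed
plus an operation tag (CRC32), so adding an operation never perturbs the
outputs of existing ones.

## What the simulation does and does not show

The generator reproduces the statistical structure the pipeline assumes —
coverage noise, CpG-density contexts, graded region-level effects, linked
expression, biased peaks — but not read-level artefacts (bisulphite
conversion error, mapping bias, strand asymmetry), biological replicate
heterogeneity beyond read noise, PMDs, or realistic genome annotation
complexity (overlapping genes, alternative TSSs). Passing recovery tests
therefore demonstrates the correctness and calibration of the
implementation under its stated model, not performance on real WGBS data.
Problem sizes (2 × 5 Mb, ~130k CpGs, 300 genes, 2,000-gene DE null,
200-gene power set) were chosen as the smallest at which stratum-level
statistics are stable; the full pipeline runs in well under a minute.

## Known limitations

- Exactly two groups are supported by the DMR caller and integrator; the
  segment comparison handles k groups.
- The DMR caller's boundary halo dilutes called |ΔMe| by roughly 10–20%
  relative to the planted core effect, so planted ≥ 0.4 effects are often
  reported in the [0.3, 0.4) bin; stratum-level analyses on called DMRs
  inherit this.
- The permutation FDR for segmentation assumes exchangeable sites within a
  chromosome under the null, which ignores local coverage autocorrelation.
- The NB Wald test relies on a cross-gene pooled dispersion; with strongly
  gene-specific dispersions a shrinkage estimator would be preferable.
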