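# dmrkit

Comparative whole-genome bisulphite sequencing (WGBS) analysis between two
cell populations — e.g. subcutaneous (SA) versus visceral (VA) adipocytes —
at desk scale. The package implements the full chain from per-CpG
methylation counts to biological summaries:

- **DMR calling** — per-sample local-likelihood smoothing of methylation
  fractions (tricube-weighted, coverage-weighted local-linear fits), a
  t-like group-difference statistic with a variance floor, and region calls
  as runs of CpGs beyond empirical quantile cutoffs. Every region carries a
  signed effect size ΔMe = pooled-count methylation difference (group 1 −
  group 2) averaged over its CpGs, stratified Low (0.1 ≤ |ΔMe| < 0.3) /
  High (|ΔMe| ≥ 0.3) and into fine bins [0.1,0.2), [0.2,0.3), [0.3,0.4), ≥0.4.
- **Methylome segmentation** — unmethylated regions (UMRs, promoter-like,
  ≥ 30 CpGs), low-methylated regions (LMRs, enhancer-like) with a
  permutation-based FDR on run lengths, and DNA methylation valleys (DMVs,
  ≥ 5 kb merged low spans).
- **Expression integration** — negative-binomial Wald differential
  expression, promoter windows (TSS ± 2 kb), DE × DM quadrant records with
  inverse/concordant labels, methylation-"cliff" detection (one cell type
  ≤ 0.25 over the region), DMV association, and D-LMRs (lowest-quartile
  LMRs of one cell type overlapping DMRs hypermethylated in the other —
  candidate differential enhancers).
- **Enrichment statistics** — exact upper-tail hypergeometric peak
  enrichment, per-TF High/Low log2 overlap ratios, Cochran–Armitage χ²
  trend tests across ΔMe strata, TSS-anchored loess metaplots,
  feature-centred signal matrices, classical MDS of samples, and
  complete-linkage Jaccard clustering of binary peak-presence matrices.
- **Synthetic data** — a generator that lays out a CpG-island/shore/open-sea
  landscape with planted DMRs of graded ΔMe, cliffs, UMR/LMR/DMV segments,
  D-LMR patches, linked expression effects (62:38 inverse:concordant split
  among promoter-linked DE genes) and biased TF peak sets, together with a
  machine-readable truth record for recovery testing.

## Worked example

```python
from dmrkit.pipeline import run_pipeline, promoter_stratum_peak_trend

res = run_pipeline(seed=1)          # 2 × 5 Mb genome, 3 vs 3 samples, ~25x
print(len(res.dmrs), res.stratum_table["stratum"])
print(res.dedm_summary["records"])
tr = promoter_stratum_peak_trend(res, "EZH2")
print(round(tr.chi2, 2), tr.p)
```

prints

```
103 {'low': 18, 'high': 85}
{'meth-up/expr-up': 9, 'meth-up/expr-down': 9, 'meth-down/expr-up': 16, 'meth-down/expr-down': 7}
6.98 0.00825866807898246
```

103 DMRs are called on the default simulation, most of them High
(|ΔMe| ≥ 0.3) because weak planted effects fall below the adaptive stat
cutoffs. The 41 DE-DM records split into the four methylation × expression
quadrants; summing the off-diagonal (inverse) quadrants recovers the
planted 62:38 inverse:concordant relationship. The trend test shows that
Polycomb-style peaks concentrate at promoters with high ΔMe (χ² = 6.98 on
1 df, p < 0.01).

The same pipeline is scriptable from the shell:

```bash
dmrkit simulate --seed 1 --outdir sim/
dmrkit dmr      --cpg sim/cpg_report.tsv --groups sim/groups.tsv --out dmrs.bed
dmrkit segment  --cpg sim/cpg_report.tsv --groups sim/groups.tsv --group SA --out seg_SA.bed
dmrkit mds      --cpg sim/cpg_report.tsv --groups sim/groups.tsv --out mds.tsv
```

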