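# Methods

This document records the statistical model, the conventions every module
commits to, the default parameters and their rationale, and the deliberate
design decisions (including the known limits of the synthetic generator).

## 1. Association model

For each SNP–transcript pair the scan fits ordinary least squares

```
expression ~ intercept + beta * dosage + age + sex + center
```

where `dosage` counts copies of the minor allele (0–2, possibly fractional
for imputed genotypes), `sex` is a single indicator and `center` enters as
treatment-coded dummies. The reported statistic is the two-sided t-test on
`beta`, with residual degrees of freedom `n − (k + 1)` for `k` design
columns. `beta` is therefore the additive log2 expression change per
minor-allele copy.

The genome-wide scan residualizes expression and dosage on the covariate
design once (Frisch–Waugh–Lovell) and computes all pair statistics
vectorized; this is algebraically identical to the single-pair estimator
`fit_eqtl`, and the test suite enforces agreement to 1e-9 on sampled pairs
and 1e-10 against an independent normal-equations oracle. SNPs with missing
dosages fall back to the exact per-pair fit on complete cases.

### Multiple testing

- **cis** (SNP within 1 Mb of the transcript TSS, same chromosome,
  boundary inclusive): Storey q-values over all cis p-values, significant at
  q ≤ 0.05. π₀ is estimated by the cubic-polynomial fit to π₀(λ) on the grid
  λ = 0.05, 0.10, …, 0.95, evaluated at the largest λ and clamped to (0, 1].
  With fewer than 100 p-values the estimate is unstable, so the code warns
  and falls back to π₀ = 1, which makes the q-values exactly
  Benjamini–Hochberg.
- **trans** (everything else): a hard floor p < 5e-8 first, then BH at 0.05
  across the surviving pairs. The floor keeps the BH input set small without
  changing which genome-wide-credible signals can pass.

### Reporting conventions

Significant SNPs per transcript are grouped into LD clusters: single-linkage
connected components of the r² > 0.6 graph, built within chromosomes only.
The top SNP of a cluster is the one with the smallest p-value (ties broken
toward the smaller position). Distances are signed and strand-aware:

- SNP inside the gene body (boundaries inclusive) → 0, "inside";
- upstream of the TSS → negative distance measured from the TSS
  (`snp − tss` on "+" strands, `tss − snp` on "−" strands);
- downstream of the gene → positive distance measured from the far gene
  boundary (`snp − gene_end` on "+", `gene_start − snp` on "−").

Cross-chromosome pairs have no distance; the low-level function raises and
the scan annotates the pair as "other_chromosome".

## 2. Expression processing

1. **Detection threshold**: the median of Y-chromosome-probe values in
   female subjects. Females carry no Y chromosome, so those probes measure
   pure background; their median is a data-driven noise floor.
2. **Probe filtering**: a probe is excluded if it contains a common SNP, if
   its sequence maps ambiguously, or if its median expression is strictly
   below the detection threshold. The three rules are applied as a union, so
   a probe failing two rules is counted in both removal tallies but removed
   once.
3. **Quantile normalization** maps every sample to the common distribution
   of per-rank means, averaging over ties; ranks (and hence within-sample
   ordering) are preserved. Input that looks linear-scale (values far above
   the log2 range) is log2-transformed first, with a warning.
4. **Sample outliers**: robust z-scores of per-sample median correlation to
   the cohort flag gross expression outliers for inspection.

## 3. Genotype quality control

Filters run as a fixed cascade, each on the survivors of the previous step:

1. **Call rate** < 0.95 (strict) removes the sample.
2. **Relatedness**: identity-by-state `1 − mean(|d_i − d_j|)/2` over shared
   called hard genotypes; pairs with IBS > 0.95 lose the lower-call-rate
   member (ties: the later sample).
3. **Heterozygosity**: per-sample heterozygote fraction, robust z
   (median/MAD; MAD = 0 falls back to mean/SD with a warning), two-sided
   p-values, BH at FDR 0.01.
4. **Stratification**: average-linkage clustering of the sample–sample
   Manhattan distance matrix, cut at `cut_scale ×` the median pairwise
   distance; clusters smaller than `min_cluster_frac` of the cohort are
   flagged, and PCA coordinates are returned for inspection.
5. **SNP filters**: MAF ≥ 0.15 (inclusive), recomputed from the retained
   samples, and imputation rsq ≥ 0.30 where the annotation provides it
   (absent rsq passes).

The MAF ≥ 0.15 cutoff is motivated by a Hardy–Weinberg design argument: the
expected count of minor-allele homozygotes is `n·q²`, which at n = 129 and
q = 0.15 is 2.9 ≈ 3 — the minimum for the homozygote class to be populated
at all, below which the additive fit leans entirely on heterozygotes.
Uncertain imputed dosages are hard-called only inside ±0.2 of an integer;
values in the open bands between are treated as missing for IBS and
heterozygosity.

## 4. GWAS overlap and enrichment

GWAS loci are LD-pruned (r² > 0.6 single linkage) and each locus is
represented by its lead SNP. Candidate look-up uses a Bonferroni threshold
`alpha / (n_loci × n_transcripts)`. Enrichment compares the observed count
Q of nominally associated elements against `n_sets` random SNP sets matched
SNP-by-SNP (sampling without replacement) on MAF bins of width 0.05 and
distance-to-nearest-TSS bins with edges 0 / 10 kb / 100 kb / 1 Mb / ∞:

- fold = `mean(Q / max(Q_i, 0.5))` — the 0.5 floor keeps null sets with
  zero hits from producing infinite folds;
- empirical p = `(#{Q_i ≥ Q} + 1) / (n_sets + 1)`, which is super-uniform
  under the null by construction.

Counting can be at the **locus** level (does any transcript associate at
p ≤ 0.05 with the lead SNP) or at the **pair** level (how many transcripts
do). With many transcripts the locus-level indicator saturates — the chance
that *some* transcript of thousands passes p ≤ 0.05 approaches 1 for every
SNP — so fold collapses to 1 regardless of signal. That is a property of the
statistic, not a bug; the pair-level count remains informative and the
analysis driver reports both. The acceptance suite calibrates the null
behavior with few transcripts precisely to keep the indicator non-degenerate.

## 5. Power

Analytic power uses the noncentral t distribution with noncentrality
`beta·sqrt(n·2·maf·(1 − maf))/noise_sd` and df = n − 2; the tail opposite a
large |ncp| underflows to NaN in scipy and is treated as 0. The simulation
arm draws genotypes and noise, applies BH per replicate batch, and agrees
with the analytic curve within Monte-Carlo error (checked at ±0.02 in the
tests). `predicted_sensitivity` averages analytic power over a set of
(|beta|, MAF) pairs at a given per-test alpha; the acceptance suite requires
the realized scan sensitivity on planted effects to be within 10 points of
it.

The effect-size axis is a log2 fold change per allele copy up to `x_max`,
and the simulated "population" of effects is drawn uniformly up to
`beta_max = 3.0` so that conditional power at the top of the grid is
well defined.

## 6. Synthetic cohort: scope and limits

Defaults (all overridable in the YAML config / `SimulationConfig`):
154 samples, 6,000 SNPs in LD blocks of 10 with within-block correlation
decay 0.8, MAF uniform on [0.05, 0.5], 400 autosomal probes plus 10
Y-chromosome probes, 4 chromosomes, SNP spacing 2–8 kb, log2 baselines
6–10 with 15% unexpressed probes near background, noise SD 1, covariate
effects on age/sex/center, 20 planted cis and 1 trans effect with |beta|
in [0.2, 2.0], and a defect specification of 4 low-call, 4 duplicate-pair,
2+2 heterozygosity and 13 stratified samples. These sizes make the full
pipeline run in seconds while leaving every filter with real work to do;
they are this package's own choices, not estimates of any particular
dataset.

Deliberate simplifications: genotypes are Hardy–Weinberg with block-local
LD only (no long-range LD, no relatedness structure beyond the injected
duplicates); expression noise is homoscedastic Gaussian on the log2 scale;
probe effects are additive with at most one planted effect per probe; the
stratified subgroup is a single frequency-shifted cluster. Detection of
that subgroup by Manhattan-distance clustering sharpens with the SNP count —
around 4,000 SNPs the separation is reliable, which is why QC-scale tests
use genome-sized panels rather than the small shared fixture.

All randomness derives from `numpy.random.default_rng([seed, stream])` with
a fixed stream id per subsystem (genotypes, annotation, covariates, planted
effects, expression, defects, matched sets, power, GWAS list), so stages are
independently reproducible and stage order does not perturb downstream draws.

## 7. Numerical choices

- p-values are floored at 1e-300 to avoid log-domain underflow in reports.
- Exact-fit residuals of zero are detected and mapped to the floor rather
  than dividing by a zero standard error.
- LD r² on a zero-variance vector is defined as 0 with a warning.
- Storey q-values with π₀ = 1 reproduce BH exactly (tested to 1e-14), making
  the conservative fallback continuous with the main path.
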