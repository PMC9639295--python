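# Methods

`reqtlkit` maps *response eQTLs* (reQTLs) in a paired two-condition design:
a panel of inbred genotypes, each profiled by RNA-seq once under control and
once under heat-stress conditions. This note documents the statistical
models, the defaults and why they hold, what the synthetic cohort does and
does not emulate, and the numerical conventions that make results
reproducible bit for bit.

## Models and procedures

### Per-condition eQTL scan

Expression per gene is CPM-normalized and rank-transformed to normal scores
(Blom offsets, `Phi^-1((rank - 3/8)/(n + 1/4))`, average ranks for ties).
For each condition the scan residualizes both the transformed expression and
the alt-allele dosages on the covariates (intercept, structure PCs, hidden
factors) via one QR projection, computes the Pearson correlation r for every
gene x variant pair as a single matrix product, and converts it to

    t = r * sqrt(df / (1 - r^2)),   df = n - n_covariates - 2,

which is inferentially identical to per-pair OLS with covariates (the test
suite verifies agreement to 1e-8). Variance explained is `t^2 / (t^2 + df)`.
Pairs within 1 Mb of the gene body (inclusive; signed distance to the
nearest gene edge, upstream negative relative to strand) are cis, all others
trans. BH adjustment runs within the cis and trans strata separately
(`bh_strata="joint"` is available); hits are pairs with adjusted p < 0.01.

Structure covariates are the first five PCs of the mean-centered dosage
matrix (columns not scaled; each component's sign fixed by making its
largest-magnitude loading positive). Hidden expression factors are the
top principal components of per-gene-standardized expression after
residualizing on the known covariates — a deterministic surrogate for
probabilistic factor models. Factor count defaults to 5 for cohorts of
~100-120 genotypes (the value 25 used on real panels assumes far more genes
and samples than the synthetic cohorts here).

**Genetic-factor screen.** Inferred expression factors absorb any strong
shared axis — including the signature of a genuine trans-regulator, which
would erase the very hotspots the trans scan looks for (with five factors
and a 1200-gene cohort, a planted 15-target regulator was absorbed in every
seed tested). Factors whose best single-variant R^2 exceeds 0.25 are
therefore dropped before use. The threshold separates cleanly: across
simulated cohorts, non-genetic factors reach at most ~0.12 (consistent with
the chance maximum `~2 log(m) / n` over m variants) while absorbed regulator
axes measure 0.48-0.63.

### Trans-eQTL hotspots

Trans hits are grouped by variant; a variant targeting >= 3 genes remotely
(> 1 Mb) is a candidate regulator. Candidates are binned on a fixed 0-based
10-kb grid, and a bin is a hotspot when the union of its candidates' target
genes exceeds 10 (i.e. >= 11).

### reQTL interaction model

For each gene commonly expressed in both conditions, the top cis hit per
condition is selected (ties broken by a seeded uniform draw). Two different
top variants merge into one candidate when their dosage r^2 > 0.8 (seeded
pick), and both are kept at r^2 <= 0.8; genes significant in one condition
contribute that variant. Each candidate pair is tested in the mixed model

    E = b0 + b_d d + b_c c + X B + (X:c) G + theta (d:c) + u_genotype + e,

with `d` alt dosage, `c` condition (control 0, heat 1), `X` the sample-level
covariates (structure PCs plus stacked-matrix expression factors, assigned
per sample-condition row), and a random intercept per genotype. The model is
fitted by REML: with equal group sizes the variance ratio is profiled and
each evaluation needs only the generalized eigenvalues of the group-sum Gram
matrix against X'X, computed once per gene — so a fit costs ~5 ms at
n = 120. The interaction t-test uses Satterthwaite denominator degrees of
freedom from the expected REML information (`df = 2 (c'Cc)^2 / (g'Ag)`).
In the balanced paired design with condition-invariant covariates this
reproduces OLS on within-genotype differences exactly, including
df = n - 32 with 30 covariates; an R lmerTest fit agrees with the engine to
1e-8 on coefficients and ~0.1% on df (expected vs observed information).
When the REML genotype variance lands on the zero boundary the two error
strata pool and the contrast oracle no longer applies — the engine handles
this case, the equivalence tests simply avoid it.

**Input scale.** The interaction model runs on `log2(CPM + 1)`, not on the
per-condition rank-normal scores used by the scans. A per-condition rank
transform standardizes each condition's variance; for strongly
heat-responding genes the heat-condition variance is inflated by genuine
response heterogeneity, so the transform shrinks real interactions (~3x in
simulation) while log2 CPM preserves the per-dose log2 effect scale. Null
calibration on log2 CPM is conservative (0 of 2000 all-null fits below
p = 1e-5).

Interaction p-values are Bonferroni-adjusted over the tested gene/variant
pairs; reQTLs are calls with adjusted p < 0.01 (strict). If both of a gene's
two candidates pass, the smaller-p one defines the gene's reQTL.

### reGene and heo-eGene classification

Classification uses homozygous dosage groups only (het genotypes excluded;
the panels are inbred) and requires >= 3 genotypes per group. Per allele,

    L = log2((median CPM_heat + 1) / (median CPM_control + 1));

the gene is prefixed `Ref` when |L_ref| > |L_alt| (`Alt` when smaller; exact
ties are ambiguous and excluded) and suffixed `Heat` when the larger-|L|
allele responds upward, `Control` otherwise. Heat-expressed-only (heo)
genes — expressed (CPM > 1 in >= 10% of genotypes, strict) under heat but
not control — become heo-eGenes when they carry a significant heat-condition
cis hit; their RefHeat/AltHeat class compares median heat CPM between the
homozygous groups at the top cis variant.

### Differential expression and consistency calls

The paired Wilcoxon signed-rank test compares CPM between conditions per
gene (exact null enumeration up to 25 non-zero untied differences, normal
approximation with tie/zero corrections otherwise; zero differences dropped,
Pratt's variant available). BH-significant genes (adjusted p < 0.01) with
|median-based log2 fold change| > 1 are up-/down-regulated ("less than 1"
in the source description is read as the symmetric bound). Consistent
upregulation requires both the median and the 90% quantile (type-7) of the
per-genotype log2 ratio to be positive; as written the quantile condition is
implied by the median condition (the intended bound was plausibly the 10%
quantile), so the quantile order is a parameter rather than a guess. The +1
CPM pseudocount applies to every ratio uniformly.

### Footprint integration

Fragments <= 80 bp are centered to 20-bp windows (odd lengths have a unique
middle base; even lengths choose one of the two with a seeded coin flip).
Differential occupancy between 3+3 replicate counts is a Welch t-test on
log2(CPM+1)-scale interval counts with BH < 0.05 — a deliberately simple
surrogate for a full differential-binding framework; pre-called statuses in
the BED columns bypass it. Footprints are assigned to genes by any-base
overlap with the gene body, the 2-kb flank, and the strand-aware 2-kb
promoter (BED intervals are 0-based half-open, gene models 1-based
inclusive; a variant at 1-based p occupies base [p-1, p)). Enrichment of
heat-enriched footprints near upregulated genes vs background is a one-sided
Fisher exact test on the presence/absence 2x2 table. For prioritization,
every variant in a reGene +- 1 kb is re-tested with the interaction model;
genes with any of the top-3 variants (raw p ascending, ties by distance to
TSS then position) inside a heat-enriched footprint are flagged, and pooled
-log10 p is compared inside vs outside footprints with a two-sided
Mann-Whitney test.

## Synthetic cohort

The generator emulates the statistical structure of a heat-stress diversity
panel at desk scale. Defaults: 120 inbred genotypes from 4 subpopulations
(Balding-Nichols allele frequencies, Fst 0.1), 6000 variants (9% InDels) in
20-variant LD blocks (within-block correlation 0.9, one shared frequency per
block so perfect correlation is attainable), residual heterozygosity 2%,
1200 non-overlapping genes on 3 chromosomes of 5 Mb. Counts are negative
binomial (dispersion 0.1) with log2 mean

    eta = alpha_g + beta_g^(c) d + delta_g c + sum_k lambda_gk f_k + u_g,

library sizes ~ U(0.8M, 1.2M), three hidden factors with sparse loadings
(30% of genes), and a per-genotype intercept (sd 0.2). Planted classes: 30%
cis-only (|beta| ~ U(0.5, 1.5) per alt dose), 5% reQTL split over the four
response categories with interaction |theta| >= 1 log2/dose and baselines
alpha ~ U(1, 4.5), 2% heo (alpha ~ U(-6, -4.5), activation delta ~ U(7, 9),
allele-dependent heat level ~ 1 log2/dose), 5% consistently upregulated
(delta ~ U(2, 4), alpha capped at 4.5), and two 15-target trans hotspots
(regulator effects ~ +-U(1.25, 2.0) per dose — strong enough to survive
structure-PC residualization and the genome-wide trans BH stratum). Causal
variants are drawn from gene body +- 2 kb with MAF >= 0.15. The baseline
caps on responding genes keep the heat library compositionally balanced;
without them the planted upregulation at desk scale (1200 genes rather than
tens of thousands) deflates every other gene's heat CPM by ~0.3 log2 units.
Footprints: ~2 background intervals per gene near the TSS (median width
~34 bp; 90% stable / 5% heat-enriched / 5% heat-depleted), a heat-enriched
footprint covering the causal variant of each upregulated reQTL/heo gene
with probability 0.8, an upstream heat-enriched footprint at each
consistent-up gene with the same probability, and 3+3 replicate counts
consistent with status (4x occupancy fold for enriched intervals).

What the generator does **not** emulate: sequence context, realistic
recombination maps and LD decay (block-uniform correlation instead), read
alignment artifacts, GC/length biases, batch structure beyond generic hidden
factors, dominance or epistasis, and multi-variant causal architecture.
Passing recovery tests therefore demonstrates the statistical machinery
under the stated generative model, not performance on any real panel.

## Numerical conventions and degenerate inputs

- Exact-vs-approximate switches are fixed: signed-rank exact for <= 25
  non-zero untied differences, Mann-Whitney exact for n*m <= 400 without
  ties, both two-sided by doubling the smaller tail.
- BH implements the step-up rule with enforced monotonicity and accepts an
  external family size m >= len(p); Bonferroni is min(1, p*m).
- Missing dosages are imputed as the variant mean rounded to the nearest of
  {0, 1, 2}, ties toward 1. Constant dosage vectors have r^2 defined as 0
  (with a warning); constant expression transforms to all zeros.
- LD pruning is greedy per window (50 variants, step 5): the first violating
  pair in position order loses its lower-MAF member, ties remove the later
  variant; windows run left to right per chromosome.
- Aliased design columns in the mixed model are dropped greedily left to
  right (earlier columns win); a dropped interaction column is an error for
  that pair, reported as a non-converged fit.
- Plasticity classes are rank-based tertiles (sizes differ by <= 1; ties
  resolve toward the lower class by sample order).
- All generator stages draw from `default_rng([seed, stage_constant])`, so
  any stage can be regenerated in isolation and every output is a pure
  function of the seed.

## Problem sizes used by the test and acceptance suites

Scan-oracle equivalence uses 50 genes x 200 variants x 60 samples; the
interaction oracle 100 balanced pairs at n = 120 with 30 covariates; FWER
control 20 all-null cohorts (n = 120, 250 genes, 1500 variants, 1000 tested
pairs each); recovery the full default cohort (n = 120, 6000 variants, 1200
genes); LD-pruning equivalence ten 500-variant chromosomes; footprint
prioritization twenty cohorts of 400 genes x 2400 variants. These sizes are
the package's chosen desk-scale study conditions; headline dataset-level
counts from real panels (tens of thousands of genes, >1M variants) are not
reproducible at this scale and are not targets of the suite.

## Known limitations

- Kenward-Roger degrees of freedom are not implemented; in the balanced
  paired designs this package targets they coincide with Satterthwaite.
- The hidden-factor surrogate is PCA-based; it will not match probabilistic
  factor models on real data with heteroskedastic noise.
- The differential-occupancy surrogate assumes 3+3 replicates and ignores
  interval-length and GC effects; supply pre-called statuses for real data.
- Satterthwaite df uses the expected (not observed) REML information;
  df values differ from lmerTest by ~0.1% in practice.
- `median_of_ratios` CPM uses a single global per-million rescaling after
  size-factor division; it is provided for compositional robustness checks,
  not as a DESeq2 replacement.
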