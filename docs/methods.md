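# Methods

This note documents the statistical models implemented in `adsigkit`, the
choices made where the procedures admit more than one reasonable
formulation, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Differential expression

### Mouse RNA-seq: NB exact test

Counts are modelled as negative binomial with variance μ + φμ².  The
test follows the classic two-group exact construction:

1. **Expression filter.** Genes with mean TPM ≤ 1 across all samples are
   removed before testing (strict inequality).
2. **TMM normalization.** Per-sample factors are the trimmed weighted mean
   of gene-wise log2 ratios (M-values) against a reference sample (the one
   whose upper-quartile count fraction is closest to the mean), with 30 %
   two-sided trimming on M, 5 % on average log expression A, and inverse
   asymptotic-variance weights.  Genes with a zero count in either sample
   are excluded from the mean; factors are rescaled to geometric mean 1.
3. **Quantile adjustment.** Effective library sizes (library size × TMM
   factor) are equalized to their geometric mean; counts are scaled
   accordingly and rounded to the nearest integer with ties to even.
4. **Common dispersion.** φ is estimated by moment matching on the
   equalized pseudo-counts: per gene, (s² − m̄)/m̄² from the within-group
   residual variance, averaged over genes and clipped at 0.  Only a common
   dispersion is fitted — no tagwise or trended component.  This is a
   deliberate simplification: it keeps the conditional enumeration
   tractable and exactly testable, and on the simulated data it recovers
   the generating φ to within a few percent.
5. **Exact p-value.** Conditional on a gene's total pseudo-count t, the
   group-A sum is distributed as the convolution of two NB group sums
   (means n·μ̂, dispersions φ/n).  The two-sided p sums P(a | t) over all
   splits a = 0…t with probability not exceeding the observed one (a
   relative tolerance of 1e-10 guards ties against floating-point noise).
   At φ = 0 this reduces to a binomial split of a Poisson total, which is
   the oracle used in the tests.
6. **Fold change.** log2FC uses the equalized group means with a prior
   count of 0.125 on both sides (configurable).  FDR is Benjamini–
   Hochberg.  DEG calls use strict inequalities: FDR < 0.05 and
   |log2FC| > log2(2) for mouse.

### Human microarrays: SAM

On log2 intensities, d_i = (x̄_B − x̄_A)/(s_i + s₀) with the pooled
two-group standard error s_i.  The fudge constant s₀, when "auto", is
chosen by the percentile rule: candidates are the 5-percent quantiles of
the s_i distribution; for each, genes are binned into 100 s-percentile
windows and the candidate minimizing the coefficient of variation of the
within-window median absolute deviations of d is selected.

The null distribution permutes group labels.  When the number of distinct
assignments C(n, n_B) is at most `n_perm` every assignment is enumerated
and p-values are exact multiples of 1/B (the identity assignment is
included, so p ≥ 1/B); otherwise `n_perm` seeded draws are used with
add-one smoothing (1 + #extreme)/(1 + B) so p is never 0.

FDR uses Storey q-values: π₀ is estimated on the λ grid 0.05…0.95 by a
cubic polynomial fit evaluated at the grid maximum; for fewer than 100
p-values this estimate is unstable and the conservative fallback
π₀ = min(1, 2·mean(p)) is used.  Human DEG calls: q < 0.10 and FC > 1.5.
The mouse arm uses BH and the human arm q-values, matching the two
communities' conventions for these platforms.

## Pathway scores

The rank-weighted single-sample score ranks each sample's genes by
descending expression (1-based, average ranks on ties) and weights gene g
by exp(−decay · rank/N), decay = 1 by default.  A set's score is the mean
weight over member genes present in the matrix minus the mean over
non-members, so scores lie in (−1, 1), are exactly 0 for constant
expression, and are invariant under any strictly monotone per-sample
transform.  The exponential-decay difference-of-means is one member of the
rank-weighting family; the decay constant is exposed rather than fixed, and
no claim is made of bit-compatibility with any particular implementation.
Sets with no expressed member or with an empty complement are dropped and
reported.  Pathway contrasts are equal-variance t-tests (BH-corrected
"corrected P"; the correction procedure is a package choice), and
cross-contrast concordance is the Pearson correlation of t-statistic
vectors over shared pathway names (≥ 3 required).

## Signature assembly and the AD index

Gene pools intersect DEG calls requiring identical direction in every
table; mouse tables are first mapped into human symbol space through the
one-to-one ortholog map (ambiguous one-to-many / many-to-one pairs are
dropped and reported — no tie-break is attempted).  Weights are the human
direction: +1 up, −1 down in lesional skin.

The AD index of sample j is Σᵢ wᵢ (eᵢⱼ − μᵢ)/τᵢ over usable signature
genes, with μᵢ, τᵢ the mean and n−1 standard deviation across the scored
sample set (lesional and non-lesional together when a mixed cohort is
scored; a `stats_in` argument allows reusing a standardization fitted on
another set).  Zero-variance and absent genes are excluded and reported.
Consequences used as test invariants: indices sum to 0 over the
standardization set, are invariant under per-gene affine rescaling, and
negate when all weights are negated.

Severity validation is the Pearson correlation with SCORAD over complete
pairs (≥ 3); treatment response is a paired t-test on per-subject index
changes between two timepoints within one tissue, excluding (and counting)
subjects missing either timepoint.

## Resampling benchmark

B random signatures are drawn uniformly without replacement from a pool,
independently across signatures (the candidate's own genes are not
excluded from the pool by default; a flag allows it).  Each draw uses a
child seed stream spawned from the master seed so enlarging B never
reshuffles earlier draws.  Each signature is scored with the AD index and
correlated with SCORAD; the candidate's tail probability uses add-one
smoothing, (1 + #{r_b ≥ r_obs})/(B + 1), whose floor at B = 1000 is
1/1001 ≈ 0.001.  Because any drawn signature's index is a weighted sum of
per-gene z-score rows, the rows are computed once per pool and reused;
draw-level results are bit-identical to scoring each signature separately.
Pool-versus-pool comparison is an equal-variance t-test on the two
correlation distributions.

## Synthetic studies

The generator emulates the full study design with planted truth:

* **Mouse arm** — four groups (VT, CHS, NT, SSS), 4 replicates each.
  NB counts with φ = 0.1, baseline means log-uniform on 5–500, library
  factors log-uniform within ±30 %.  Planted per direction: 30 DEGs shared
  by both models at log2FC 2, 25 per model-specific direction, plus 10
  genes dysregulated in opposite directions in the two models and 200
  low-expression genes (baseline 0.02–0.3) that the TPM filter removes.
  TPM is derived from counts with unit gene lengths.
* **Human discovery cohorts** — DE-like (14 control / 12 lesional) and
  SE-like (10/10) log2 intensities: uniform 6–12 baselines, Gaussian noise
  σ = 0.4, lesional effect ±1.2 log2 units planted concordantly in both
  cohorts on the ortholog images of half the mouse shared DEGs (these 30
  genes are the true signature) and on 40 human-only DEGs.  An optional
  probe-level expansion (2–3 probes per gene) exercises the
  geometric-mean probe collapse.
* **Validation cohort** — 19 subjects × {baseline, week2, week12} ×
  {lesional, non-lesional}.  A per-subject severity latent ~ N(2, 1)
  drives signature-gene expression (coupling 1.0 lesional, 0.5
  non-lesional); treatment multiplies it by 1.0 / 0.6 / 0.45 at the three
  timepoints.  The latent's positive mean is what makes multiplicative
  attenuation lower the index on average, giving the paired tests a
  defined direction.  SCORAD is generated from the realized mean
  signature z-score standardized within tissue, plus Gaussian noise with
  σ_η = sqrt(1/ρ² − 1) so that the within-tissue correlation with the
  true-signature score is the designed ρ = 0.8 (40 + 12·(t + η), floored
  at 0).
* **Fixtures** — the ortholog map is the capitalization bijection plus 20
  decoy one-to-many pairs planted on non-DEG genes to exercise the
  ambiguity-drop path; the pathway collection holds 50 sets (sizes
  10–100), the first two seeded with the planted up- and down-regulated
  genes so pathway contrasts carry real cross-species signal.

What the generator does **not** emulate: probe-specific affinity effects,
batch and platform effects, correlated gene-gene noise, dropout subjects,
and realistic read-depth heterogeneity beyond the ±30 % library factors.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration, not robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

* Writers sort rows and columns and print floats at 6 significant digits,
  so identical inputs give byte-identical files.
* Pathway t-tests with zero pooled variance return t = 0, p = 1 when the
  means are equal; otherwise t is capped (±1e12) with p = 0 and a
  `degenerate` flag.
* Paired tests whose per-subject differences are all equal return p = 1
  (all zero) or p = 0 (all equal, nonzero).
* Every stochastic routine takes an explicit integer seed (default 17) and
  records it in the run report; the full pipeline is bit-reproducible from
  (config, seed).
* Problem sizes in the test suite: oracle tests run on 4–60 genes;
  calibration and recovery checks run at the default study scale
  (2,000 genes, B = 200–1,000 resamples, 100 validation replicates),
  chosen so the whole suite completes in well under a minute on one core.

## Limitations

Only a common NB dispersion is fitted; GLM-style contrasts, batch
correction and tagwise shrinkage are out of scope.  Ortholog handling is
strictly one-to-one; paralog-aware mapping is not attempted.  SCORAD is
treated as an externally supplied covariate — the package does not compute
it from clinical items.  The resampling scheme randomizes genes, not
sample labels.
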