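# Methods

## The aging model

Each gene *i* is assumed to follow a linear aging law on the log2 scale,

    Y_ij = b0_i + b1_i A_j + b2_i S_j + b3_i A_j S_j + e_ij,

with chronological age `A_j` (years), sex indicator `S_j` (female = 0,
male = 1), and homoscedastic Gaussian residuals `e_ij ~ N(0, s_i^2)` per
gene. An intercept `b0_i` is always included. The design therefore allows
both a sex main effect (`b2`, log2 units) and a sex-specific aging rate
(`b3`, log2 units/year); `b1` is the aging rate of females, `b1 + b3` that
of males.

Fitting is ordinary least squares. Because every gene of a dataset shares
the same design matrix, all genes are fitted in one vectorised
normal-equations pass; the residual variance is the unbiased estimate
`RSS/(n - p)` and coefficient p-values are two-sided t-tests on `n - p`
degrees of freedom (p = 4, or 2 for single-sex data). This batch solve is
numerically identical (to ~1e-13) to statsmodels OLS on each gene, which the
test suite verifies against both statsmodels and an explicit 4x4
normal-equations solve.

Degenerate inputs are handled explicitly rather than propagating NaNs:

* constant-expression genes get `b1 = b2 = b3 = 0`, all p-values 1, and a
  `degenerate` flag (plus a warning) — they can never be selected;
* genes fitted exactly (zero residual, e.g. noise-free synthetic data) get
  p = 0 for nonzero coefficients and p = 1 for zero ones;
* single-sex datasets are refitted on `[1, A]` with `b2 = b3 = 0` and
  `p2 = p3 = 1`, since the sex terms are inestimable; this keeps heavily
  sex-skewed cohorts usable.

## Gene filtering

Two nominal thresholds, applied in order and both configurable:

1. **Sex filter** (`alpha_gender = 0.05`): genes with `p2 <= 0.05` or
   `p3 <= 0.05` are removed. The filter's purpose is to prevent cohort sex
   composition from leaking into age prediction. A literal inversion of
   this rule (removing the sex-*neutral* genes) is exposed behind
   `literal_gender_filter=True` for comparison, but it contradicts the
   filter's purpose and is not the default. Note the filter operates at its
   own test level: it falsely removes a design-dependent 5–10% of genuinely
   sex-neutral genes (two correlated level-0.05 tests), which bounds
   attainable age-gene recovery at roughly 90–95% regardless of
   signal strength.
2. **Age selection** (`alpha_age = 0.005`, inclusive): genes with
   `p1 <= alpha_age` form the predictor. No multiple-testing correction is
   applied; thresholds are nominal by design, and gene-list analyses
   (region comparisons at 0.01, disease lists at 0.001) use their own
   nominal cut-offs.

## Age prediction

For a sample of sex `S`, each predictor gene has effective intercept
`c_i = b0_i + b2_i S` and slope `s_i = b1_i + b3_i S`. The sex terms are
retained here even though selected genes are sex-neutral: their fitted
values are near zero by construction, so this is harmless and faithful to
the fitted model. Two aggregation rules convert per-gene votes into one
age:

* `weighted_ls` (default): the closed-form minimiser of
  `sum_i w_i (y_i - c_i - s_i a)^2` over age `a`, with precision weights
  `w_i = 1/max(resid_var_i, 1e-8)`. This is the maximum-likelihood age
  under the Gaussian model — inverse regression weighted by how tightly
  each gene tracks age. The variance floor only matters for noise-free
  synthetic data.
* `median_inversion`: the median of `(y_i - c_i)/s_i` over genes with
  `|s_i| > 1e-12`; robust to a few outlying genes, less efficient
  otherwise.

The choice of combination rule is a genuinely open design point (no single
canonical estimator exists for inverse calibration from many univariate
regressions); both interpretations are provided and the default is the
likelihood-based one. Predictions are not clamped to the training age
range.

## Cross-platform harmonisation and calibration

Platform differences are bridged with vendor best-match probeset tables,
treated as a plain binary relation: a model gene is retained if it maps to
at least one target probeset, and multi-mapped target rows are averaged so
exactly one value feeds each model gene. Baseline (experimental-technique)
differences are modelled as a single constant log2 offset, estimated as the
**median** over shared housekeeping genes of (reference mean − target
mean); the median is chosen over the mean so a few misbehaving housekeeping
genes cannot corrupt the calibration. Calibrated predictions are exactly
invariant to any constant shift of the target dataset (a property test
checks this at 1e-9 over shifts in ±5 log2 units).

## Validation

* **Five-fold cross-validation**: samples are randomly partitioned
  (seeded) into folds of near-equal size; the *entire* training pipeline —
  sex filter and age selection included — is re-run on each 80% split, so
  the held-out error is unbiased by gene selection. Selecting genes once on
  all data would be cheaper but optimistically biased; the per-fold choice
  is deliberate.
* **Error metrics** over pooled held-out predictions: mean and sample SD of
  absolute errors (reported as `mean ± SD`), the absolute difference of
  medians, and the median absolute difference. The last two differ in
  general (the tests include a distinguishing example).
* **Permutation test**: ages are shuffled across samples (sex stays with
  its sample, since the model uses sex as a covariate rather than a
  prediction target) and the full cross-validation is re-run per
  permutation. The p-value is the strict fraction of permuted errors below
  the observed error — it can be exactly 0; the positively biased
  `(b+1)/(m+1)` estimator is available behind `p_value_method="add_one"`.
  Permutations in which no gene survives selection in any fold count as
  infinitely bad (they cannot beat the observed error).
* **Cohort-median scaling**: the error of a cohort's *median* age estimate
  shrinks relative to the per-individual error like `1/sqrt(n - 1)`,
  analogous to a standard error versus a standard deviation. For Gaussian
  errors the exact factor is the sample-median efficiency
  (`sqrt(pi/2) ~ 1.25` asymptotically), which deviates from
  `1/sqrt(n - 1)` by 12–22% for n between 10 and 50; the scaling rule is
  therefore validated at 25% relative tolerance, using 4000 simulated
  cohorts per size so the Monte Carlo error on the measured SD (~1%) is
  negligible against the tolerance.

## Disease cohorts and gene-list overlap

Age acceleration is the difference between predicted and chronological age
in a cohort, tested with a two-sided **paired Wilcoxon signed-rank test**.
The test is implemented in-package with a pinned contract: zero differences
are dropped; for up to 25 non-zero differences the exact sign-flip
distribution of the positive-rank sum is enumerated by integer convolution
(midranks doubled so ties stay on the integer lattice; two-sided p is twice
the smaller tail, capped at 1); beyond 25 a normal approximation with tie
correction (and no continuity correction) is used. Both regimes are
verified against scipy and against brute-force enumeration of all sign
assignments.

Disease-associated genes are defined by Welch's unequal-variance t-test at
`p < 0.001` combined with an absolute mean log2 difference above
`log2(2) = 1` (fold change > 2). Overlap between gene lists is tested with
the one-sided hypergeometric enrichment tail over a declared universe —
the defensible universe being the genes assayed on both platforms after
harmonisation, which the caller supplies explicitly; a two-sided Fisher
variant is available. Enrichment is one-sided by default because the
scientific claims being tested are enrichment claims.

## Synthetic data

The generator emulates exactly the structure the model assumes: ages
uniform on 20–95 years (every adult decade represented), sexes
Bernoulli(1/2), baselines uniform on 4–12 log2 units, age genes with
slopes drawn uniformly from ±[0.01, 0.05] log2/year, sex-affected genes
with main effects ±[0.5, 1.5] log2 (half also carrying interactions
±[0.02, 0.06] log2/year), flat housekeeping genes, and i.i.d. Gaussian
noise (default SD 0.3 log2; 0.5 for the harder recovery checks). Gene
roles are disjoint sets — in particular sex-affected genes are drawn only
from genes that are neither age- nor housekeeping genes, so the sex filter
removes confounders rather than signal. Disease cohorts are generated by
evaluating the expression mean at `age + acceleration` years — the minimal
generative form of a "prematurely aged" profile — optionally plus a
constant dataset offset applied after the noise.

What the generator does **not** emulate: probe-level effects, non-constant
batch structure, heteroscedastic or heavy-tailed noise, correlated genes,
nonlinear aging trajectories, and region-specific biology. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness of the biology to their violation on real
arrays.

## Problem sizes and numerical choices

Default test/validation problem sizes are 120 samples × 500 genes (50 age
genes, 50 housekeeping), five folds, 100 permutations in the acceptance
runs, 50 replicate cohorts for null calibration, and 4000 cohorts for the
scaling law — sizes at which every stochastic check has comfortable
statistical resolution. Ties in the Wilcoxon statistic are handled by
midranks; the even-length median is the midpoint of the two central order
statistics throughout; the per-gene residual-variance floor is 1e-8 and the
zero-slope guard 1e-12. All stochastic entry points take an explicit seed
and are bit-reproducible given it.

## Known limitations

* The constant-offset calibration cannot correct gene-specific platform
  effects; it assumes the baseline shift is shared across genes.
* The per-gene models ignore gene–gene correlation, so the weighted
  combination overstates its nominal precision when genes are co-regulated;
  predicted ages remain consistent, but no uncertainty is attached to them.
* Selection at nominal thresholds is intentionally uncorrected for multiple
  testing; selected gene lists on null data contain the expected share of
  false positives.
* With fewer than ~10 samples per fold, per-fold gene re-selection becomes
  unstable; failed folds are reported rather than silently dropped.
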