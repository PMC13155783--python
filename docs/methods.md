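# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Model and estimators

All analyses operate on per-SNP summary associations
(beta, SE) from non-overlapping GWAS cohorts. For instrument SNP *j* with
exposure association `x_j` (SE `sx_j`) and outcome association `y_j`
(SE `sy_j`) aligned to the same effect allele, the Wald ratio
`y_j / x_j` with first-order SE `sy_j / |x_j|` is the shared primitive.

* **IVW** is weighted least squares of `y` on `x` through the origin with
  weights `sy^-2`, algebraically identical to the `se^-2`-weighted mean of
  Wald ratios. The default is the multiplicative random-effects variant:
  the fixed-effect SE is inflated by `sqrt(max(1, Q/(k-1)))`, which leaves
  well-behaved data untouched and absorbs over-dispersion otherwise. The
  fixed-effects variant is available by flag. (The choice of variant is a
  package decision; summary-data MR practice is split and the difference
  vanishes when Q <= k-1.)
* **MR-Egger** adds a free intercept after orienting SNPs to non-negative
  exposure betas; the intercept and its normal-theory p-value are the
  directional-pleiotropy test. SEs use the same multiplicative
  over-dispersion factor with k-2 denominator.
* **Weighted median**: ratios are ordered, cumulative normalised weights
  `w = se^-2` computed at each ratio's centre
  (`(cumsum(w) - w/2) / sum(w)`), and the estimate linearly interpolated at
  0.5. With equal weights and odd k this is exactly the sample median.
* **Simple / weighted mode**: the estimate is the argmax over a dense grid
  (512 points) of a normal-kernel density of the ratios with uniform or
  `se^-2` weights. Bandwidth is a modified Silverman rule,
  `0.9 * min(sd, mad/0.6745) * k^(-1/5)`, scaled by a configurable
  `bandwidth_factor` (default 1). When the MAD is zero (clustered ties)
  the SD is used, and vice versa; if all ratios coincide the common value
  is returned for any bandwidth.
* Median and mode SEs come from a parametric bootstrap (default 1,000
  resamples) drawing `x* ~ N(x, sx)`, `y* ~ N(y, sy)` per SNP, with an
  explicit seed. p-values are two-sided normal throughout — a summary-data
  convention; with the instrument counts involved the normal/t distinction
  is immaterial.

## Instrument selection and harmonization

Instruments are exposure SNPs with p below a threshold (default 1e-5 —
the relaxed threshold commonly used for molecular phenotypes where 5e-8
leaves too few variants), clumped greedily: sort ascending by p (ties
broken by chromosome, position, then identifier, for determinism), keep
the best SNP, discard remaining SNPs with r² >= 0.001 to a kept SNP within
10,000 kb on the same chromosome, repeat. SNPs absent from the LD matrix
are treated as unlinked with a logged warning.

Instrument strength is `F = [R²(N−1−K)] / [K(1−R²)]` with R² the summed
per-SNP variance explained: `2 p (1−p) beta²` when the effect-allele
frequency is available, else `beta² / (beta² + N se²)`. Both forms are
standard; which one feeds F is a package decision since only the F formula
itself is prescribed. Sets with F <= 10 (strictly) are flagged weak and
excluded downstream.

Harmonization aligns outcome records to the exposure's effect allele:
matching allele pairs pass through, swapped pairs flip the outcome beta's
sign and complement the frequency, anything else is dropped as an allele
mismatch. Palindromic SNPs (A/T, C/G) are kept only when both study
frequencies fall outside the ambiguity band (default 0.42–0.58, a common
convention) and on the same side of 0.5; strand-flip inference for
ambiguous palindromes is deliberately not attempted. Harmonization is
idempotent and every exclusion is reported with a reason.

## Sensitivity diagnostics

* **Cochran's Q** around the IVW estimate with first-order ratio SEs,
  chi-square with k−1 df.
* **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares with each SNP's residual taken against the slope fitted without
  it (so an outlier cannot mask itself). The null distribution comes from
  parametric simulations (default 1,000): `x* ~ N(x, sx)`,
  `y* ~ N(beta_ivw * x, sy)`, refitting the leave-one-out slopes per
  simulation. The pooled (not leave-one-out) slope generates the null
  because per-SNP slopes would inject their sampling scatter into the
  simulated outcomes twice, making the global test conservative (verified
  by calibration: empirical type-I error ~0.047 at nominal 0.05).
  Monte-Carlo p-values use the `(1+exceedances)/(1+n_sim)` convention.
  Outliers are flagged at `alpha/k` (Bonferroni); the distortion p-value
  compares the estimate shift after outlier removal with removing equally
  many random SNPs.
* **Leave-one-out** IVW re-estimates flag omissions that change the sign
  or nominal significance of the estimate; **funnel data** pairs each
  ratio with its precision, with asymmetry summarised by the Egger
  intercept.
* The combined **verdict** drives the screening gate: an exposure is
  excluded when Q p < 0.05, Egger intercept p < 0.05, or MR-PRESSO global
  p < 0.05.

## Mediation

`decompose` computes `ab = a*b`, `c' = c − ab`, `proportion = ab/c` and
the delta-method SE `sqrt(a² se_b² + b² se_a²)`. An optional `rounding`
argument rounds `ab` to a fixed number of decimals *before* deriving `c'`
and the proportion — this reproduces published tables computed from
rounded intermediates; note that tables derived this way can be internally
inconsistent at the printed precision (one published glycosylceramide-style
row is: 0.031 × 0.078 = 0.0024, not the printed 0.0025), which the package
reports as-is rather than force-fitting. Both the rounded and full-precision
paths are exposed; the identity `c = c' + ab` always holds exactly for the
stored `ab`.

Only IVW feeds the decomposition (it is the primary estimator); the other
four methods are reported alongside but never enter `a`, `b` or `c`.
Masking is classified purely by the sign rule `sign(ab) != sign(c)`.
A zero total effect leaves the proportion undefined (NaN with a warning).
No multiple-testing correction is applied across screens by default, to
match the raw p < 0.05 screening convention; Benjamini–Hochberg is
available behind a flag.

The screening funnel: (1) exposures with IVW p < 0.05 on the outcome;
(2) drop exposures failing the sensitivity verdict; (3) keep mediators
with significant exposure→mediator *and* mediator→outcome IVW effects;
(4) decompose and classify. Reverse MR is the same forward chain with
roles swapped; when the outcome trait has no instruments at the threshold
the check is reported as not-evaluable rather than passed.

## The synthetic-data generator

The generator emulates the three-cohort two-step design: a continuous
exposure (cohort of 3,757 — the size of the Sardinian immune-phenotype
GWAS), a continuous mediator (8,299 — the CLSA metabolite GWAS) and a
binary outcome on the log-odds scale (406,565 with 28,546 cases — the
FinnGen myocardial-infarction cohort). Per SNP the expected associations
follow the structural equations

```
E[x] = gamma
E[m] = a*gamma + kappa
E[y] = (c_dir + a*b)*gamma + b*kappa + alpha
```

with observed betas adding independent normal noise at the standard
summary-statistic SE `1/sqrt(2 p (1−p) n)` (outcome n deflated by
`phi(1−phi)` for case fraction `phi`). SNP roles are disjoint by default:
exposure instruments (`gamma != 0`), mediator-specific instruments
(`kappa != 0`), and optionally outcome-specific loci (`alpha != 0`) that
give reverse-MR analyses genuine instruments. Effect magnitudes default to
|U(0.1, 0.5)|: strong enough that instruments clear F > 10 at the small
exposure-cohort size, and spread widely enough (high instrument-strength
heterogeneity, I²GX ≈ 0.95) that MR-Egger's slope does not suffer
appreciable regression dilution — with near-equal instrument strengths the
Egger intercept test is visibly anti-conservative, which is a property of
the estimator, not of the implementation. Allele letters are random with a
10% palindromic fraction to exercise harmonization; `inject_ld_blocks`
re-simulates with block-constant causal signals and noise correlation
`sqrt(r²)` for clumping tests.

What the generator does **not** emulate: realistic LD from a reference
panel, MAF-dependent effect-size architecture, population stratification,
sample overlap between cohorts, winner's curse in the source GWAS, or
binary-trait non-collapsibility (the outcome is linear on the log-odds
scale by construction). A green calibration test therefore establishes
correctness of the estimators and diagnostics under clean two-sample
assumptions — not robustness to those real-data complications.

## Calibration conventions and numerical notes

* Calibration studies (CI coverage, Q uniformity, MR-PRESSO type-I error)
  bypass the significance threshold and harmonization and pair the
  generated datasets directly, to avoid conditioning the sampled SNPs on
  their own p-values (winner's curse would otherwise contaminate what is
  meant to be a pure estimator check).
* Q-uniformity is assessed in the null-effect world: with a nonzero causal
  effect the first-order ratio SE omits the `beta² sx²` term, inflating Q
  by a factor `1 + beta² sx²/sy²` — a known property of the first-order
  approximation, visible at the default cohort-size ratio once
  |beta| > ~0.05. The coverage check keeps a nonzero effect because the
  multiplicative random-effects SE absorbs that same inflation.
* Simulation seeds are threaded explicitly everywhere; scenario seeds and
  resampling seeds are always distinct integers. Seeds derived from a root
  stay below 2^31.
* The weighted-median interpolation clamps to the extreme ratios when the
  0.5 quantile falls outside the weight centres; bootstrap SEs of
  degenerate (all-identical) fixtures are reported as a tiny positive
  number rather than zero so downstream Wald machinery stays defined.
* Zero-exposure-beta SNPs are dropped from ratio-based computations with a
  warning; datasets failing validation row-wise are filtered with a
  per-row reason, and only an entirely invalid file is an error.
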