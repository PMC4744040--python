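# Methods

## Design overview

The package implements an allele-score Mendelian-randomization design
for the effect of alcohol consumption on nine lipid measures, together
with a synthetic cohort generator that reproduces the statistical
structure the estimator assumes. Everything the estimator sees — the
exposure coding, the screening thresholds, the covariate roster, the
quartiled second stage — follows the published study design this
pipeline emulates; everything the generator invents (noise levels,
confounder strengths, curve magnitudes) is our own choice and is
documented here.

## Exposure model and recording convention

Alcohol is analysed as x = ln(g/wk + 1). Never and former drinkers,
and current drinkers averaging under one drink per week, are recorded
as 0 g/wk; "one drink" is operationalised as one 12-oz-beer-equivalent
(13.2 g ethanol), since no standard-drink gram value is defined for
the classification rule. Gram conversions are 10.8 / 13.2 / 15.1 g per
wine / beer / liquor unit. Heavy drinking is > 210 g/wk for men and
> 105 g/wk for women, with the boundary itself low-to-moderate.

In the generator, latent log-consumption for current drinkers is

x* = a₀ + Σⱼ βⱼGⱼ + 0.9·male + (−0.01)·(age − 54.3) + 0.4·U + ε,
ε ~ N(0, σ²), truncated at 0,

with the five instrument SNPs' allele frequencies (0.001, 0.172,
0.169, 0.409, 0.313) and per-allele effects (0.33, 0.06, 0.07, 0.05,
0.07) on the log scale. Drinking status (never/former/current with
probabilities 0.181/0.170/0.649) is independent of genotype, so the
exclusion restriction holds by construction; an optional switch
couples abstention to the latent confounder U for reverse-causation
stress tests.

**Causal curves act on the recorded exposure.** Lipid means depend on
the recorded x (zero for abstainers and sub-one-drink drinkers), not
the latent x*. This makes the estimand of the continuous 2SLS exactly
the curve parameter — consumption below one drink a week is treated
as having no effect, consistent with the recording rule — and keeps
the linear-recovery oracle exact rather than attenuated.

**Calibration.** The intercept a₀ = 2.9 and noise σ = 1.15 were tuned
once by simulation so that the unweighted score's first-stage partial
R² averages ≈ 0.11% at n ≈ 10⁴ (F ≈ 11) — the weak-instrument regime
that motivates the F > 10 diagnostic — while keeping the drinker
category mix and the mean recorded consumption (≈ 45 g/wk) near the
reference cohort summary. A single draw's partial R² has sampling SD
≈ 0.08 percentage points in this regime, so the calibration band
[0.05%, 0.2%] is a statement about the replicate mean, not any one
draw.

## Lipid model

Skewed lipids (TG, HDL2-c, sdLDL-c, apoB, Lp(a)) are drawn lognormal
around reference medians; total cholesterol and HDL3-c are Gaussian
around reference means, floored at 1 mg/dL (no negative
concentrations). HDL-c is emitted as the sum of latent HDL2-c and
HDL3-c so that the downstream subtraction HDL2-c = HDL-c − HDL3-c
recovers the causal HDL2-c signal. LDL-c is not generated: it is
derived downstream by the Friedewald formula (TC − HDL − TG/5,
undefined when TG > 400 mg/dL), so its causal behaviour emerges from
its parents. Lp(a) is emitted on the legacy assay scale and rescaled
by 1.326 during derivation. sdLDL-c and apoB carry a visit-4
attendance process (default 78%) and use visit-4 age in their models;
baseline lipids have a 5% sporadic missing rate.

A causal curve per lipid maps recorded x to the lipid mean: `null`,
`linear(β)`, or `peaked(rise, peak_location, decline)` — a
piecewise-linear function with slope `rise` up to the turning point
and `decline` beyond it. Default curves give TG, total cholesterol,
sdLDL-c and apoB a trough (and HDL2-c a peak) at x = 4.1 (~59 g/wk),
with HDL3-c and Lp(a) null; magnitudes are realism-only defaults.

The latent confounder U ~ N(0,1) raises drinking and shifts each
lipid (e.g. +0.12 on ln TG), and drives the observed confounders
(smoking, BMI, waist-to-hip ratio, diabetes) as noisy functions, so
the instrument screens have real structure to test against.

## Estimator

* **First stage**: OLS of x on score + sex + age + PC1 + PC2 over the
  outcome's complete cases. Partial R² = (RSS_red − RSS_full)/RSS_red;
  F is the nested-model F for the score, satisfying
  F = R²/(1−R²)·(n−k) exactly. F ≤ 10 sets a weak-instrument flag on
  the results row; it never gates estimation.
* **Quartiles**: empirical 25/50/75 cut-points of the fitted exposure,
  recomputed per outcome model on that model's complete-case set
  (per-outcome sample sizes differ); boundary ties go to the lower
  quartile; boundaries are also reported as exp(x)−1 g/wk. A config
  switch computes them once globally instead.
* **Second stage**: OLS of the (possibly ln) lipid on quartile
  indicators plus covariates. Default covariance is
  heteroskedasticity-robust (HC1), with a classical option; Wald
  tests use the large-sample normal/χ² reference (n ≈ 10⁴). The
  reported intervals are conditional on the estimated quartile
  assignment — no closed-form generated-regressor correction exists
  for quartiled fitted values.
* **Continuous 2SLS**: explicit two-step with standard errors from
  residuals recomputed at the observed exposure; the point estimate
  is checked against the closed-form just-identified IV solution
  (partialled Wald ratio) to 1e-8 in tests.
* **PC helper**: genotype columns centred at 2p̂, scaled by
  √(2p̂(1−p̂)); leading left singular vectors, sign fixed by the
  largest-magnitude loading. This is a functional stand-in used to
  generate/consume ancestry covariates; reproducing any particular
  stratification software is out of scope.

## Screening

Screens run in order: (1) LD with supplied lipid-locus genotypes
(r² > 0.2 fails), (2) Pearson correlation with smoking (ordinal
0/1/2), BMI, WHR, diabetes (0/1) — any single |r| > 0.1 fails,
(3) pairwise LD among survivors (r² > 0.7), resolved per connected
component by functional class (exonic/splicing first), then source
sample size, then lexicographic id — fully deterministic, so the
surviving set is invariant to candidate order. LD is composite r² on
unphased dosages. Correlations use pairwise-complete observations
with a 50-individual floor; below it the statistic is undetermined
and strict mode fails conservatively. The assembled score is
re-screened with the same criteria; breaches are recorded as flags.
Scores are computed only for individuals with complete dosages
(unweighted sums are biased by per-individual missingness).

## Replicate studies and what they show

* **Linear recovery** (500 cohorts, n = 10,000): with a true effect of
  −0.13 on ln TG and the confounder active, the 2SLS replicate mean is
  within Monte-Carlo error of the truth while OLS is biased upward
  (toward zero) by construction.
* **Wald size** (n = 2,000 per cohort): under a null curve with
  confounding, the 3-df overall test rejects at ≈ 0.058 — a small
  intrinsic inflation from the estimated quartile boundaries at this
  n, inside the 0.05 ± 0.015 band. Replicates whose second-stage
  design is exactly rank-deficient (male count landing precisely on
  the median fitted-value boundary) are excluded; ≲ 0.1% of draws.
* **Calibration** (20 cohorts, n = 10,000): mean partial R² in
  [0.05%, 0.2%].
* **Peaked-curve pattern** (200 cohorts, n = 20,000): run under a
  dose-response *resolution* design — current drinkers only
  (mirroring the never/former-excluding sensitivity analyses),
  exposure noise 0.35, TG curve with rise −0.40 to a trough at
  x = 4.1 inside the third predicted-exposure quartile and decline
  +0.60 beyond. There |β_q3| ≥ |β_q4| in ~100% of replicates, with
  the mean pattern (β₂, β₃, β₄) ≈ (−0.06, −0.08, −0.04) reproducing
  the qualitative third-quartile-dominant shape. Under the *default*
  weak-instrument mixed cohort this ordering is not resolvable: the
  map from any causal curve to expected quartile contrasts is nearly
  rank-one (every basis contrast monotone across quartiles), so
  curve shape is smoothed away by the 57% recorded zeros and the
  exposure noise — a genuine limitation of quartiled-fitted-value
  designs at ~0.1% instrument strength, worth keeping in mind when
  interpreting such analyses on real data.

## What the generator does not emulate

No LD among the five instruments (the final published set is
effectively independent; LD appears only in screening fixtures), no
assay error structure, no longitudinal visit process beyond the
visit-4 attendance flag, no population stratification in the default
cohort (PCs are standard normals unless computed from a supplied
panel). Passing tests therefore certify the estimator's statistical
behaviour under the assumed structure, not robustness to violations
of it.

## Numerical and policy choices

Problem sizes in the test suite and acceptance script (replicate
counts 200–4,000; cohorts of 2,000–20,000) were chosen to give each
check Monte-Carlo resolution well inside its tolerance. Determinism:
every stochastic routine takes a seed; replicate seeds are spawned
from a single root via a PCG64 integer stream kept below 2³¹.
Degenerate inputs (constant dosages, all-equal fitted values, empty
quartiles, rank-deficient designs) raise typed errors naming the
offending columns rather than producing numbers.
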