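# Methods

This note documents the models implemented in `echosic`, the default
parameters, the synthetic-data generators used to exercise them, and the
numerical and design choices made where more than one reasonable option
existed.

## The texture score

The high-spectrum signal intensity coefficient summarises the upper half
of the intensity histogram of a region of interest (ROI) placed at the
myocardial–pericardial interface of an 8-bit parasternal long-axis still
frame:

```
HS-SIC = Σ_{n ∈ {50,60,70,80,90}} (1 − p(n)/256)
```

with `p(n)` the n-th intensity percentile of the ROI pixel multiset.
Numerical conventions:

* **Percentile estimator.** Linear interpolation between order statistics
  (Hyndman–Fan type 7), the default of mainstream numerical libraries; it
  is continuous in the data. Other estimators (e.g. `"lower"` for a
  nearest-rank-style variant) are selectable through the `method`
  argument for sensitivity analysis, since the estimator used by the
  original interactive workflow is not standardised.
* **Divisor 256.** Taken literally from the score definition (not 255).
  Consequence: the score never reaches 0; with five levels its exact
  range is `[5/256, 5]`, attained at an all-255 and an all-0 ROI
  respectively.
* **Pixel membership.** A pixel belongs to an ROI iff its *center* lies
  inside: rectangles are half-open on their far edges
  (`[r0,r1) × [c0,c1)`), polygons use the even–odd (ray-crossing) rule.
  This is unambiguous and area-consistent; boundary pixels follow the
  stated tie-breaks deterministically.
* **Bit depth.** Frames wider than 8 bits are min–max rescaled to 0–255
  with a logged warning. Rescaling preserves intensity ordering, which is
  all the percentile statistic consumes. Multi-frame DICOMs require an
  explicit frame index — there is no silent default, because frame choice
  (end-diastole) is a clinical decision upstream of this package.
* **Gain sensitivity.** Adding a constant `c` to all pixels (absent
  clipping) changes the score by exactly `−5c/256`; the shift-property
  test quantifies this. No gain normalisation is attempted: the score is
  a post-acquisition measure and harmonisation across vendors/settings is
  out of scope.

ROI coordinates are always supplied explicitly (manifest CSV); automatic
pericardium detection is a non-goal.

## Synthetic images

`synth_echo_image` emulates the imaging substrate only as far as the
texture engine cares: a darker/brighter horizontal "pericardial band"
inside a speckled background. Speckle is multiplicative Rayleigh noise —
the first-order model of fully developed ultrasound speckle — normalised
to a unit-mean multiplier. Because pixel values are clipped to [0,255]
and quantised, the pre-clip region mean is calibrated (closed-form
Rayleigh partial expectation inverted with Brent's method) so that the
*observed* pixel mean matches the configured target; a target of 255 is
treated as a saturated band. What the generator deliberately does *not*
reproduce: anatomical structure, depth-dependent attenuation, vendor
post-processing, cine motion. Passing round-trip tests therefore show
that the scoring chain is faithful to band brightness under realistic
speckle noise — not that the score is clinically valid on real frames.

`synth_image_cohort_link` inverts the score formula per subject,
`band_mean = 256·(1 − hs_sic/5)`, so re-scoring the emitted frames
approximately recovers the cohort's HS-SIC column (rank correlation
> 0.99 at default noise in practice).

## Synthetic cohorts

`synth_cohort` draws one row per subject:

1. **Sex**: Bernoulli, P(woman) = 0.56.
2. **Covariates**: independent given sex, with sex-specific means/SDs and
   prevalences taken from the emulated community cohort's clinical
   characteristics (age ≈ 65.7 ± 8.8 y, BMI 27.6/28.7 kg/m², SBP ≈ 128
   mm Hg, TC/HDL 3.27/3.74, diabetes 8.6%/15%, anti-hypertensive
   treatment 41%/49%, LVEF 69%/66%, E/e′ 7.37/6.49, women/men). RWT uses
   means 0.40/0.42 with SD 0.0634 — the SD that anchors the per-SD unit
   of all RWT hazard ratios. Independence given sex is the simplest
   structure that keeps sex-stratified analyses non-degenerate; real
   risk-factor correlations are not modelled, so multivariable-adjusted
   estimates on synthetic data are less attenuated than they would be on
   real data.
3. **HS-SIC**: intercept 2.5 plus per-SD coefficients on the standardised
   continuous covariates and per-category coefficients on binaries
   (female −0.43, age 0.16, BMI 0.34, TC/HDL 0.15, SBP 0.04, anti-HTN
   0.21, diabetes 0.40, smoking 0.03, LVEF −0.01, E/e′ 0.02), plus
   Gaussian noise with SD 0.7 — giving a mid-scale score with SD ≈ 0.86.
   Scores are clipped to `[5/256, 5]` and the clip count is recorded in
   the companion truth file.
4. **Event times**: Weibull proportional hazards (shape 1, i.e.
   exponential, chosen for closed-form inversion sampling) with a
   sex-specific per-SD log hazard ratio for HS-SIC (women log 1.67, men
   log 1.16) and RWT (women log 1.17, men log 1.55), plus covariate
   effects (age 0.5/SD, BMI 0.2, SBP 0.2, TC/HDL 0.1, diabetes 0.5,
   smoking 0.3, anti-HTN 0.4, male sex 0.69 — the sex effect sized so
   ~60% of events occur in men). The *baseline* Weibull scale is not a
   free parameter: it is solved by root finding so that the expected
   observed-event fraction equals the target (94/2511 ≈ 3.74% by
   default) under the drawn censoring horizons; an unreachable target
   raises with the achievable range.
5. **Censoring**: administrative, per-subject horizons Normal(7.4, 1.7)
   years floored at 0.5 — matching the follow-up mean ± SD without
   modelling dropout.

Exposure effects are applied to the *sample-standardised* score, so a
per-SD Cox fit on the standardised column estimates the configured
coefficient directly. The companion `SimTruth` object round-trips the
exact parameters and the uncensored event times through JSON.

`synth_mediation_cohort` provides a minimal exposure → mediator → binary
outcome chain with a known decomposition (defaults mirror a diabetes-like
exposure with mediated fraction `a·b/(c′+a·b) ≈ 0.10` on the
event-probability scale).

## Cross-sectional models

Continuous variables are normalised by their sample SD (n−1 denominator);
binary predictors enter 0/1, because per-category effects are the natural
scale for treatment/diagnosis indicators. The "1 SD" unit is always the
overall analysis-sample SD, including inside sex strata, so estimates
share a unit across all tables; an `sd_anchor` argument overrides it.
Associations are ordinary least squares with Wald inference; the
risk-factor table adjusts every predictor for age and sex, except that
the sex row is adjusted for age only and the age row for sex only, and
sex is dropped from stratified models. Missing data are handled by
complete-case analysis with a logged exclusion count. LVEF and E/e′
per-SD estimates can be reported per unit instead via `per_sd=False`,
since small printed per-SD values for these variables are consistent with
per-unit scaling.

## Survival models

The Cox ladder: model 0 — exposure alone; model 1 — + sex; model 2 —
+ anti-hypertensive treatment; model 3 — + BMI, SBP, diabetes, smoking,
TC/HDL. Age never enters as a covariate: it fails the proportional-
hazards assumption, so models 1–3 stratify the baseline hazard by age
quartile (sample quartiles, linear-interpolation cut points, boundary
ties to the lower stratum). Model 0 is genuinely "alone" — no strata.
Ties use the Efron approximation (standard for moderately tied
community-cohort data); confidence intervals are Wald on the log-HR
scale. Sex interaction is the Wald test of the `exposure × sex` term in
the pooled model. Rank-deficient designs, event-free subsets and
non-convergence raise or are flagged — never silent.

**Proportional hazards.** The Grambsch–Therneau test is assembled from
lifelines' scaled Schoenfeld residuals: with centred transformed event
times `g_k`, residual matrix `s*`, event count `d` and coefficient
covariance `V`, the statistic is `u'(d·Σg²·V)⁻¹u` with `u = Σ g_k s*_k`
(per-covariate: the diagonal version, 1 df). The time transform is the
identity by default, with rank, log and KM transforms available. The
per-covariate statistic reproduces lifelines'
`proportional_hazard_test` to numerical precision (cross-checked in the
suite); the global statistic follows the same construction with the full
covariance.

**Non-linearity.** Restricted cubic splines in Harrell's truncated-power
form, normalised by `(t_k − t_1)²`, linear beyond the boundary knots;
default 4 knots at the (0.05, 0.35, 0.65, 0.95) exposure quantiles. The
test is a likelihood-ratio chi-square with k−2 df of the spline Cox model
against the linear one.

**Cumulative incidence.** Kaplan–Meier complements (1 − S(t)) comparing
the top fourth of the exposure with the lower three-fourths, pooled or by
sex. With no competing-risk adjustment — competing risks, time-varying
covariates and HF-subtype analyses are out of scope.

## Mediation

Standardised-coefficient product-of-coefficients decomposition. The
mediator model regresses the (standardised) mediator on exposure +
covariates (slope `a`); the outcome model regresses the binary HF
indicator on exposure + mediator + covariates on the **linear-probability
scale** (slopes `c′` and `b`). Indirect = `a·b`, total = `c′ + a·b`,
which equals the reduced-model exposure coefficient *exactly* — the
linear scale is the package default precisely because it yields this
additive identity; an Aalen additive-hazard outcome backend is provided
for sensitivity analysis (effects are average hazard increments per year;
additivity is then only approximate). Proportion mediated =
indirect/total, flagged as "inconsistent mediation" when the two effects
have opposite signs.

Inference: delta-method (Sobel) SEs by default; a seeded percentile
bootstrap (2,000 reps by default) is available and agrees with the delta
method within ~20% at n ≥ 5,000 under the default generator. A known
property of the Sobel test worth stating: under the *joint* null
(`a = 0` and `b = 0`, e.g. a permuted mediator) the product statistic is
not asymptotically normal and the test is severely conservative
(rejection rate near 0); under a single-path null (`a ≠ 0, b = 0`) it is
calibrated at the nominal level. The test suite checks both behaviours.
The default adjustment set for the mediation table is "all other listed
risk factors"; an age+sex-only scheme is selectable. Causal-inference
extensions (exposure–mediator interactions, sensitivity to unmeasured
confounding, natural effects on the hazard scale) are out of scope.

## Pipeline and reproducibility

One master seed is fanned out to the stages through
`SeedSequence.spawn` in fixed order, so a config + seed determines every
output byte. Each output CSV carries a `# config_hash:` header (hash of
the analysis-relevant config, output paths excluded) and a `run_log.json`
archives seeds and library versions. Stages communicate through plain
CSV so intermediate products are inspectable.

## Problem sizes used in the test suite

Simulation-backed checks use sizes chosen to balance statistical
resolution against run time: marginal/event-fraction calibration at the
default n = 2,511; parameter-recovery fits at n = 50,000 (2-SE bands);
CI-coverage over 200 replicates of the default cohort; null calibration
of the Schoenfeld and spline diagnostics over 500 replicates at n = 500
(~380 events each, where the asymptotic reference distributions are
adequate); power checks for constructed violations at n = 6,000–20,000.

## Known limitations

* Covariates are independent given sex in the generator; real risk-factor
  correlation structures (and familial clustering) are not emulated.
* The linear-probability outcome model can in principle predict outside
  [0,1]; at the low event rates modelled here this is immaterial, but the
  additive-hazard backend exists for exactly this concern.
* The Wald CI coverage of sex-specific hazard ratios runs slightly below
  nominal (~0.92–0.95 observed) at ~37 events per stratum — the usual
  small-event-count behaviour of partial-likelihood asymptotics.
* The texture engine treats the supplied still frame and ROI as ground
  truth; frame selection and ROI placement quality are upstream concerns.
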