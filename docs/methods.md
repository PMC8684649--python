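# Methods

This note documents the statistical procedures, the synthetic-data model
and the design decisions behind `munophen`, in the order the pipeline runs
them.

## Cohort model and eligibility

A cohort is one row per patient with canonical units fixed once: height in
metres, waist circumference (WC) in centimetres, labs (FPG, TG, HDL-C,
LDL-C, TC) in mmol/L, pre-dialysis blood pressure in mmHg (the stored
SBP/DBP pair is understood as the average of repeated pre-dialysis
readings; averaging is the data provider's job). WC is kept in centimetres
everywhere and converted to metres only inside the ABSI formula — a single
canonical unit prevents silent 100× errors.

Eligibility for analysis requires dialysis vintage strictly greater than
3 months, BMI < 25 kg/m² (the boundary value 25.0 is excluded) and complete
mandatory analysis fields (complete-case analysis; LDL-C and TC are
optional). A record failing several rules is counted once under the first
matching rule in the fixed order *vintage → BMI → missing data*, so
exclusion reports are reproducible. Records with missing covariates never
enter any model silently; the exclusion count is part of the run manifest.

## Adiposity indices

The seven indices use the published sex-specific constants (LAP anchors
65/58 cm; the VAI ratio constants; the CVAI linear coefficients; ABSI's
BMI^(2/3)·height^(1/2) denominator). Two transcription notes:

* The male CVAI BMI coefficient is 0.03 — far smaller than the female 4.23.
  This is the printed value of the source formula and is implemented
  literally; the asymmetry is flagged here rather than silently
  "corrected".
* LAP is negative when WC is at or below the sex anchor. No truncation rule
  exists in the source, so the value is retained as-is and the per-cohort
  count of nonpositive LAP values is logged. Downstream quartile and ROC
  analyses are rank-based and unaffected by the sign. Note a consequence:
  LAP is strictly increasing in TG only above the anchor; below it, TG
  scales a negative quantity downward.

All computation is in double precision; rounding (2 decimals) happens only
in the presentation layer of the pipeline outputs.

## Phenotype rule

The four metabolic-syndrome components are evaluated with inclusive ≥
thresholds for SBP (130), DBP (85), TG (1.7) and FPG (5.6), and strict <
for HDL-C (1.0 men / 1.3 women). Medication flags are sufficient for their
component regardless of the measured value: antihypertensives for BP,
lipid-lowering drugs for the HDL component (not the TG component — the rule
attaches treatment to HDL only), antidiabetics for FPG. MUNO requires BMI
< 25 and component count ≥ 2 (2 inclusive); BMI ≥ 25 is outside the
phenotype's domain and labelled `not_applicable`.

## Descriptive comparisons

Skewed continuous variables are summarised as median (Q1, Q3) using linear
interpolation between order statistics — the common default in scientific
software; the estimator is isolated in one function and shared with the
quartile cutpoints, so binning and descriptives can never drift apart.

The Mann–Whitney U test reports U under the min convention. When both
groups have fewer than 8 observations the two-sided p comes from exact
enumeration of the permutation null of the midrank U statistic (tie-aware;
the null is symmetric, so the two-sided p is the probability of |U − mean|
at least as extreme). Otherwise the continuity-corrected normal
approximation with tie correction is used. The exact path exists because
the normal approximation is genuinely poor for tiny, heavily tied samples;
fully degenerate input (every value identical) returns p = 1 by contract.
Chi-square tests are Pearson without Yates continuity correction
(documented choice; the source does not state one), with zero marginals
rejected.

## Quartile logistic regression

Each index is cut at its cohort quartiles with intervals
(−∞, q25], (q25, q50], (q50, q75], (q75, ∞); a value exactly at a cutpoint
falls in the lower bin. The lowest quartile is the reference. The binary
phenotype is regressed on the three upper-quartile indicators plus
covariates (age in years, male sex, education ≥ junior high, smoking
history — matching the binary presentation of those covariates), pooled
across sexes with sex as a covariate; only the ROC analysis is
sex-stratified.

The fitter is maximum likelihood via IRLS: Newton steps on the observed
information, convergence when the largest absolute coefficient change is
below 1e-8, at most 100 iterations, weights floored at 1e-10 for numerical
safety. The per-iteration log-likelihood history is exposed so monotone
ascent is verifiable. Rank-deficient designs (constant or collinear
predictors) and one-class outcomes are hard errors; quasi-separation is
flagged (non-convergence or any SE > 100 on the log-odds scale) and
propagated into the output rows rather than silently reported.
Confidence intervals are Wald (exp(β ± 1.96·SE)) — the common epidemiology
output; profile-likelihood intervals are out of scope.

## ROC, Youden and DeLong

ROC curves are empirical staircases with one vertex per distinct score
(ties grouped), oriented so that a higher index predicts MUNO — all seven
indices increase with adiposity/metabolic burden. The trapezoidal AUC
equals the Mann–Whitney pair probability (#concordant + ½·#tied)/(n₁·n₀)
exactly; the suite asserts this identity against exhaustive enumeration.

Youden-optimal cutoffs scan the observed distinct values with the rule
"positive if score ≥ cutoff" and maximise J = sensitivity + specificity −
1. Ties in J — including floating-point near-ties within 1e-12 — are broken
toward the smallest cutoff, making results reproducible across platforms.
Candidate cutoffs are observed values, not midpoints (unambiguous and
sufficient for rank-based J).

AUC uncertainty uses DeLong's placement-value covariance: each positive
subject contributes the fraction of negatives it outscores (ties half),
each negative the complement; the empirical covariance of these placements
gives Var(AUC) and, for two indices scored on the same subjects, the
paired variance Var(AUC_A − AUC_B) = S_AA + S_BB − 2·S_AB with class-size
scaling. Z = ΔAUC/√Var is signed first-minus-second and p-values are
two-sided normal. The 95% AUC CI is normal-theory on the DeLong SE,
clipped to [0, 1]. Degenerate zero variance is flagged: identical
placements give Z = 0, p = 1 (self-comparison contract), while zero
variance with a real AUC gap (perfect separation both ways) gives p → 0.
The default comparison list is the nine index pairs whose CIs overlapped
in the motivating study design (BMI–WC, BMI–WHtR, BMI–ABSI, WC–WHtR,
WC–ABSI, WC–CVAI, WHtR–CVAI, WHtR–ABSI, LAP–VAI).

## Synthetic cohort generator

The generator emulates a nonobese hemodialysis population as a
two-component mixture. Each subject is *destined* MHNO or MUNO, then the
eleven coupled variables (age, SBP, DBP, WC, BMI, FPG, TG, HDL, LDL, TC,
vintage) are drawn from group-specific marginals through a shared Gaussian
copula. Marginals are lognormal parameterised by target (median, Q1, Q3) —
the simplest positive, right-skewed family reproducing median/IQR
summaries — with a support shift for blood pressure (60/30 mmHg) so its
skew stays mild. The default group targets are medians/IQRs of the kind
reported for MHNO and MUNO hemodialysis patients (e.g. TG 1.05 (0.81,
1.33) vs 1.62 (1.10, 2.31) mmol/L); vintage (median 48, IQR 24–84 months)
and heights (normal, 1.66 ± 0.06 m men, 1.55 ± 0.06 m women, truncated to
1.40–1.95) are author-chosen realistic values. Weight is derived from the
drawn BMI and height. Ages are integerized and clipped to 18–90; vintage is
clipped to at most 600 months so every record satisfies the data-model
bounds.

Latent correlations (WC–BMI 0.8, SBP–DBP 0.6, TG–HDL −0.4, LDL–TC 0.7,
moderate positive couplings of WC/BMI/TG/FPG, …) are stated modelling
assumptions, not estimates; the matrix is checked for positive
definiteness. Medication flags follow logistic links to the latent z of
their lab (antihypertensives ← SBP, antidiabetics ← FPG, lipid-lowering ←
TG) around group-specific base rates, so treated subjects have plausibly
worse labs. HDL gets a multiplicative sex factor (men ×0.94, women ×1.10,
preserving the pooled median at the default 60.3% male mix) so the
sex-specific HDL thresholds of the phenotype rule behave sensibly.

The *realized* phenotype of a generated subject is whatever the
classification rule says about its drawn values. The prevalence knob
(default 65.6%) is honoured by an internal seeded pilot calibration: the
generator draws a pilot block per destined group, measures each group's
eligibility fraction (BMI < 25) and realized MUNO rate among the eligible,
and solves the destined mixing fraction from the eligibility-weighted
mixture equation. The eligibility weights matter: destined-MUNO subjects
have higher BMI and are preferentially excluded, and ignoring that biases
the realized prevalence low by about two points. Everything is driven by
one `numpy` SeedSequence, so cohorts are bit-reproducible given
(config, seed).

Separability scenarios replace group-conditional marginals by pooled ones
and instead shift the latent components feeding a designated dominant
index by ±δ/2 between outcome-positive and outcome-negative subjects (for
VAI: TG up, HDL down, WC/BMI/FPG/BP mildly up, height slightly down; each
index has its own profile designed so it wins by construction). The
scenario outcome is the assigned label itself, so zero shift is an exact
null (all AUCs ≈ 0.5) and the strength parameter scales the whole profile.

### What the generator does and does not show

The generator reproduces marginal location/spread, plausible rank
correlations, medication–lab coupling and a tunable phenotype prevalence.
It does **not** reproduce the unknown true inter-variable correlations of
any real dialysis cohort, measurement error structure, within-centre
clustering, or longitudinal dynamics — so passing tests demonstrate the
*machinery* (formulas, rules, estimators, orderings recover known
structure), not clinical effect sizes. Published AUC/OR magnitudes from
real cohorts are not reproduction targets; only qualitative structure
(e.g. VAI ranked first when VAI is constructed dominant) is.

## Problem sizes

Default analysis cohorts are n = 1302 with a 4000-subject calibration
pilot; calibration checks use n = 5000, separability scenarios n = 4000,
oracle-equivalence checks 500 random small instances (n ≤ 12), DeLong
bootstrap comparison 10,000 replicates at n = 30, and the null-coverage
simulation 200 replicates of n = 2000 — sizes at which sampling error is
well below the tolerances being asserted while the whole suite runs in
seconds.

## Known limitations

* Wald CIs can misbehave under near-separation; such rows carry an explicit
  flag instead of a corrected estimate (no Firth penalisation).
* The exact Mann–Whitney path enumerates all assignments and is used only
  below 8 observations per group.
* The DeLong AUC CI is normal-theory and can be anti-conservative for AUCs
  near 1 with small samples.
* The quantile estimator (linear interpolation) is a documented choice;
  published cutpoints computed with a different estimator can be supplied
  explicitly to the binning function.
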