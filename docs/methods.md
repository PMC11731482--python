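# Methods

This note documents the models implemented in `lipidtraj`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer should know about.

## Study design being emulated

The pipeline reproduces a retrospective case-control design: subjects with at
least three annual serum-lipid measurements in distinct years during the 11
years up to an index year (year of first cognitive symptom for cases, the
propensity-match age for controls).  All time is expressed on a relative-year
axis −10…0 with 0 the index year.  Total cholesterol, HDL-C, LDL-C, non-HDL-C
and ln(triglycerides) are analysed per cohort; cholesterol-lowering medication
use enters as a time-varying covariate and a matching criterion, but lipid
values are never adjusted for it.

## Derived variables

* **Medication use at year t**: active iff a qualifying order
  (Sent/Dispensed/Verified) exists at or before t and the latest such order is
  not superseded by a strictly earlier discontinuation — equivalently, a
  discontinuation is ignored when another qualifying order was placed at or
  after it.  This single rule reproduces both the "not Discontinued" and the
  "unless replaced" clauses and is idempotent and order-insensitive.
* **Lipid algebra**: non-HDL-C = TC − HDL-C identically; LDL-C is the recorded
  value when present, else Friedewald TC − HDL-C − TG/5 with the standard
  TG ≤ 400 mg/dl validity bound (missing, not an error, beyond it);
  triglycerides use the natural log.  Same-year duplicate measurements are
  averaged on the raw scale before any transformation, preserving the annual
  semantics of the design.
* **ICD comorbidity flags**: dot-stripped string-prefix matching against the
  versioned lists in `lipidtraj/data/icd_codes.txt`; printed ranges are
  expanded at load time.  A code can flag several conditions (I25- is both
  atherosclerosis and ischemic heart disease).
* **Scores**: polygenic-score columns are standardized to mean 0, sample SD 1
  within each cohort, so effect sizes are per-SD.

## Group-based trajectory models

A subject's lipid series is modelled as a finite mixture over latent groups g
with polynomial mean curves in scaled time s = t/10 ∈ [−1, 0] (the constant
term is therefore the year-0 mean, and bases up to s⁴ stay well conditioned):

  y_it | g ~ CensoredNormal( Σ_k β_gk s^k + α_g·med_it , σ ),  P(g) = π_g.

The observation model is a tobit: interior values get the normal density,
values at or beyond a censoring bound get the corresponding tail mass.
Subjects contribute the product of their observed years only, so gappy,
unequal schedules are handled naturally.

Estimation is EM.  The E-step computes subject-level posteriors; the M-step is
weighted least squares per group plus a pooled residual variance — the exact
maximizer when no observation is censored.  When censored observations are
present the M-step refines the WLS candidate with a warm-started quasi-Newton
pass on the complete-data objective and keeps whichever parameter set
(previous, WLS, refined) has the best objective, so the marginal
log-likelihood is non-decreasing (generalized EM) in all cases.

Choices, with rationale:

* **Residual σ shared across groups** (the common plug-in default for
  latent-class growth models).
* **Censoring bounds** default to the data range padded outward by 10⁻⁶ of the
  range, making censoring inert unless bounds are configured explicitly; an
  exact user-supplied bound treats boundary values as censored, per the tobit
  contract.
* **Starts**: one deterministic start from 1-D k-means on subject mean levels
  plus random restarts seeded by randomly chosen subject means (10 by
  default).  Pure quantile seeding was found to miss small groups (a 15%-share
  high-HDL group is invisible to the 5/6 quantile of subject means).
* **Convergence**: relative log-likelihood change ≤ 1e-6, 500 max iterations;
  non-convergence is flagged on the returned fit, never silent.
* **Diagnostics**: APP_g is the mean posterior among modally assigned
  subjects; OCC_g = [APP_g/(1−APP_g)] / [π_g/(1−π_g)] with a +∞ sentinel at
  APP = 1.  A fit is admissible iff every group has APP ≥ 0.85, OCC ≥ 5 and at
  least 5% of the cohort.
* **Sweep**: equal polynomial order across groups over the requested grid
  first; the best-BIC admissible fit then gets one pass of per-group order
  refinement.  BIC uses the number of subjects.  If nothing is admissible the
  sweep reports "no admissible model" and the pipeline omits trajectory-group
  covariates downstream instead of failing.
* **Label switching** is resolved by sorting groups on the fitted year-0 mean
  (group 1 = lowest), so group numbers are stable and comparable.

## Variability independent of the mean

For each lipid, per-subject mean and SD over the same annual values used for
the trajectory models give

  x = OLS slope of ln SD_i on ln mean_i  (subjects with SD > 0),
  VIM_i = k · SD_i / mean_i^x,  k = (grand mean of subject means)^x.

VIM carries the units of the SD and is, by construction of x,
decorrelated from the subject mean in-sample; this defining property is what
the acceptance checks verify on heteroscedastic synthetic data.  Quintiles cut
at the sample 20/40/60/80 percentiles with ties broken by stable subject-id
rank, so label counts differ by at most one (quintile 1 = least variability).
Degenerate inputs: all-equal means yield x = 0 with a warning; SD = 0 maps to
VIM = 0; all-equal VIM values refuse quintile assignment.

## Propensity matching

Within exact strata (sex, age group with the published cutpoints, BMI group,
medication use), cases are processed in descending propensity score and each
greedily takes up to `ratio` nearest unmatched controls on the propensity
logit (optionally within a caliper), without replacement.  The propensity
model is a case-vs-control logistic on the nearest variables; perfect
separation falls back to an L2-penalized fit and is flagged.  Weights follow
the ATT convention: cases 1, the controls of a set sharing 1 in total.
Default maximum ratio 4, reflecting control:case ratios of roughly 2–4 in the
emulated cohorts.  Cases whose stratum has no control are reported unmatched
and the run continues.

One deliberate deviation: matched-set ATT weights are *not* placed in the risk
models' covariate sets by default.  With variable-ratio sets the weight is
exactly 1 for every case and below 1 for controls, so as a covariate it
identifies case status and inflates in-sample AUROC (~0.98 in synthetic
cohorts).  The flag `include_weight_covariate` restores the
weights-as-covariate convention for users who match with a fixed ratio.

## Longitudinal mixed models

Per lipid: a linear mixed model with subject random intercept and random slope
on age, unstructured 2×2 covariance, maximum likelihood.  Wald confidence
intervals; AIC counts fixed effects, the three covariance parameters and the
residual variance.  A singular random-effects covariance triggers a flagged
refit with diagonal structure.  Model reduction is AIC backward selection:
repeatedly drop the single candidate whose removal most lowers AIC, never
dropping locked terms (e.g. genetic principal components), with the full
elimination trace retained.  Complete-case analysis for covariates.

## Risk models

Logistic ML fits (IRLS/Newton to tight tolerance, so a saturated binary
predictor reproduces the 2×2 cross-product odds ratio to ~1e-12).  The
covariance is a cluster sandwich: bread (X'WX)⁻¹, meat the sum of within-set
score outer products, with *no* small-sample degrees-of-freedom correction —
so with singleton clusters it equals HC0 exactly, a useful definitional
identity.  ORs and CIs come from the robust SEs.

Diagnostics: Hosmer–Lemeshow on deciles of risk (duplicate quantile edges
merged; df = groups − 2) and a specification link test (refit on the linear
predictor and its square; pass iff the squared term is non-significant at
0.05; separation is flagged, not failed).

AUROC comparison follows the correlated-curves approach: AUCs via the
midrank Mann–Whitney statistic, the DeLong structural-component covariance,
a global equality χ² on successive-difference contrasts (df = contrast rank;
a self-comparison yields P = 1), and Bonferroni-adjusted pairwise P values.
Nested covariate sets (base; +lipid groups; +genetics; +both) are compared on
the same subjects.

Predictive margins fix grid covariates and either average predictions over the
sample or predict at design-matrix means; CIs are delta-method under the
cluster-robust covariance, clamped to [0, 1].

## Synthetic cohorts

The generator emulates: an 11-year window with per-year Bernoulli visits
(default probability 0.6, resampled until ≥3 distinct years — matching the
observed 3–11 measurements and ~60% of subjects measured per year); latent
per-lipid trajectory groups with polynomial curves and additive medication
effects; a medication-order table with start, discontinuation and replacement
events interpreted by the same rule the derivations module applies; subject
residual SDs proportional to a power x of the subject mean (lognormal
dispersion), giving the VIM machinery a true exponent; demographics,
education, race, APOE allele counts, comorbidity flags and standardized score
columns with realistic prevalences; and case status from a configurable
logistic model (defaults: log-OR 1.0 and 1.3 for the two lower HDL-C groups
relative to the highest, 0.9 for the lowest TC-VIM quintile, plus age,
education, cerebrovascular and score terms; intercept −2 for ≈30% prevalence,
a case-control mix rather than a population rate).  Group mean levels are
illustrative three-level configurations, not estimates from any cohort.
Each lipid's own score column shifts that lipid's level (e.g. 2.5 mg/dl per
SD for HDL-C), reproducing the score-specificity pattern the mixed models
should find.

Not emulated: calendar-date granularity below one year, genotype or ICD-code
streams (flags are drawn directly), adherence dynamics, informative visit
schedules, and any correlation between lipids beyond what the shared
medication process induces.  Consequently, passing parameter-recovery tests
shows the estimators are correct under the assumed data-generating process;
it does not certify behaviour under real-EHR pathologies such as informative
missingness.

Two purpose-built configurations define validation conditions used by the
tests and the acceptance script:

* the *three-group recovery cohort* (400 subjects; flat HDL-C groups at
  40/55/85 mg/dl, shares 0.45/0.40/0.15, residual SD 4 and no additional
  between-subject heterogeneity — exactly the stated mixture law);
* the *VIM validation cohort* (one flat TC trajectory, no medication, full
  visit schedule, wide between-subject spread), on which SD_i
  = c·mean_i^0.8·noise holds exactly.  Under the default cohort, medication
  shifts and secular trends add within-subject variance unrelated to the mean,
  which attenuates the fitted exponent — a property of such data, not an
  estimator defect.

## Problem sizes

Defaults were chosen so the whole validation suite runs comfortably on a
single CPU: 400 subjects for trajectory recovery, 500 for the VIM property,
100 replicates of 700 subjects for odds-ratio coverage and AUROC nesting, and
1000 replicates of 200 observations for the AUROC-equality test level.  These
sizes give binomial Monte-Carlo error small enough for the stated bounds
(e.g. coverage checked against ≥90/100).

## Known limitations

* The censored-normal M-step refinement is quasi-Newton with a bounded
  iteration budget; heavily censored data may need more starts.
* Greedy nearest-neighbour matching is order-dependent by construction; the
  descending-PS case order makes it deterministic but not optimal.
* The mixed-model engine fits by numerical ML; with nearly singular random
  effects the diagonal fallback changes the parameter count (reflected in
  AIC).
* VIM exponent estimation assumes subject SDs estimated from ≥3 visits;
  with few visits the sampling noise of the SD dominates and correlations
  against the mean are attenuated.
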