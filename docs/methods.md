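# Methods

## The model

The pipeline estimates absolute risk of pancreatic ductal adenocarcinoma
(PDAC) from the moment a diabetes patient's glycemic control worsens. The
core model is a Cox proportional-hazards regression on time from a
progression index date to incident PDAC, with two kinds of covariate
effects:

* **Linear effects** for continuous and categorical covariates measured at
  (or in a window before) the index date: age, weight and % weight change,
  peak BMI, HbA1c level and 12-month change, creatinine, cholesterol,
  bilirubin and % change, red-cell count and % change, race, ethnicity,
  smoking and heavy-drinking categories.
* **Decaying indicator effects** for binary history variables (acute and
  chronic pancreatitis, abdominal pain, jaundice, alcoholism, NAFLD, heart
  disease, PPI and statin prescriptions). An indicator first recorded `t`
  months before the index date contributes

      log HR(t) = beta1 * exp(-beta2 * t),        beta2 >= 0,

  to the log hazard: `beta1` is the log hazard ratio of a diagnosis made
  at cohort entry ("current"), and `beta2` (per month) is how quickly the
  association fades with time since diagnosis. `beta2 = 0` recovers an
  ordinary constant effect. The lag is fixed at its index-date value; the
  covariate does not update during follow-up, matching a design in which
  all predictors are assessed on or before cohort entry.

Both effect types are estimated jointly by maximizing the Cox partial
likelihood (Efron tie correction by default; Breslow available for
cross-checks against references that use it).

### Estimation: iterative linearization

The decay parameters make the log hazard nonlinear in `beta2`. Estimation
follows a Gauss–Newton scheme on working covariates: at outer iteration k,
with current rates `beta2`, each decay term is replaced by the two columns

    z1 = I * exp(-beta2 * t)          (carries beta1)
    z2 = -beta1 * I * t * exp(-beta2 * t)   (the beta2 direction)

and an ordinary linear Cox model in (linear covariates, z1, z2) is fully
refit; then `beta1 <- coef(z1)` and `beta2 <- beta2 + coef(z2)`, projected
onto `[0, beta2_max]`. Updates are damped: a step is only accepted at the
largest step fraction (halving from 1) that does not increase the exact
negative log partial likelihood, so the objective is monotone. After the
loop, the solution is polished by bound-constrained L-BFGS-B on the exact
partial likelihood with analytic gradients — the Gauss–Newton iteration
can two-cycle with slowly shrinking amplitude on flat ridges, while the
polish lands on the stationary point (and rescues a loop that exhausts its
iterations). The reported covariance is the inverse observed information
of the full nonlinear model at the solution, with analytic curvature
corrections for the (beta1, beta2) blocks, not the last linearization's
information (which would understate Var(beta2)).

Presentation follows the "current" vs. "3 years in the past" convention:
`hr_at_lag` evaluates HR(t) = exp(beta1*exp(-beta2*t)) with delta-method
intervals from the (beta1, beta2) covariance block. As a consistency
anchor, beta1 = log 7.26 with beta2 solved from HR(36) = 6.63 reproduces
both printed values exactly.

### Numerical safeguards

EMR cohorts contain rare indicators (a handful of carriers, most with
events), which produce flat or monotone likelihood directions. The
safeguards, in the order they engage:

* Newton steps larger than 10 in max-norm are rescaled (trust region);
  a ridge is added to the Hessian until the step is a descent direction.
* Working-fit coefficients in the decay fitter are bounded at |beta| = 15
  (HR ~ 3x10^6): a separated rare indicator pins at the bound with an
  enormous standard error instead of aborting. Plain `fit_linear_cox`
  keeps the strict behaviour and raises a convergence error naming the
  separating covariate.
* A decay rate whose working column separates (non-identifiable from too
  few recent-onset carriers) is fixed at 0 — a constant effect — via a
  restart, recorded in the fit trace; it is then not counted as a free
  parameter in the AIC.
* `beta2` is capped at 1/month by default (the effect would be gone
  within a few months; larger rates concentrate the effect on a vanishing
  subgroup and are clinically meaningless).
* The L-BFGS-B polish declares convergence when the likelihood is flat to
  numerical precision along the remaining (often boundary) directions;
  `final_score_norm` on the fitted object exposes the residual score.

Default tolerances: 1e-8 on the score for linear fits, 1e-7 on parameter
changes for the outer linearization, at most 100 outer iterations.

## Cohorts and covariate windows

Diabetes requires at least two outpatient diabetes diagnoses **and** one
qualifying outpatient lab (HbA1c >= 6.5%, fasting glucose >= 126, random
glucose >= 200); inpatient/ED labs are excluded because acute illness
inflates glucose. First evidence is the earlier of the first diagnosis
and the first qualifying lab; subjects under 50 at first evidence are
excluded. The three progression cohorts overlap (a subject may enter all
three):

* **insulin_init** — date of first insulin prescription;
* **combo_oral** — first day on which two distinct oral hypoglycemic
  classes are prescribed simultaneously after a period on exactly one
  class ("simultaneous" = same calendar day by default; a
  `combo_grace_days` window widens this, as the strict reading is a
  design choice, not a law);
* **hba1c_rise** — first outpatient HbA1c >= 8.0% with a prior value at
  least 1.0 point lower within the preceding 15 months (prior strictly
  before the test, gap <= 457 days; comparisons carry a 1e-9 float
  tolerance so one-decimal assay values behave like decimals).

Progression dates within 90 days of first diabetes evidence are excluded
(apparent progression that soon after diagnosis more likely reflects
late-discovered diabetes). Current labs are the most proximal values in
the 12 months up to the index date; 12-month changes compare the current
test against the prior test closest to 12 months before it within a 3-to-
15-month window (ties broken toward the earlier test). Weight is
plausibility-filtered to 75–500 lbs and height to 48–84 inches before any
use; peak BMI uses the highest valid weight ever recorded before the
index and the latest valid height. A subject with both acute and chronic
pancreatitis is classified as chronic. Rows missing any continuous
covariate are excluded, with a per-covariate report and a warning if the
loss exceeds 10%. All day-to-month conversions use 30.4375 days/month.

## Model selection

Collinearity is reduced first: within any covariate pair with |Pearson r|
above 0.8 (a conventional cutoff; the design gives no number), the member
with the worse univariate AIC is dropped. Stepwise selection then runs in
two stages, because duration parameters are constrained to follow their
indicators rather than compete on AIC:

1. bidirectional stepwise AIC over linear covariates, categorical blocks
   (dummy-encoded against the most frequent level) and indicators as
   constant effects, with deterministic alphabetical tie-breaking — so
   the output is invariant to candidate ordering and bit-reproducible;
2. the decay rate of every retained decay-eligible indicator is freed and
   the model refit by iterative linearization, **regardless** of whether
   the AIC improves.

Age is forced into every model: it is a universal risk factor here and
guards against null-model pathologies in small cohorts. Models are
developed separately per sex; at desk scale the simulated female stratum
(~7% of subjects, mirroring a predominantly male patient population) is
too small to support
selection, so the study driver develops models on the male subset and
includes both sexes in the incidence descriptives.

## Validation

Absolute risk at horizon h is 1 − S0(h)^exp(lp − lp̄) with S0 the Breslow
baseline survival centered at the training-mean linear predictor.
Discrimination is the cumulative/dynamic time-dependent AUC: cases are
subjects with events by the horizon, controls those still under
observation beyond it, and case contributions are weighted by 1/G(T−)
where G is the reverse Kaplan–Meier censoring survival (the constant
control weight cancels). The AUC variance is a first-order U-statistic
(DeLong-type) approximation that treats the censoring weights as fixed —
adequate for the moderate censoring simulated here, slightly anticonservative
under heavy censoring. Calibration slope is the coefficient of the linear
predictor refit as the sole covariate; on the training data of an interior
converged fit it equals 1 by the score equation (boundary-pinned or
frozen-rate fits can deviate slightly, which the reports show honestly).

Optimism correction follows Harrell's bootstrap: B resamples (default
200, midpoint of the conventional 100–300 range), each rerun through the
modelling pipeline, scored on the resample and on the original data; the
mean gap is subtracted from apparent performance. Two modes exist and are
labelled in every report: `selection` reruns screening + stepwise +
decay refitting per replicate (the honest variant), `refit` refits only
the selected model's coefficients (fast; used by the study driver for
runtime). Replicates in which a resample makes a covariate degenerate
(no carriers) or separable (all carriers with events) drop that covariate
for that replicate; replicate failures beyond 10% abort. Replicate RNG
streams derive from the master seed by fixed offsets, so all results are
reproducible bit-for-bit.

Threshold operating characteristics classify test-positive as predicted
risk at or above an absolute threshold (0.5%, 1%, 2% at the real event
scale); outcome-positive is an observed event by the horizon, outcome-
negative survival beyond it. Subjects censored before the horizon without
an event are excluded from classification by default — how such subjects
should count is genuinely ambiguous — and an IPCW-weighted variant is
available behind a flag for sensitivity analysis (its intervals use an
effective sample size). Intervals are Clopper–Pearson exact binomial. A
threshold of 0 is accepted as the degenerate flag-everyone limit.

## Incidence

Median follow-up is the median of the Kaplan–Meier curve of the censoring
distribution (reverse Kaplan–Meier), reported as "> max" when not
reached. Cumulative incidence standardized to age 60 comes from a Cox fit
with age as the sole covariate: 1 − exp(−H0(τ)·exp(β·(60 − mean age))),
i.e. model-based standardization at the reference age rather than
stratified direct standardization (the model-based form is the natural
choice with a single continuous standardization variable). Intervals
combine the Breslow baseline variance (Σ d/S²) with the delta-method age
term on the log cumulative hazard scale; the baseline–coefficient
covariance is ignored, as it vanishes at the mean age. Death is treated
as censoring (last-known-vital-status), not as a competing risk.

## What the synthetic EMR emulates — and what it does not

The generator plants exactly the structures the cohort builder looks for:
duplicated outpatient diabetes codes plus a qualifying lab, decoy subjects
who fail each arm of the diabetes definition, insulin starts, same-day
combination starts after monotherapy, HbA1c rises with in-window priors,
early-progression subjects caught by the 90-day rule, condition onsets
with exponential lags, lab panels with ~12-month priors, implausible
vitals, and a small (1%/analyte) missingness rate yielding ~5–7%
complete-case loss. Ground truth (membership, index dates, linear
predictors, outcomes) is emitted as a side table so round-trip tests never
re-derive it from the generator's internals. Default effect sizes are the
male insulin-initiation multivariable estimates (e.g. acute pancreatitis
HR 7.26 current / 6.63 at three years; 20-point weight gain HR 0.56);
default covariate locations are the published cohort medians; the Weibull
baseline (shape 1) is calibrated so the uninflated 12-month cumulative
incidence at the covariate centers is 0.18%. Administrative censoring
defaults to 84 months with a small per-month dropout hazard, giving
median follow-ups in the 7-year range.

Real PDAC is rare (~0.1–0.5% over 1–5 years). Cohorts of a few thousand
subjects would carry almost no events, so `event_inflation` (default 50×)
scales the baseline hazard for test-size runs; set it to 1 for
full-scale realism. Consequences to keep in mind: absolute risks,
PPVs and threshold operating characteristics live on the inflated scale
(the acceptance script scales the thresholds by the same factor);
discrimination and calibration are less affected but not identical to
what the real event rate would give. The generator also simplifies in
ways that bound what passing tests show about real data: one event
process per subject anchored at the latest index date, covariates
independent across subjects, no ICD code strings or claims linkage, no
calendar trends, no informative censoring, and oral-hypoglycemic classes
kept disjoint from the covariate drug classes so combination therapy is
unambiguous.

## Known limitations

* The decay form cannot represent effects that strengthen with time
  since onset (beta2 is constrained non-negative by design); such
  covariates are better served by the constant-effect stage-1 fit.
* Rare indicators (< ~10 carriers) have non-identifiable decay rates;
  the fitter reverts them to constant effects and says so in the trace.
* The AUC interval ignores the variability of the estimated censoring
  weights, and the threshold-metric intervals condition on the observed
  classification denominators.
* Sex-stratified modelling is only exercised on the male stratum at the
  default simulation scale.
* Optimism correction in `refit` mode understates the selection
  component of optimism; use `selection` mode for honest reporting when
  runtime permits.
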