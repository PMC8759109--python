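# pdacrisk

Pancreatic ductal adenocarcinoma (PDAC) is usually diagnosed too late to
resect. One of its strongest early signals is worsening glycemic control in
people who already have diabetes: starting insulin, escalating to
combination oral hypoglycemic therapy, or a sharp HbA1c rise all mark
moments at which PDAC risk is elevated and screening decisions could be
made. `pdacrisk` implements, end to end, a survival-modelling pipeline for
estimating absolute PDAC risk at such progression events from EMR-style
records:

* **Synthetic EMR generation** — relational patient / diagnosis /
  prescription / lab / vitals tables with planted progression events and a
  known ground-truth hazard model, so every downstream stage is testable
  without access to restricted clinical data.
* **Cohort construction** — a diabetes definition (two outpatient
  diagnoses plus a qualifying outpatient lab: HbA1c ≥ 6.5%, fasting
  glucose ≥ 126 mg/dL or random glucose ≥ 200 mg/dL; age ≥ 50), three
  overlapping progression cohorts (insulin initiation; same-day
  combination oral therapy after monotherapy; ≥ 1-point HbA1c rise to
  ≥ 8% within 15 months), a 90-day exclusion after first diabetes
  evidence, and covariates assessed in the 12-month window before the
  index date with 12-month changes taken from a 3-to-15-month prior window.
* **Cox models with decaying effects** — binary clinical predictors
  (e.g. acute pancreatitis) contribute log HR(t) = β₁·exp(−β₂·t), where t
  is months between first record and cohort entry, so a recent diagnosis
  carries its full effect while a distant one fades; (β₁, β₂) are fitted
  by iterative linearization (Gauss–Newton on working covariates, with an
  L-BFGS-B polish), on top of a from-scratch partial-likelihood engine
  (Efron/Breslow ties, Newton–Raphson, Breslow baseline, Schoenfeld
  diagnostics).
* **Model selection** — correlation screening, then stepwise AIC in two
  stages: indicators enter as constant effects first; the decay rate of
  every retained indicator is then freed regardless of whether it improves
  the AIC (duration terms always accompany their indicators).
* **Internal validation** — cumulative/dynamic time-dependent AUC with
  inverse-probability-of-censoring weights, calibration slope, Harrell
  bootstrap optimism correction, and sensitivity/specificity/PPV at
  absolute predicted-risk thresholds with Clopper–Pearson exact intervals.
* **Incidence** — reverse Kaplan–Meier median follow-up and cumulative
  PDAC incidence standardized to age 60.

## Worked example

The analysis is a sequence of numbered scripts that hand off CSV tables
under `results/`:

```bash
python analysis/01_simulate_emr.py --n-subjects 3000 --seed 3
python analysis/02_build_cohorts.py
python analysis/03_fit_models.py
python analysis/04_validate_models.py --b 30
python analysis/05_incidence.py
```

With that seed, step 02 reports the three cohorts and their complete-case
sizes (events are inflated 50× by default so a small population carries
enough of them to fit models):

```
insulin_init: 751 complete rows (45 excluded, 5.7%)
combo_oral: 702 complete rows (52 excluded, 6.9%)
hba1c_rise: 1049 complete rows (53 excluded, 4.8%)
```

Step 03 prints, per cohort, the selected covariates and the decaying
effects as hazard ratios "current" (lag 0) versus "3 years in the past"
(lag 36 months) — the fingerprint of the decay model:

```
hba1c_rise (M, n=972, events=543) selected: age, abdominal_pain,
acute_pancreatitis, alcoholism, weight, jaundice, rbc, pct_weight_change,
smoking, ethnicity, cholesterol, heart_disease
         covariate      hr  hr_lag36  beta2
    abdominal_pain   3.581     3.154  0.003
acute_pancreatitis   8.749     8.433  0.000
        alcoholism   1.608     1.608  0.000
          jaundice 482.448     2.671  0.051
```

A jaundice code entered days before cohort entry multiplies the hazard
hundreds-fold (it is effectively a symptom of the undiagnosed cancer),
but the same code three years earlier carries an HR of only ~2.7 —
that is what β₂ = 0.051/month means. Step 04 then reports discrimination
with bootstrap optimism correction:

```
insulin_init 36m: AUC 0.731 (corrected 0.716)
hba1c_rise  36m: AUC 0.744 (corrected 0.732)
```

and step 05 the age-60-standardized cumulative incidence per cohort and
sex. All of these numbers refer to the simulated population at 50× event
inflation; they are internally consistent with its ground truth, not
estimates for any real population.

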