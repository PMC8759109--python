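"""Independent oracles and data factories shared across the test suite.

The oracles here are deliberately naive (explicit loops over risk sets,
pairwise counting) so they share no code path with the package internals
they check.
"""

import numpy as np
import pandas as pd

from pdacrisk._constants import STUDY_END_DAY


def brute_force_nll(time, event, lp, ties="efron"):
    """Negative log partial likelihood by direct risk-set products."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    lp = np.asarray(lp, dtype=float)
    eta = np.exp(lp)
    out = 0.0
    for tau in sorted(set(time[event])):
        D = [i for i in range(len(time)) if time[i] == tau and event[i]]
        R = [i for i in range(len(time)) if time[i] >= tau]
        d = len(D)
        sum_d = sum(eta[i] for i in D)
        sum_r = sum(eta[i] for i in R)
        out -= sum(lp[i] for i in D)
        if ties == "breslow":
            out += d * np.log(sum_r)
        else:
            for ell in range(d):
                out += np.log(sum_r - (ell / d) * sum_d)
    return out


def brute_force_auc(risks, times, events, horizon):
    """Concordant case-control pair fraction (ties count half)."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    cases = np.flatnonzero((times <= horizon) & events)
    ctrls = np.flatnonzero(times > horizon)
    num = 0.0
    for i in cases:
        for j in ctrls:
            if risks[i] > risks[j]:
                num += 1.0
            elif risks[i] == risks[j]:
                num += 0.5
    return num / (len(cases) * len(ctrls))


def simulate_cox_data(n, beta, seed, scale=60.0, admin=60.0, cens_rate=0.0,
                      day_ties=False):
    """Exponential-baseline PH data with known linear coefficients."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = rng.normal(size=(n, beta.size))
    lp = X @ beta
    t = rng.exponential(scale, n) / np.exp(lp)
    c = np.full(n, admin)
    if cens_rate > 0:
        c = np.minimum(c, rng.exponential(1.0 / cens_rate, n))
    time = np.minimum(t, c)
    if day_ties:
        time = np.ceil(time * 30.4375) / 30.4375
    event = (t <= c).astype(int)
    return time, event, X


def simulate_decay_data(n, beta1, beta2, seed, prevalence=0.3, lag_max=120.0,
                        scale=1500.0, admin=60.0, with_age=False):
    """PH data with one exponentially decaying indicator effect."""
    rng = np.random.default_rng(seed)
    I = (rng.random(n) < prevalence).astype(float)
    T = rng.uniform(0.0, lag_max, n) * I
    lp = beta1 * I * np.exp(-beta2 * T)
    X = None
    if with_age:
        age = rng.normal(0.0, 8.0, n)
        lp = lp + 0.04 * age
        X = age.reshape(-1, 1)
    t = rng.exponential(scale, n) / np.exp(lp)
    time = np.minimum(t, admin)
    time = np.ceil(time * 30.4375) / 30.4375     # day-resolution ties
    event = (t <= admin).astype(int)
    return time, event, X, I, T


def hand_emr():
    """Eight hand-built subjects covering the three progression definitions,
    the 90-day exclusion, boundary labs and the covariate windows.

    Expected membership (index day): insulin A=700, H=900; combination oral
    B=800; HbA1c rise C=1000, H=1100.  E is excluded by the 90-day rule,
    F fails on an inpatient-only lab, G has a single diagnosis code, and
    D's prior HbA1c falls outside the 15-month window.
    """
    from pdacrisk.simulate import RawEMR

    def birth(first_ev, age=60.0):
        return int(first_ev - round(age * 365.25))

    patients = pd.DataFrame(
        [("A", "M", birth(500), "White", "Non-Hispanic", "Never smoker", "No"),
         ("B", "M", birth(400), "White", "Non-Hispanic", "Never smoker", "No"),
         ("C", "M", birth(300), "White", "Non-Hispanic", "Never smoker", "No"),
         ("D", "M", birth(400), "White", "Non-Hispanic", "Never smoker", "No"),
         ("E", "M", birth(600), "White", "Non-Hispanic", "Never smoker", "No"),
         ("F", "M", birth(500), "White", "Non-Hispanic", "Never smoker", "No"),
         ("G", "M", birth(500), "White", "Non-Hispanic", "Never smoker", "No"),
         ("H", "M", birth(500), "White", "Non-Hispanic", "Never smoker", "No")],
        columns=["subject_id", "sex", "birth_day", "race", "ethnicity",
                 "smoking", "drinking"])

    dx = [
        ("A", 500, "diabetes", "outpatient"),
        ("A", 560, "diabetes", "outpatient"),
        ("A", 486, "acute_pancreatitis", "outpatient"),   # lag ~7 months
        ("B", 400, "diabetes", "outpatient"),
        ("B", 450, "diabetes", "outpatient"),
        ("B", 700, "acute_pancreatitis", "outpatient"),
        ("B", 750, "chronic_pancreatitis", "outpatient"),
        ("C", 300, "diabetes", "outpatient"),
        ("C", 350, "diabetes", "outpatient"),
        ("D", 400, "diabetes", "outpatient"),
        ("D", 450, "diabetes", "outpatient"),
        ("E", 600, "diabetes", "outpatient"),
        ("E", 650, "diabetes", "outpatient"),
        ("F", 500, "diabetes", "outpatient"),
        ("F", 550, "diabetes", "outpatient"),
        ("G", 500, "diabetes", "outpatient"),
        ("H", 500, "diabetes", "outpatient"),
        ("H", 550, "diabetes", "outpatient"),
    ]
    diagnoses = pd.DataFrame(dx, columns=["subject_id", "diagnosis_day",
                                          "condition", "setting"])

    labs = [
        ("A", 505, "hba1c", 6.5, False),                  # boundary include
        ("B", 410, "glucose_fasting", 126.0, False),      # boundary include
        ("C", 574, "hba1c", 7.0, False),                  # 14 months before
        ("C", 1000, "hba1c", 8.0, False),                 # rise of exactly 1.0
        ("D", 460, "glucose_random", 200.0, False),       # boundary include
        ("D", 513, "hba1c", 6.9, False),                  # 16 months before
        ("D", 1000, "hba1c", 8.1, False),                 # prior outside window
        ("E", 605, "hba1c", 6.8, False),
        ("F", 505, "glucose_random", 250.0, True),        # inpatient: ignored
        ("G", 505, "glucose_fasting", 130.0, False),      # only one dx code
        ("H", 800, "hba1c", 6.6, False),
        ("H", 1100, "hba1c", 8.2, False),                 # rise 1.6, gap 300 d
    ]
    labs = pd.DataFrame(labs, columns=["subject_id", "lab_day", "analyte",
                                       "value", "inpatient"])

    rx = [
        ("A", 700, "insulin"),
        ("B", 500, "biguanide"),
        ("B", 800, "biguanide"),
        ("B", 800, "sulfonylurea"),
        ("E", 690, "insulin"),                            # exactly +90 days
        ("H", 900, "insulin"),
    ]
    prescriptions = pd.DataFrame(rx, columns=["subject_id", "rx_day",
                                              "drug_class"])

    vitals = pd.DataFrame(
        [("A", 304, 210.0, 70.0),     # 13 months before index 700
         ("A", 600, 520.0, 70.0),     # implausible: filtered
         ("A", 700, 200.0, 70.0)],
        columns=["subject_id", "vital_day", "weight_lbs", "height_in"])

    outcomes = pd.DataFrame(
        [(s, STUDY_END_DAY, 0) for s in "ABCDEFG"] + [("H", 2000, 1)],
        columns=["subject_id", "outcome_day", "pdac"])

    truth = pd.DataFrame(columns=["subject_id", "cohort", "member",
                                  "index_day", "lp", "time_months", "event",
                                  "diabetic", "first_evidence_day"])
    return RawEMR(patients=patients, diagnoses=diagnoses,
                  prescriptions=prescriptions, labs=labs, vitals=vitals,
                  outcomes=outcomes, truth=truth, meta={"seed": -1})


EXPECTED_MEMBERSHIP = {
    "insulin_init": {"A": 700, "H": 900},
    "combo_oral": {"B": 800},
    "hba1c_rise": {"C": 1000, "H": 1100},
}
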