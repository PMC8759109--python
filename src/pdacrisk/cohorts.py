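"""Cohort construction from EMR-like tables.

Reconstructs the diabetes population and the three progression cohorts from
the relational tables, then assembles one analysis row per subject per cohort
with the covariate windows used in the modelling:

* diabetes = at least two outpatient diabetes diagnoses AND one qualifying
  outpatient lab (HbA1c >= 6.5%, fasting glucose >= 126, or random glucose
  >= 200), age >= 50 at first evidence;
* progression = insulin initiation, same-day combination oral hypoglycemic
  initiation from monotherapy, or a >= 1-point HbA1c rise to >= 8% within 15
  months — excluding indices within 90 days of first diabetes evidence;
* covariates assessed on/before the index date: most proximal lab within 12
  months, 12-month changes from a prior test in a 3-to-15-month window,
  plausibility-filtered vitals, peak BMI, and condition/drug indicators with
  months-since-onset lags.

All day/month conversions use the fixed 30.4375 days-per-month convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import (DAYS_PER_MONTH, HEIGHT_RANGE_IN,
                         ORAL_HYPOGLYCEMIC_CLASSES, WEIGHT_RANGE_LBS)
from .simulate import COHORTS, RawEMR

__all__ = [
    "identify_diabetes",
    "build_progression_cohorts",
    "extract_covariates",
    "exclude_incomplete",
    "build_analysis_datasets",
    "CONDITIONS",
    "DRUGS",
    "CONTINUOUS_COVARIATES",
]

#: binary clinical predictors extracted as indicator + months-since-onset lag
CONDITIONS = (
    "acute_pancreatitis",
    "chronic_pancreatitis",
    "abdominal_pain",
    "jaundice",
    "alcoholism",
    "nafld",
    "heart_disease",
)

DRUGS = ("ppi", "statin")

#: continuous covariates whose completeness is required for modelling
CONTINUOUS_COVARIATES = (
    "age",
    "weight",
    "pct_weight_change",
    "peak_bmi",
    "hba1c",
    "hba1c_change",
    "creatinine",
    "cholesterol",
    "bilirubin",
    "pct_bilirubin_change",
    "rbc",
    "pct_rbc_change",
)

LAB_WINDOW_DAYS = 12.0 * DAYS_PER_MONTH            # current-value lookback
CHANGE_MIN_DAYS = 3.0 * DAYS_PER_MONTH             # 3-month lower bound
CHANGE_MAX_DAYS = 15.0 * DAYS_PER_MONTH            # 15-month upper bound
TARGET_GAP_DAYS = 12.0 * DAYS_PER_MONTH            # aim at ~12 months
RISE_WINDOW_DAYS = 457                             # 15-month HbA1c lookback


# ---------------------------------------------------------------------------
# diabetes population
# ---------------------------------------------------------------------------

def identify_diabetes(raw: RawEMR) -> pd.DataFrame:
    """Subjects meeting the diabetes definition, with first-evidence dates.

    Requires >= 2 outpatient diabetes diagnoses and >= 1 qualifying
    outpatient lab; labs drawn during hospitalization are ignored.  The
    first-evidence date is the earlier of the first diabetes diagnosis and
    the first qualifying lab.  Subjects younger than 50 at first evidence are
    excluded.  Returns columns (subject_id, first_evidence_day).
    """
    dx = raw.diagnoses
    dx = dx[(dx["condition"] == "diabetes") & (dx["setting"] == "outpatient")]
    code_counts = dx.groupby("subject_id")["diagnosis_day"].agg(["count", "min"])
    code_ok = code_counts[code_counts["count"] >= 2]

    labs = raw.labs
    labs = labs[~labs["inpatient"].astype(bool)]
    qual = labs[
        ((labs["analyte"] == "hba1c") & (labs["value"] >= 6.5))
        | ((labs["analyte"] == "glucose_fasting") & (labs["value"] >= 126.0))
        | ((labs["analyte"] == "glucose_random") & (labs["value"] >= 200.0))
    ]
    lab_first = qual.groupby("subject_id")["lab_day"].min()

    both = code_ok.join(lab_first.rename("lab_day"), how="inner")
    first_ev = np.minimum(both["min"], both["lab_day"])

    birth = raw.patients.set_index("subject_id")["birth_day"]
    age = (first_ev - birth.reindex(first_ev.index)) / 365.25
    first_ev = first_ev[age >= 50.0]
    out = first_ev.rename("first_evidence_day").reset_index()
    return out.sort_values("subject_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# progression cohorts
# ---------------------------------------------------------------------------

def _insulin_index(raw, subjects):
    rx = raw.prescriptions
    ins = rx[(rx["drug_class"] == "insulin")
             & rx["subject_id"].isin(subjects)]
    return ins.groupby("subject_id")["rx_day"].min().to_dict()


def _combo_oral_index(raw, subjects, grace_days=0):
    """First day with >= 2 distinct oral classes after exactly one class.

    ``grace_days`` widens "simultaneous" from the same calendar day to a
    trailing window of that many days (0 = strict same-day reading).
    """
    rx = raw.prescriptions
    oral = rx[rx["drug_class"].isin(ORAL_HYPOGLYCEMIC_CLASSES)
              & rx["subject_id"].isin(subjects)]
    oral = oral.drop_duplicates(["subject_id", "rx_day", "drug_class"])
    out = {}
    for sid, grp in oral.groupby("subject_id"):
        grp = grp.sort_values(["rx_day", "drug_class"])
        days = grp["rx_day"].to_numpy()
        classes = grp["drug_class"].to_numpy()
        for day in np.unique(days):
            window = set(classes[(days >= day - grace_days) & (days <= day)])
            if len(window) < 2:
                continue
            prior = set(classes[days < day - grace_days])
            if len(prior) == 1:
                out[sid] = int(day)
                break
    return out


def _hba1c_rise_index(raw, subjects):
    """First outpatient HbA1c >= 8 with a prior value >= 1 point lower within
    the 15-month lookback (prior strictly before, gap <= 457 days)."""
    labs = raw.labs
    a1c = labs[(labs["analyte"] == "hba1c") & ~labs["inpatient"].astype(bool)
               & labs["subject_id"].isin(subjects)]
    out = {}
    for sid, grp in a1c.groupby("subject_id"):
        grp = grp.sort_values("lab_day")
        days = grp["lab_day"].to_numpy()
        vals = grp["value"].to_numpy()
        hit = None
        # 1e-9 slack keeps the >= comparisons exact for one-decimal assay
        # values that float arithmetic would otherwise push below threshold
        for i in np.flatnonzero(vals >= 8.0 - 1e-9):
            prior = (days < days[i]) & (days >= days[i] - RISE_WINDOW_DAYS)
            if np.any(vals[prior] <= vals[i] - 1.0 + 1e-9):
                hit = int(days[i])
                break
        if hit is not None:
            out[sid] = hit
    return out


def build_progression_cohorts(raw: RawEMR, diabetics: pd.DataFrame,
                              combo_grace_days: int = 0) -> dict:
    """Map cohort kind -> DataFrame (subject_id, index_day, first_evidence_day).

    Cohorts overlap; a subject may appear in all three.  Indices within 90
    days of first diabetes evidence are excluded (apparent progression too
    close to diagnosis to be trusted).
    """
    first_ev = diabetics.set_index("subject_id")["first_evidence_day"]
    subjects = set(first_ev.index)
    raw_indices = {
        "insulin_init": _insulin_index(raw, subjects),
        "combo_oral": _combo_oral_index(raw, subjects, combo_grace_days),
        "hba1c_rise": _hba1c_rise_index(raw, subjects),
    }
    out = {}
    for kind, idx in raw_indices.items():
        df = pd.DataFrame({"subject_id": list(idx.keys()),
                           "index_day": [int(v) for v in idx.values()]})
        if df.empty:
            df = pd.DataFrame(columns=["subject_id", "index_day"])
        df["first_evidence_day"] = df["subject_id"].map(first_ev)
        df = df[df["index_day"] - df["first_evidence_day"] > 90]
        out[kind] = df.sort_values("subject_id").reset_index(drop=True)
    return out


def nonprogressors(diabetics: pd.DataFrame, cohorts: dict) -> pd.DataFrame:
    """Diabetic subjects belonging to none of the progression cohorts."""
    in_any = set()
    for df in cohorts.values():
        in_any.update(df["subject_id"])
    return diabetics[~diabetics["subject_id"].isin(in_any)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

def _closest_before(days, values, index_day, window_days):
    """Most proximal (day, value) with day <= index within the lookback."""
    ok = (days <= index_day) & (days > index_day - window_days)
    if not np.any(ok):
        return None, np.nan
    pos = np.flatnonzero(ok)
    best = pos[np.argmax(days[pos])]
    return int(days[best]), float(values[best])


def _prior_in_change_window(days, values, current_day):
    """Prior test closest to 12 months before ``current_day`` within the
    3-to-15-month window; ties broken toward the earlier test."""
    gap = current_day - days
    ok = (gap >= CHANGE_MIN_DAYS) & (gap <= CHANGE_MAX_DAYS)
    if not np.any(ok):
        return np.nan
    pos = np.flatnonzero(ok)
    dist = np.abs(gap[pos] - TARGET_GAP_DAYS)
    # stable argmin prefers the first occurrence; sort by (dist, -gap) so the
    # earlier test (larger gap) wins ties
    order = np.lexsort((-gap[pos], dist))
    return float(values[pos[order[0]]])


@dataclass
class _SubjectRecords:
    """Per-subject record arrays grouped once for fast repeated lookups."""

    labs: dict          # analyte -> (days, values)
    vitals: tuple       # (days, weights, heights) already plausibility-filtered
    conditions: dict    # condition -> first day
    drugs: dict         # drug -> first day


def _group_records(raw: RawEMR):
    labs = raw.labs[~raw.labs["inpatient"].astype(bool)]
    lab_map = {}
    for (sid, analyte), grp in labs.groupby(["subject_id", "analyte"]):
        grp = grp.sort_values("lab_day")
        lab_map.setdefault(sid, {})[analyte] = (
            grp["lab_day"].to_numpy(), grp["value"].to_numpy())

    vit = raw.vitals
    wlo, whi = WEIGHT_RANGE_LBS
    hlo, hhi = HEIGHT_RANGE_IN
    vit = vit[(vit["weight_lbs"] >= wlo) & (vit["weight_lbs"] <= whi)
              & (vit["height_in"] >= hlo) & (vit["height_in"] <= hhi)]
    vit_map = {}
    for sid, grp in vit.groupby("subject_id"):
        grp = grp.sort_values("vital_day")
        vit_map[sid] = (grp["vital_day"].to_numpy(),
                        grp["weight_lbs"].to_numpy(),
                        grp["height_in"].to_numpy())

    dx = raw.diagnoses[raw.diagnoses["condition"].isin(CONDITIONS)]
    cond_map = {}
    for (sid, cond), grp in dx.groupby(["subject_id", "condition"]):
        cond_map.setdefault(sid, {})[cond] = int(grp["diagnosis_day"].min())

    rx = raw.prescriptions[raw.prescriptions["drug_class"].isin(DRUGS)]
    drug_map = {}
    for (sid, drug), grp in rx.groupby(["subject_id", "drug_class"]):
        drug_map.setdefault(sid, {})[drug] = int(grp["rx_day"].min())

    return lab_map, vit_map, cond_map, drug_map


def extract_covariates(raw: RawEMR, cohort: pd.DataFrame, kind: str,
                       _grouped=None) -> pd.DataFrame:
    """Assemble the analysis dataset for one progression cohort.

    One row per subject: demographics, current labs (most proximal within 12
    months before index), 12-month changes (3-to-15-month prior window),
    plausibility-filtered weight and peak BMI, condition/drug indicators with
    lags in months, follow-up time and the pancreatic-cancer event flag.
    Missing continuous values are left as NaN for ``exclude_incomplete``.
    """
    lab_map, vit_map, cond_map, drug_map = (_grouped if _grouped is not None
                                            else _group_records(raw))
    patients = raw.patients.set_index("subject_id")
    outcomes = raw.outcomes.set_index("subject_id")
    if outcomes.index.has_duplicates:
        raise ValueError("data integrity: multiple outcome rows per subject")

    rows = []
    for rec in cohort.itertuples(index=False):
        sid, index_day = rec.subject_id, int(rec.index_day)
        if sid not in outcomes.index:
            raise ValueError(f"data integrity: subject {sid!r} has no "
                             "vital-status/outcome row")
        pat = patients.loc[sid]
        out = outcomes.loc[sid]
        row = {
            "subject_id": sid,
            "cohort": kind,
            "index_day": index_day,
            "sex": pat["sex"],
            "age": (index_day - pat["birth_day"]) / 365.25,
            "race": pat["race"],
            "ethnicity": pat["ethnicity"] if pd.notna(pat["ethnicity"])
            else "Missing/unknown",
            "smoking": pat["smoking"] if pd.notna(pat["smoking"])
            else "Missing/unknown",
            "drinking": pat["drinking"] if pd.notna(pat["drinking"])
            else "Missing/unknown",
        }

        slabs = lab_map.get(sid, {})

        def current_and_change(analyte):
            if analyte not in slabs:
                return np.nan, np.nan
            days, vals = slabs[analyte]
            day, cur = _closest_before(days, vals, index_day, LAB_WINDOW_DAYS)
            if day is None:
                return np.nan, np.nan
            prior = _prior_in_change_window(days, vals, day)
            return cur, prior

        cur, prior = current_and_change("hba1c")
        row["hba1c"] = cur
        row["hba1c_change"] = cur - prior          # percentage points
        for analyte in ("creatinine", "cholesterol"):
            cur, _ = current_and_change(analyte)
            row[analyte] = cur
        for analyte in ("bilirubin", "rbc"):
            cur, prior = current_and_change(analyte)
            row[analyte] = cur
            row[f"pct_{analyte}_change"] = 100.0 * (cur - prior) / prior \
                if np.isfinite(cur) and np.isfinite(prior) and prior != 0 \
                else np.nan

        # vitals: current weight, % change, peak BMI from highest-ever weight
        if sid in vit_map:
            vdays, vweights, vheights = vit_map[sid]
            day, wcur = _closest_before(vdays, vweights, index_day,
                                        LAB_WINDOW_DAYS)
            row["weight"] = wcur
            if day is not None:
                wprior = _prior_in_change_window(vdays, vweights, day)
                row["pct_weight_change"] = (100.0 * (wcur - wprior) / wprior
                                            if np.isfinite(wprior) else np.nan)
            else:
                row["pct_weight_change"] = np.nan
            before = vdays <= index_day
            if np.any(before):
                peak_w = float(vweights[before].max())
                height = float(vheights[before][-1])
                row["peak_bmi"] = 703.0 * peak_w / height ** 2
            else:
                row["peak_bmi"] = np.nan
        else:
            row["weight"] = row["pct_weight_change"] = row["peak_bmi"] = np.nan

        # condition indicators with lags; chronic pancreatitis takes
        # precedence over acute when both are on record
        sconds = cond_map.get(sid, {})
        firsts = {c: d for c, d in sconds.items() if d <= index_day}
        if "acute_pancreatitis" in firsts and "chronic_pancreatitis" in firsts:
            firsts.pop("acute_pancreatitis")
        for cond in CONDITIONS:
            if cond in firsts:
                row[f"{cond}_ind"] = 1
                row[f"{cond}_lag"] = (index_day - firsts[cond]) / DAYS_PER_MONTH
            else:
                row[f"{cond}_ind"] = 0
                row[f"{cond}_lag"] = 0.0
        sdrugs = drug_map.get(sid, {})
        for drug in DRUGS:
            d = sdrugs.get(drug)
            if d is not None and d <= index_day:
                row[f"{drug}_ind"] = 1
                row[f"{drug}_lag"] = (index_day - d) / DAYS_PER_MONTH
            else:
                row[f"{drug}_ind"] = 0
                row[f"{drug}_lag"] = 0.0

        fu_days = int(out["outcome_day"]) - index_day
        if fu_days <= 0:
            raise ValueError(f"data integrity: subject {sid!r} outcome on or "
                             "before the index date")
        row["time_months"] = fu_days / DAYS_PER_MONTH
        row["event"] = int(out["pdac"])
        rows.append(row)

    return pd.DataFrame(rows)


def exclude_incomplete(dataset: pd.DataFrame):
    """Drop rows with any missing continuous covariate.

    Returns (retained dataset, report).  The report lists per-covariate
    missing counts and the excluded fraction; a warning is emitted when more
    than 10% of rows are lost (the modelling assumes near-complete data).
    """
    if len(dataset) == 0:
        return dataset.copy(), {"n_total": 0, "n_excluded": 0,
                                "fraction_excluded": 0.0, "by_covariate": {}}
    cols = [c for c in CONTINUOUS_COVARIATES if c in dataset.columns]
    missing = dataset[cols].isna()
    drop = missing.any(axis=1)
    report = {
        "n_total": int(len(dataset)),
        "n_excluded": int(drop.sum()),
        "fraction_excluded": float(drop.mean()),
        "by_covariate": {c: int(missing[c].sum()) for c in cols
                         if missing[c].sum()},
    }
    if report["fraction_excluded"] > 0.10:
        warnings.warn(
            f"{100 * report['fraction_excluded']:.1f}% of rows dropped for "
            "incomplete continuous covariates (expected < 10%)")
    return dataset[~drop].reset_index(drop=True), report


def build_analysis_datasets(raw: RawEMR, combo_grace_days: int = 0):
    """End-to-end cohort construction: identify diabetes, build the three
    progression cohorts, extract covariates and drop incomplete rows.

    Returns (datasets, reports, extras) where ``datasets`` maps cohort kind
    to its complete-case analysis DataFrame, ``reports`` holds the exclusion
    reports, and ``extras`` carries the diabetic roster, raw cohort index
    tables and the nonprogressor complement used by the incidence module.
    """
    diabetics = identify_diabetes(raw)
    cohorts = build_progression_cohorts(raw, diabetics, combo_grace_days)
    grouped = _group_records(raw)
    datasets, reports = {}, {}
    for kind in COHORTS:
        ds = extract_covariates(raw, cohorts[kind], kind, _grouped=grouped)
        datasets[kind], reports[kind] = exclude_incomplete(ds)
    extras = {
        "diabetics": diabetics,
        "cohort_indices": cohorts,
        "nonprogressors": nonprogressors(diabetics, cohorts),
    }
    return datasets, reports, extras
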