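"""Cohort construction: diabetes definition, progression indices, covariate
windows, completeness exclusions."""

import numpy as np
import pandas as pd
import pytest

from pdacrisk.cohorts import (CONTINUOUS_COVARIATES, build_analysis_datasets,
                              build_progression_cohorts, exclude_incomplete,
                              extract_covariates, identify_diabetes,
                              nonprogressors)
from pdacrisk.simulate import COHORTS

from helpers import EXPECTED_MEMBERSHIP, hand_emr


@pytest.fixture(scope="module")
def hand_raw():
    return hand_emr()


@pytest.fixture(scope="module")
def hand_cohorts(hand_raw):
    dia = identify_diabetes(hand_raw)
    return dia, build_progression_cohorts(hand_raw, dia)


def test_diabetes_definition_on_hand_fixture(hand_cohorts):
    dia, _ = hand_cohorts
    # F: inpatient-only lab; G: single diagnosis code
    assert set(dia["subject_id"]) == {"A", "B", "C", "D", "E", "H"}
    first = dict(zip(dia["subject_id"], dia["first_evidence_day"]))
    assert first["A"] == 500          # dx before the boundary HbA1c of 6.5
    assert first["C"] == 300


def test_membership_matrix_matches_hand_enumeration(hand_cohorts):
    _, cohorts = hand_cohorts
    for kind in COHORTS:
        got = dict(zip(cohorts[kind]["subject_id"],
                       cohorts[kind]["index_day"]))
        assert got == EXPECTED_MEMBERSHIP[kind], kind


def test_ninety_day_exclusion_boundary(hand_cohorts):
    # E starts insulin exactly 90 days after first evidence: excluded
    _, cohorts = hand_cohorts
    assert "E" not in set(cohorts["insulin_init"]["subject_id"])


def test_fifteen_month_window_excludes_d(hand_cohorts):
    _, cohorts = hand_cohorts
    assert "D" not in set(cohorts["hba1c_rise"]["subject_id"])


def test_nonprogressor_complement(hand_cohorts):
    dia, cohorts = hand_cohorts
    np_set = set(nonprogressors(dia, cohorts)["subject_id"])
    assert np_set == {"D", "E"}


def test_weight_change_and_peak_bmi_hand_arithmetic(hand_raw, hand_cohorts):
    _, cohorts = hand_cohorts
    ds = extract_covariates(hand_raw, cohorts["insulin_init"], "insulin_init")
    a = ds[ds["subject_id"] == "A"].iloc[0]
    # 210 lbs thirteen months before, 200 at index
    assert a["weight"] == pytest.approx(200.0)
    assert a["pct_weight_change"] == pytest.approx(100 * (200 - 210) / 210,
                                                   abs=1e-9)
    # the 520-lb record is outside [75, 500] and must not drive peak BMI
    assert a["peak_bmi"] == pytest.approx(703.0 * 210.0 / 70.0 ** 2,
                                          abs=1e-9)
    # acute pancreatitis 214 days before index
    assert a["acute_pancreatitis_ind"] == 1
    assert a["acute_pancreatitis_lag"] == pytest.approx(214 / 30.4375,
                                                        abs=1e-9)


def test_chronic_supersedes_acute_pancreatitis(hand_raw, hand_cohorts):
    _, cohorts = hand_cohorts
    ds = extract_covariates(hand_raw, cohorts["combo_oral"], "combo_oral")
    b = ds[ds["subject_id"] == "B"].iloc[0]
    assert b["chronic_pancreatitis_ind"] == 1
    assert b["acute_pancreatitis_ind"] == 0
    assert b["chronic_pancreatitis_lag"] == pytest.approx(50 / 30.4375)


def test_missing_prior_hba1c_leads_to_exclusion(hand_raw, hand_cohorts):
    _, cohorts = hand_cohorts
    ds = extract_covariates(hand_raw, cohorts["insulin_init"], "insulin_init")
    a = ds[ds["subject_id"] == "A"].iloc[0]
    assert np.isnan(a["hba1c_change"])          # no prior in the 3-15 window
    with pytest.warns(UserWarning):             # tiny fixture: all rows go
        kept, report = exclude_incomplete(ds)
    assert "A" not in set(kept["subject_id"])
    assert report["by_covariate"]["hba1c_change"] >= 1


def test_exclude_incomplete_counts_and_warning():
    base = {c: 1.0 for c in CONTINUOUS_COVARIATES}
    rows = [dict(base, subject_id=i) for i in range(10)]
    df = pd.DataFrame(rows)
    kept, report = exclude_incomplete(df)
    assert len(kept) == 10 and report["n_excluded"] == 0

    df.loc[0, "cholesterol"] = np.nan
    kept, report = exclude_incomplete(df)
    assert len(kept) == 9
    assert report["by_covariate"] == {"cholesterol": 1}

    df.loc[1, "rbc"] = np.nan
    with pytest.warns(UserWarning, match="10%"):
        kept, report = exclude_incomplete(df)
    assert report["fraction_excluded"] == pytest.approx(0.2)


def test_round_trip_against_simulator_truth(emr_small):
    dia = identify_diabetes(emr_small)
    cohorts = build_progression_cohorts(emr_small, dia)
    truth = emr_small.truth
    assert set(dia["subject_id"]) == set(
        truth.loc[truth["diabetic"], "subject_id"])
    for kind in COHORTS:
        tm = truth[(truth["cohort"] == kind) & truth["member"]]
        expected = dict(zip(tm["subject_id"], tm["index_day"]))
        got = dict(zip(cohorts[kind]["subject_id"],
                       cohorts[kind]["index_day"]))
        assert got == expected, kind


def test_build_is_deterministic(emr_small):
    a = build_analysis_datasets(emr_small)[0]
    b = build_analysis_datasets(emr_small)[0]
    for kind in COHORTS:
        pd.testing.assert_frame_equal(a[kind], b[kind])


def test_lags_nonnegative_and_followup_positive(built_small):
    datasets, _, _ = built_small
    for kind, d in datasets.items():
        assert (d["time_months"] > 0).all()
        for c in d.columns:
            if c.endswith("_lag"):
                assert (d[c] >= 0).all()


def test_cohort_union_within_diabetic_set(emr_small, built_small):
    _, _, extras = built_small
    dia = set(extras["diabetics"]["subject_id"])
    for kind, df in extras["cohort_indices"].items():
        assert set(df["subject_id"]) <= dia
        assert df["subject_id"].is_unique


def test_combo_grace_window_widens_definition(hand_raw, hand_cohorts):
    dia, _ = hand_cohorts
    raw = hand_raw
    # split B's combination day: biguanide on 800, sulfonylurea on 802
    rx = raw.prescriptions.copy()
    rx.loc[(rx["subject_id"] == "B") & (rx["drug_class"] == "sulfonylurea"),
           "rx_day"] = 802
    import dataclasses
    raw2 = dataclasses.replace(raw, prescriptions=rx)
    strict = build_progression_cohorts(raw2, dia, combo_grace_days=0)
    assert "B" not in set(strict["combo_oral"]["subject_id"])
    lax = build_progression_cohorts(raw2, dia, combo_grace_days=7)
    got = dict(zip(lax["combo_oral"]["subject_id"],
                   lax["combo_oral"]["index_day"]))
    assert got["B"] == 802
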