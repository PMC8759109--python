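"""Shared unit conventions for the EMR simulation and cohort construction."""

import numpy as np

#: fixed month length used for every day<->month conversion in the package
DAYS_PER_MONTH = 30.4375

#: simulation epoch; all integer day offsets are relative to this date
EPOCH = np.datetime64("2000-01-01")

#: last day of the simulation window (2017-12-31 relative to the epoch)
STUDY_END_DAY = int((np.datetime64("2017-12-31") - EPOCH).astype(int))

#: oral hypoglycemic drug classes recognised for the combination-therapy rule
ORAL_HYPOGLYCEMIC_CLASSES = (
    "biguanide",
    "sulfonylurea",
    "thiazolidinedione",
    "alpha_glucosidase_inhibitor",
    "dpp4_inhibitor",
    "glp1_agonist",
)

#: weight/height plausibility ranges (lbs, inches)
WEIGHT_RANGE_LBS = (75.0, 500.0)
HEIGHT_RANGE_IN = (48.0, 84.0)


def days_to_months(days):
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH


def months_to_days(months):
    return np.asarray(months, dtype=float) * DAYS_PER_MONTH


def day_to_date(day):
    """Integer day offset -> numpy datetime64 date."""
    return EPOCH + np.asarray(day).astype("timedelta64[D]")


def date_to_day(date):
    """ISO date / datetime64 -> integer day offset from the epoch."""
    d = np.asarray(date, dtype="datetime64[D]")
    return (d - EPOCH).astype(int)
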