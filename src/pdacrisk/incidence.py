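"""Descriptive survival summaries: follow-up and age-standardized incidence.

Median follow-up uses the reverse Kaplan-Meier method (the Kaplan-Meier
estimator applied to the censoring distribution).  Cumulative incidence of
pancreatic cancer is standardized to a reference age (60 years) through a
Cox model with age as the sole covariate: incidence(tau | 60) =
1 - S0(tau)^exp(beta_age * (60 - mean age)), with delta-method intervals.
Death is treated as censoring (no competing-risk decomposition), matching a
last-known-vital-status censoring rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cox import fit_linear_cox

__all__ = [
    "km_survival",
    "censoring_survival",
    "reverse_km_median_followup",
    "format_followup",
    "age_standardized_cuminc",
]


def km_survival(times, events):
    """Kaplan-Meier survival curve; returns (distinct event times, S(t))."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, starts, counts = np.unique(t[e], return_index=True,
                                     return_counts=True)
    n_at_risk = t.size - np.searchsorted(t, uniq, side="left")
    frac = 1.0 - counts / n_at_risk
    return uniq, np.cumprod(frac)


def censoring_survival(times, events):
    """Reverse Kaplan-Meier: survival curve of the censoring distribution."""
    return km_survival(times, ~np.asarray(events).astype(bool))


def reverse_km_median_followup(times, events):
    """Median follow-up in months by the reverse Kaplan-Meier method.

    Returns the smallest time at which the censoring-distribution survival
    drops to <= 0.5, or ``inf`` when the median is not reached (e.g. every
    subject experienced the event).
    """
    events = np.asarray(events).astype(bool)
    if not (~events).any():
        return float("inf")
    t, s = censoring_survival(times, events)
    below = s <= 0.5 + 1e-12
    if not below.any():
        return float("inf")
    return float(t[np.argmax(below)])


def format_followup(median, max_time):
    """Human-readable median follow-up; '> max' when not reached."""
    if np.isinf(median):
        return f"> {max_time:g}"
    return f"{median:g}"


def age_standardized_cuminc(age, times, events,
                            eval_months=(12, 24, 36, 48, 60),
                            standard_age=60.0, level=0.95,
                            tie_method="efron"):
    """Cumulative incidence standardized to ``standard_age`` years.

    Fits a Cox model with age as the only covariate and predicts the
    absolute risk profile of a subject aged ``standard_age``:
    1 - exp(-H0(tau) * exp(beta * (standard_age - mean age))).  Interval
    estimates combine the Breslow baseline variance with the delta-method
    age-coefficient variance on the log cumulative hazard scale (their
    covariance is ignored; it vanishes at the mean age).  Returns a
    DataFrame with one row per evaluation month.
    """
    age = np.asarray(age, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() == 0:
        raise ValueError("no events: cumulative incidence is unidentified")
    fit = fit_linear_cox(times, events, age.reshape(-1, 1), ["age"],
                         tie_method=tie_method)
    beta = float(fit.beta[0])
    var_beta = float(fit.cov[0, 0])
    mean_age = fit.lp_mean / beta if beta != 0 else float(age.mean())
    a = standard_age - mean_age
    z = stats.norm.ppf(0.5 + level / 2.0)

    rows = []
    for tau in eval_months:
        idx = np.searchsorted(fit.baseline_times, float(tau), side="right") - 1
        if idx < 0:
            h0, vh0 = 0.0, 0.0
        else:
            h0 = float(fit.baseline_cumhaz[idx])
            vh0 = float(fit.baseline_cumhaz_var[idx])
        h = h0 * np.exp(beta * a)
        if h > 0:
            # var on the log-H scale: relative baseline var + (a*se_beta)^2
            vlog = vh0 / h0 ** 2 + a ** 2 * var_beta
            half = z * np.sqrt(vlog)
            lo = 1.0 - np.exp(-h * np.exp(-half))
            hi = 1.0 - np.exp(-h * np.exp(half))
        else:
            lo = hi = 0.0
        rows.append({"months": float(tau), "incidence": 1.0 - np.exp(-h),
                     "lo": lo, "hi": hi})
    out = pd.DataFrame(rows)
    out.attrs["standard_age"] = float(standard_age)
    out.attrs["beta_age"] = beta
    return out
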