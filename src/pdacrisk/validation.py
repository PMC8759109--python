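"""Internal validation of fitted risk models.

Discrimination is measured with the cumulative/dynamic time-dependent AUC
(cases = events by the horizon, controls = subjects still event-free past
it), with inverse-probability-of-censoring weights from the reverse
Kaplan-Meier of the censoring distribution.  Calibration is the slope of a
Cox refit on the model's linear predictor.  Optimism from model development
(screening + stepwise selection + decay refitting) is estimated with
Harrell's bootstrap and subtracted from the apparent performance.  Operating
characteristics (sensitivity, specificity, PPV) are reported at absolute
predicted-risk thresholds with Clopper-Pearson exact intervals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cox import CoxFit, fit_linear_cox
from .incidence import censoring_survival

__all__ = [
    "predicted_risk",
    "cumulative_dynamic_auc",
    "calibration_slope",
    "optimism_correct",
    "threshold_metrics",
    "clopper_pearson",
]


def predicted_risk(fit: CoxFit, lp, horizon):
    """Absolute event risk by ``horizon`` months for each linear predictor.

    risk = 1 - S0(horizon)^exp(lp - lp_mean), with S0 the Breslow baseline
    survival centered at the training-mean linear predictor.  ``horizon``
    must not exceed the last observed event time (the baseline is flat and
    uninformative beyond it).
    """
    horizon = float(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0.0:
        return np.zeros(np.asarray(lp, dtype=float).shape)
    if fit.baseline_times.size == 0:
        raise ValueError("model has no events: no baseline hazard")
    tmax = float(fit.baseline_times[-1])
    if horizon > tmax:
        raise ValueError(
            f"horizon {horizon:g} exceeds the last event time; the maximum "
            f"usable horizon is {tmax:g} months")
    h0 = fit.baseline_cumhaz_at(horizon)
    lp = np.asarray(lp, dtype=float)
    return 1.0 - np.exp(-h0 * np.exp(lp - fit.lp_mean))


def cumulative_dynamic_auc(risks, times, events, horizon, level=0.95):
    """Cumulative/dynamic time-dependent AUC with IPCW for censoring.

    Cases are subjects with an observed event by ``horizon``; controls are
    subjects under observation beyond it.  Case contributions are weighted by
    1/G(T-) where G is the reverse Kaplan-Meier censoring survival (the
    constant control weight 1/G(horizon) cancels).  Returns (auc, (lo, hi),
    se); the variance is a first-order U-statistic (DeLong-type)
    approximation treating the censoring weights as fixed.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    horizon = float(horizon)
    case = (times <= horizon) & events
    ctrl = times > horizon
    if not case.any() or not ctrl.any():
        raise ValueError("AUC undefined: no cases or no controls at horizon")

    w = np.ones(case.sum())
    if (~events & (times <= horizon)).any():      # censoring present
        Gt, Gs = censoring_survival(times, events)
        # G evaluated just before each case's event time
        idx = np.searchsorted(Gt, times[case], side="left") - 1
        G = np.where(idx >= 0, Gs[np.maximum(idx, 0)], 1.0)
        if np.any(G <= 0):
            raise ValueError("IPCW weight undefined (censoring survival 0 "
                             "before a case's event time)")
        w = 1.0 / G

    r_case = risks[case]
    r_ctrl = np.sort(risks[ctrl])
    n1, n0 = r_case.size, r_ctrl.size
    lo = np.searchsorted(r_ctrl, r_case, side="left")
    hi = np.searchsorted(r_ctrl, r_case, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n0             # P(case risk > control risk)
    sw = w.sum()
    auc = float((w * v10).sum() / sw)

    # control-side placements: weighted fraction of cases above each control
    order = np.argsort(r_case, kind="stable")
    rc_sorted = r_case[order]
    wc_sorted = w[order]
    cw = np.concatenate([[0.0], np.cumsum(wc_sorted)])
    lo0 = np.searchsorted(rc_sorted, r_ctrl, side="left")
    hi0 = np.searchsorted(rc_sorted, r_ctrl, side="right")
    above = sw - cw[hi0]
    ties = cw[hi0] - cw[lo0]
    v01 = (above + 0.5 * ties) / sw

    var_case = float((w ** 2 * (v10 - auc) ** 2).sum() / sw ** 2)
    var_ctrl = float(((v01 - auc) ** 2).sum() / n0 ** 2)
    se = np.sqrt(var_case + var_ctrl)
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return auc, ci, se


def calibration_slope(lp, times, events, tie_method="efron"):
    """Slope of a Cox refit with the linear predictor as sole covariate.

    1.0 indicates perfect calibration of relative risks; < 1 indicates the
    model's predictions are too extreme (overfitting).  Evaluated on the
    training data of any converged fit the slope is exactly 1 (the score
    equation of the original fit).
    """
    lp = np.asarray(lp, dtype=float)
    fit = fit_linear_cox(times, events, lp.reshape(-1, 1), ["lp"],
                         tie_method=tie_method)
    return float(fit.beta[0]), float(fit.se[0])


def optimism_correct(dataset, fit_fn, metric_fns, B=200, seed=0,
                     level=0.95, max_failure_fraction=0.10):
    """Harrell's bootstrap optimism correction for a modelling pipeline.

    ``fit_fn(df)`` must run the *entire* development pipeline on a dataset
    and return a fitted object; each ``metric_fns[name](fitted, df)`` scores
    a fitted object on a dataset (higher = better or worse, the correction
    is sign-agnostic).  For b = 1..B the pipeline is rerun on a resample,
    scored on the resample (apparent_b) and on the original data (test_b);
    optimism = mean(apparent_b - test_b) and corrected = apparent -
    optimism.  Percentile intervals over replicates are returned.  Replicate
    RNG streams derive from ``seed`` by fixed offsets, so results are
    reproducible.  Failed replicates are dropped with a logged reason; more
    than ``max_failure_fraction`` failures is an error.
    """
    n = len(dataset)
    full = fit_fn(dataset)
    apparent = {m: float(f(full, dataset)) for m, f in metric_fns.items()}

    opt = {m: [] for m in metric_fns}
    failures = []
    for b in range(B):
        rng = np.random.default_rng([int(seed), b])
        idx = rng.integers(0, n, size=n)
        boot = dataset.iloc[idx].reset_index(drop=True)
        try:
            fit_b = fit_fn(boot)
            for m, f in metric_fns.items():
                opt[m].append(float(f(fit_b, boot)) - float(f(fit_b, dataset)))
        except Exception as err:     # replicate-level failure: drop & log
            failures.append((b, f"{type(err).__name__}: {err}"))
    n_ok = B - len(failures)
    if len(failures) > max_failure_fraction * B:
        raise RuntimeError(
            f"{len(failures)}/{B} bootstrap replicates failed; first: "
            f"{failures[0][1]}")

    alpha = 1.0 - level
    out = {}
    for m in metric_fns:
        o = np.asarray(opt[m], dtype=float)
        optimism = float(o.mean()) if n_ok else 0.0
        corrected = apparent[m] - optimism
        if n_ok:
            qlo, qhi = np.quantile(o, [1.0 - alpha / 2.0, alpha / 2.0])
            ci = (apparent[m] - float(qlo), apparent[m] - float(qhi))
        else:
            ci = (np.nan, np.nan)
        out[m] = {
            "apparent": apparent[m],
            "optimism": optimism,
            "corrected": corrected,
            "ci": ci,
            "n_replicates": n_ok,
        }
    out["_failures"] = failures
    out["_settings"] = {"B": B, "seed": int(seed)}
    return out


def clopper_pearson(k, n, level=0.95):
    """Exact binomial confidence interval from Beta quantiles."""
    if n == 0:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2.0, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k) if k < n else 1.0
    return (float(lo), float(hi))


def threshold_metrics(risks, times, events, horizon, threshold,
                      level=0.95, ipcw=False):
    """Sensitivity, specificity and PPV at an absolute-risk threshold.

    Test-positive = predicted risk >= threshold.  Outcome-positive =
    observed event by the horizon; outcome-negative = followed beyond the
    horizon event-free.  Subjects censored before the horizon without an
    event are excluded from classification by default; with ``ipcw=True``
    they are instead handled by weighting the classified subjects with
    inverse-probability-of-censoring weights (intervals then use an
    effective sample size).  Intervals are Clopper-Pearson exact binomial.
    Metrics with empty denominators are reported as NaN.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    horizon = float(horizon)

    pos = (times <= horizon) & events
    neg = times > horizon
    flagged = risks >= threshold

    if not ipcw:
        w_pos = np.ones(int(pos.sum()))
        w_neg = np.ones(int(neg.sum()))
    else:
        Gt, Gs = censoring_survival(times, events)
        idx = np.searchsorted(Gt, times[pos], side="left") - 1
        Gp = np.where(idx >= 0, Gs[np.maximum(idx, 0)], 1.0)
        ih = np.searchsorted(Gt, horizon, side="right") - 1
        Gh = float(Gs[ih]) if ih >= 0 else 1.0
        if np.any(Gp <= 0) or Gh <= 0:
            raise ValueError("IPCW weight undefined")
        w_pos = 1.0 / Gp
        w_neg = np.full(int(neg.sum()), 1.0 / Gh)

    tp = float(w_pos[flagged[pos]].sum())
    fn = float(w_pos[~flagged[pos]].sum())
    tn = float(w_neg[~flagged[neg]].sum())
    fp = float(w_neg[flagged[neg]].sum())

    def _eff_n(wsub):
        # effective sample size for weighted intervals
        s1, s2 = wsub.sum(), (wsub ** 2).sum()
        return s1 ** 2 / s2 if s2 > 0 else 0.0

    def _metric(num, den, wsub):
        if den <= 0:
            return {"value": np.nan, "ci": (np.nan, np.nan),
                    "numerator": num, "denominator": den}
        p = num / den
        n_eff = len(wsub) if not ipcw else _eff_n(wsub)
        k_eff = int(round(p * n_eff))
        return {"value": p, "ci": clopper_pearson(k_eff, int(round(n_eff)),
                                                  level),
                "numerator": num, "denominator": den}

    w_flagged = np.concatenate([w_pos[flagged[pos]], w_neg[flagged[neg]]])
    out = {
        "sensitivity": _metric(tp, tp + fn, w_pos),
        "specificity": _metric(tn, tn + fp, w_neg),
        "ppv": _metric(tp, tp + fp, w_flagged),
        "n_cases": int(pos.sum()),
        "n_controls": int(neg.sum()),
        "n_excluded": int((~pos & ~neg).sum()),
        "threshold": threshold,
        "horizon": horizon,
        "ipcw": ipcw,
    }
    return out
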