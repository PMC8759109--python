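"""End-to-end study driver: simulate -> build -> select -> fit -> validate.

This module glues the stages into the reproducible analysis the numbered
scripts under ``analysis/`` run: generate a synthetic EMR population, build
the three progression cohorts, develop a sex-specific risk model per cohort
(correlation screen, stepwise AIC, decay refit), validate it at the 12-,
36- and 60-month horizons, and summarize incidence.  All outputs are plain
text (CSV/JSON) with deterministic formatting: the same seed produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import CONDITIONS, DRUGS, build_analysis_datasets
from .cox import hr_at_lag
from .incidence import (age_standardized_cuminc, format_followup,
                        reverse_km_median_followup)
from .selection import Candidate, SelectedModel, correlation_screen, stepwise_aic
from .simulate import COHORTS, RawEMR, SimConfig, generate_population
from .validation import (cumulative_dynamic_auc, calibration_slope,
                         optimism_correct, predicted_risk, threshold_metrics)

__all__ = [
    "default_candidates",
    "develop_model",
    "validate_model",
    "run_study",
]

HORIZONS = (12.0, 36.0, 60.0)
THRESHOLDS = (0.005, 0.01, 0.02)


def default_candidates():
    """The candidate covariate set considered for every cohort model."""
    cands = [
        Candidate("age"),
        Candidate("race", kind="categorical"),
        Candidate("ethnicity", kind="categorical"),
        Candidate("smoking", kind="categorical"),
        Candidate("drinking", kind="categorical"),
        Candidate("weight"),
        Candidate("pct_weight_change"),
        Candidate("peak_bmi"),
        Candidate("hba1c"),
        Candidate("hba1c_change"),
        Candidate("creatinine"),
        Candidate("cholesterol"),
        Candidate("bilirubin"),
        Candidate("pct_bilirubin_change"),
        Candidate("rbc"),
        Candidate("pct_rbc_change"),
    ]
    cands += [Candidate(c, kind="indicator", decay=True) for c in CONDITIONS]
    cands += [Candidate(d, kind="indicator", decay=True) for d in DRUGS]
    return cands


def develop_model(df, candidates=None, forced=("age",), r_threshold=0.8,
                  tie_method="efron"):
    """Correlation screen followed by two-stage stepwise AIC selection."""
    if candidates is None:
        candidates = default_candidates()
    kept, screen_report = correlation_screen(df, candidates, r_threshold)
    model = stepwise_aic(df, kept, forced=forced, tie_method=tie_method)
    return model, screen_report


def _risks(model: SelectedModel, df, horizon):
    lp = model.linear_predictor(df)
    h = min(float(horizon), float(model.fit.baseline_times[-1]))
    return predicted_risk(model.fit, lp, h)


def validate_model(df, model: SelectedModel, horizons=HORIZONS,
                   thresholds=THRESHOLDS, B=100, seed=0,
                   bootstrap_mode="selection", candidates=None,
                   forced=("age",)):
    """Apparent and optimism-corrected performance plus threshold metrics.

    ``bootstrap_mode`` is ``"selection"`` (honest: the whole screen +
    stepwise + decay pipeline is rerun on every bootstrap resample) or
    ``"refit"`` (fast: only the selected model's coefficients are refit).
    The mode is recorded in the report.
    """
    times = df[model.time_col].to_numpy(dtype=float)
    events = df[model.event_col].to_numpy(dtype=int)
    lp = model.linear_predictor(df)

    report = {"horizons": {}, "thresholds": [],
              "bootstrap": {"B": B, "seed": int(seed),
                            "mode": bootstrap_mode}}

    metric_fns = {}
    for h in horizons:
        def auc_h(m, d, _h=h):
            r = _risks(m, d, _h)
            return cumulative_dynamic_auc(
                r, d[m.time_col].to_numpy(dtype=float),
                d[m.event_col].to_numpy(dtype=int), _h)[0]
        metric_fns[f"auc_{int(h)}"] = auc_h

    def slope_m(m, d):
        return calibration_slope(m.linear_predictor(d),
                                 d[m.time_col].to_numpy(dtype=float),
                                 d[m.event_col].to_numpy(dtype=int))[0]
    metric_fns["calibration_slope"] = slope_m

    if bootstrap_mode == "selection":
        def fit_fn(d):
            return develop_model(d, candidates=candidates, forced=forced)[0]
    elif bootstrap_mode == "refit":
        def fit_fn(d):
            # a resample may lose every carrier of a rare indicator (zero
            # variance) or keep only carriers with events (separation); in
            # either case that covariate is unidentifiable there and is
            # dropped from the replicate refit
            import re as _re

            from .cox import ConvergenceError
            sel = []
            for c in model.selected:
                col = (f"{c.name}_ind" if c.kind == "indicator" else c.name)
                if c.kind != "categorical" and d[col].nunique() < 2:
                    continue
                sel.append(c)
            for _ in range(len(sel)):
                try:
                    return stepwise_aic(d, sel,
                                        forced=[c.name for c in sel],
                                        direction="backward",
                                        tie_method=model.fit.tie_method,
                                        time_col=model.time_col,
                                        event_col=model.event_col)
                except ConvergenceError as err:
                    m = _re.search(r"'([^']+)'", str(err))
                    bad = m.group(1) if m else None
                    if bad is not None:
                        base = _re.sub(r"(_ind|\[.*\])$", "", bad)
                        keep = [c for c in sel if c.name != base]
                        if len(keep) < len(sel):
                            sel = keep
                            continue
                    raise
            raise ConvergenceError("replicate refit failed for every "
                                   "covariate subset")
    else:
        raise ValueError(f"unknown bootstrap mode {bootstrap_mode!r}")

    boot = optimism_correct(df, fit_fn, metric_fns, B=B, seed=seed)

    for h in horizons:
        r = _risks(model, df, h)
        auc, ci, se = cumulative_dynamic_auc(r, times, events, h)
        key = f"auc_{int(h)}"
        report["horizons"][int(h)] = {
            "auc": auc, "auc_ci": ci, "auc_se": se,
            "auc_corrected": boot[key]["corrected"],
            "auc_corrected_ci": boot[key]["ci"],
        }
        for thr in thresholds:
            tm = threshold_metrics(r, times, events, h, thr)
            report["thresholds"].append({
                "horizon": int(h), "threshold": thr,
                "sensitivity": tm["sensitivity"]["value"],
                "sensitivity_ci": tm["sensitivity"]["ci"],
                "specificity": tm["specificity"]["value"],
                "specificity_ci": tm["specificity"]["ci"],
                "ppv": tm["ppv"]["value"],
                "ppv_ci": tm["ppv"]["ci"],
                "n_cases": tm["n_cases"], "n_controls": tm["n_controls"],
                "n_excluded": tm["n_excluded"],
            })
    slope, slope_se = calibration_slope(lp, times, events)
    report["calibration_slope"] = {
        "apparent": slope, "se": slope_se,
        "corrected": boot["calibration_slope"]["corrected"],
        "corrected_ci": boot["calibration_slope"]["ci"],
    }
    report["bootstrap"]["n_failures"] = len(boot["_failures"])
    return report


def _effects_table(model: SelectedModel):
    rows = []
    for nm, b, se in zip(model.fit.names, model.fit.beta, model.fit.se):
        rows.append({"covariate": nm, "type": "linear", "coef": b, "se": se,
                     "hr": float(np.exp(b)), "hr_lag36": float(np.exp(b)),
                     "beta2": 0.0})
    for nm in model.fit.decay_names:
        eff = model.fit.decay_effects[nm]
        hr0, _ = hr_at_lag(eff, 0.0)
        hr36, _ = hr_at_lag(eff, 36.0)
        rows.append({"covariate": nm, "type": "decay", "coef": eff.beta1,
                     "se": float(np.sqrt(eff.cov[0, 0])), "hr": hr0,
                     "hr_lag36": hr36, "beta2": eff.beta2})
    return pd.DataFrame(rows)


def run_study(outdir=None, seed=0, n_subjects=5000, sex="M", B=50,
              bootstrap_mode="refit", horizons=HORIZONS,
              thresholds=THRESHOLDS, config=None, raw: RawEMR = None):
    """Run the complete analysis and (optionally) write its text outputs.

    Returns a dict with, per cohort: the analysis dataset, the selected
    model, the validation report, the age-standardized incidence table and
    the reverse-KM median follow-up.  Models are developed on the ``sex``
    subset (the simulated population is predominantly male, mirroring the
    study population; female subsets are too small to support selection at
    desk scale and enter the incidence summaries only).
    """
    if raw is None:
        if config is None:
            config = SimConfig(n_subjects=n_subjects, seed=seed)
        raw = generate_population(config)
    datasets, reports, extras = build_analysis_datasets(raw)

    results = {"seed": int(seed), "cohorts": {}, "exclusions": reports}
    inc_rows = []
    for kind in COHORTS:
        ds = datasets[kind]
        sub = ds[ds["sex"] == sex].reset_index(drop=True)
        model, screen = develop_model(sub)
        val = validate_model(sub, model, horizons=horizons,
                             thresholds=thresholds, B=B, seed=seed,
                             bootstrap_mode=bootstrap_mode)
        med = reverse_km_median_followup(sub["time_months"], sub["event"])
        inc = age_standardized_cuminc(sub["age"], sub["time_months"],
                                      sub["event"])
        inc.insert(0, "cohort", kind)
        inc.insert(1, "sex", sex)
        inc_rows.append(inc)
        results["cohorts"][kind] = {
            "dataset": sub, "model": model, "screen": screen,
            "validation": val, "median_followup": med, "incidence": inc,
        }
    np_df = extras["nonprogressors"]
    results["n_nonprogressors"] = int(len(np_df))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reports(results, outdir)
    return results


def _fmt(x):
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def write_reports(results, outdir):
    """Serialize study results as deterministic text files."""
    outdir = Path(outdir)
    perf_rows, thr_rows, eff_frames, inc_frames = [], [], [], []
    for kind, res in results["cohorts"].items():
        val = res["validation"]
        for h, d in val["horizons"].items():
            perf_rows.append({
                "cohort": kind, "horizon": h,
                "auc": d["auc"], "auc_lo": d["auc_ci"][0],
                "auc_hi": d["auc_ci"][1],
                "auc_corrected": d["auc_corrected"],
                "calibration_slope": val["calibration_slope"]["apparent"],
                "calibration_slope_corrected":
                    val["calibration_slope"]["corrected"],
                "median_followup_months": res["median_followup"],
                "bootstrap_mode": val["bootstrap"]["mode"],
                "bootstrap_B": val["bootstrap"]["B"],
            })
        for row in val["thresholds"]:
            thr_rows.append({"cohort": kind, **{
                k: (v if not isinstance(v, tuple) else None)
                for k, v in row.items() if not isinstance(v, tuple)}})
        eff = _effects_table(res["model"])
        eff.insert(0, "cohort", kind)
        eff_frames.append(eff)
        inc_frames.append(res["incidence"])

    float_format = "%.10g"
    pd.DataFrame(perf_rows).to_csv(outdir / "performance.csv", index=False,
                                   float_format=float_format)
    pd.DataFrame(thr_rows).to_csv(outdir / "threshold_metrics.csv",
                                  index=False, float_format=float_format)
    pd.concat(eff_frames, ignore_index=True).to_csv(
        outdir / "model_effects.csv", index=False, float_format=float_format)
    pd.concat(inc_frames, ignore_index=True).to_csv(
        outdir / "incidence.csv", index=False, float_format=float_format)

    trail = {kind: res["model"].trail
             for kind, res in results["cohorts"].items()}
    (outdir / "selection_trail.json").write_text(
        json.dumps(trail, indent=1, sort_keys=True, default=_fmt))
    summary = {
        "seed": results["seed"],
        "n_nonprogressors": results["n_nonprogressors"],
        "exclusions": results["exclusions"],
        "selected": {k: res["model"].selected_names
                     for k, res in results["cohorts"].items()},
        "median_followup": {
            k: format_followup(res["median_followup"], 84.0)
            for k, res in results["cohorts"].items()},
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_fmt))
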