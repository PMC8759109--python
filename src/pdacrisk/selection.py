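"""Stepwise AIC model selection with duration-term constraints.

Selection runs in two stages.  Stage 1 performs bidirectional stepwise
search over linear covariates, categorical blocks and binary indicators,
with every indicator entering as a constant (non-decaying) effect; the move
with the best AIC improvement is applied until no move improves, with
deterministic alphabetical tie-breaking.  Stage 2 then frees the decay rate
beta2 of every retained decay-eligible indicator and refits by iterative
linearization — duration parameters are kept regardless of whether they
improve the AIC, because a retained diagnosis/prescription indicator always
carries its time-since-onset structure.

Collinearity is reduced beforehand: of any covariate pair correlated beyond
``r_threshold``, the member with the worse univariate AIC is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxFit, fit_decay_cox, fit_linear_cox, neg_log_partial_likelihood

__all__ = [
    "Candidate",
    "SelectedModel",
    "correlation_screen",
    "stepwise_aic",
]


@dataclass(frozen=True)
class Candidate:
    """One selectable covariate.

    kind:
      * ``linear`` — a numeric column entered as-is;
      * ``categorical`` — a string column entered as a dummy block
        (reference = most frequent level, ties broken alphabetically);
      * ``indicator`` — a 0/1 column ``<name>_ind`` with companion lag
        column ``<name>_lag`` (months); ``decay=True`` marks it eligible for
        a freed decay rate in stage 2.
    """

    name: str
    kind: str = "linear"
    decay: bool = False

    def columns(self, df):
        """Design columns (values, names) this candidate contributes."""
        if self.kind == "linear":
            return [df[self.name].to_numpy(dtype=float)], [self.name]
        if self.kind == "indicator":
            return ([df[f"{self.name}_ind"].to_numpy(dtype=float)],
                    [f"{self.name}_ind"])
        if self.kind == "categorical":
            s = df[self.name].astype(str)
            counts = s.value_counts()
            ref = sorted(counts[counts == counts.max()].index)[0]
            levels = sorted(lv for lv in s.unique() if lv != ref)
            return ([(s == lv).to_numpy(dtype=float) for lv in levels],
                    [f"{self.name}[{lv}]" for lv in levels])
        raise ValueError(f"unknown candidate kind {self.kind!r}")


def _design(df, cands):
    cols, names = [], []
    for c in cands:
        v, n = c.columns(df)
        cols += v
        names += n
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def _null_aic(times, events, tie_method):
    nll = neg_log_partial_likelihood(times, events, np.zeros(len(times)),
                                     tie_method)
    return 2.0 * nll


@dataclass
class SelectedModel:
    """Result of the two-stage selection: spec, fit and AIC trail."""

    candidates: list                    # full screened candidate list
    selected: list                      # selected Candidate objects
    forced: tuple
    fit: CoxFit
    trail: list = field(default_factory=list)
    time_col: str = "time_months"
    event_col: str = "event"

    @property
    def selected_names(self):
        return [c.name for c in self.selected]

    def design(self, df):
        """(X, names, I, T, decay_names) for this model on any dataset."""
        lin = [c for c in self.selected if not (c.kind == "indicator"
                                                and c.decay)]
        dec = [c for c in self.selected if c.kind == "indicator" and c.decay]
        X, names = _design(df, lin)
        if dec:
            I = np.column_stack([df[f"{c.name}_ind"].to_numpy(dtype=float)
                                 for c in dec])
            T = np.column_stack([df[f"{c.name}_lag"].to_numpy(dtype=float)
                                 for c in dec])
        else:
            I = np.empty((len(df), 0))
            T = np.empty((len(df), 0))
        return X, names, I, T, [c.name for c in dec]

    def linear_predictor(self, df):
        X, _, I, T, _ = self.design(df)
        return self.fit.linear_predictor(
            X=X if X.shape[1] else None,
            I=I if I.shape[1] else None,
            T=T if T.shape[1] else None)


def correlation_screen(df, candidates, r_threshold=0.8,
                       time_col="time_months", event_col="event",
                       tie_method="efron"):
    """Drop one member of every highly correlated covariate pair.

    Numeric representatives (linear columns and 0/1 indicators; categorical
    blocks are exempt) are compared pairwise on standardized Pearson
    correlation.  Within an offending pair the covariate with the larger
    univariate AIC loses.  Returns (retained candidates, report rows).
    """
    times = df[time_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    numeric = [c for c in candidates if c.kind in ("linear", "indicator")]
    reps = {}
    for c in numeric:
        col = (df[c.name] if c.kind == "linear"
               else df[f"{c.name}_ind"]).to_numpy(dtype=float)
        reps[c.name] = col

    aic_cache = {}

    def _uni_aic(c):
        if c.name not in aic_cache:
            fit = fit_linear_cox(times, events,
                                 reps[c.name].reshape(-1, 1), [c.name],
                                 tie_method=tie_method)
            aic_cache[c.name] = fit.aic
        return aic_cache[c.name]

    pairs = []
    for i in range(len(numeric)):
        for j in range(i + 1, len(numeric)):
            a, b = numeric[i], numeric[j]
            xa, xb = reps[a.name], reps[b.name]
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            if abs(r) >= r_threshold:
                pairs.append((abs(r), a, b, r))
    pairs.sort(key=lambda t: (-t[0], t[1].name, t[2].name))

    dropped = set()
    report = []
    for _, a, b, r in pairs:
        if a.name in dropped or b.name in dropped:
            continue
        loser = a if _uni_aic(a) > _uni_aic(b) else b
        dropped.add(loser.name)
        report.append({"covariate_a": a.name, "covariate_b": b.name,
                       "r": r, "dropped": loser.name})
    retained = [c for c in candidates if c.name not in dropped]
    return retained, report


def stepwise_aic(df, candidates, forced=(), direction="both",
                 tie_method="efron", time_col="time_months",
                 event_col="event") -> SelectedModel:
    """Two-stage stepwise AIC selection (see module docstring).

    ``forced`` names candidates kept in the model at every step.  Returns a
    SelectedModel whose ``fit`` is the stage-2 decay fit when any retained
    indicator is decay-eligible, otherwise the stage-1 linear fit.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    times = df[time_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    by_name = {c.name: c for c in candidates}
    for f in forced:
        if f not in by_name:
            raise ValueError(f"forced-in covariate {f!r} not a candidate")

    def _fit(sel):
        X, names = _design(df, sel)
        if X.shape[1] == 0:
            return None, _null_aic(times, events, tie_method)
        fit = fit_linear_cox(times, events, X, names, tie_method=tie_method)
        return fit, fit.aic

    selected = [by_name[f] for f in sorted(forced)]
    if direction == "backward":
        selected += sorted((c for c in candidates if c.name not in forced),
                           key=lambda c: c.name)
    cur_fit, cur_aic = _fit(selected)
    trail = [{"stage": 1, "action": "start",
              "model": [c.name for c in selected], "aic": cur_aic}]

    while True:
        moves = []
        if direction in ("both", "forward"):
            for c in sorted((c for c in candidates
                             if c not in selected), key=lambda c: c.name):
                cand_sel = selected + [c]
                try:
                    fit, aic = _fit(cand_sel)
                except Exception:
                    continue
                moves.append((aic, "add", c.name, cand_sel, fit))
        if direction in ("both", "backward"):
            for c in sorted((c for c in selected
                             if c.name not in forced), key=lambda c: c.name):
                cand_sel = [s for s in selected if s is not c]
                try:
                    fit, aic = _fit(cand_sel)
                except Exception:
                    continue
                moves.append((aic, "drop", c.name, cand_sel, fit))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best = moves[0]
        if best[0] >= cur_aic - 1e-10:
            break
        cur_aic, cur_fit = best[0], best[4]
        selected = best[3]
        trail.append({"stage": 1, "action": best[1], "covariate": best[2],
                      "aic": cur_aic})

    if cur_fit is None and not selected:
        warnings_msg = "no candidate improves on the null model"
        trail.append({"stage": 1, "action": "null-model", "note": warnings_msg})
        import warnings as _w
        _w.warn(warnings_msg)

    # stage 2: free beta2 for retained decay-eligible indicators, keeping
    # the duration parameters regardless of the AIC change
    decay_sel = [c for c in selected if c.kind == "indicator" and c.decay]
    final_fit = cur_fit
    if decay_sel:
        lin_sel = [c for c in selected if c not in decay_sel]
        X, names = _design(df, lin_sel)
        I = np.column_stack([df[f"{c.name}_ind"].to_numpy(dtype=float)
                             for c in decay_sel])
        T = np.column_stack([df[f"{c.name}_lag"].to_numpy(dtype=float)
                             for c in decay_sel])
        final_fit = fit_decay_cox(times, events,
                                  X if X.shape[1] else None, I, T,
                                  names=names if X.shape[1] else None,
                                  decay_names=[c.name for c in decay_sel],
                                  tie_method=tie_method)
        trail.append({"stage": 2, "action": "free-decay",
                      "covariates": [c.name for c in decay_sel],
                      "aic": final_fit.aic})

    return SelectedModel(candidates=list(candidates), selected=selected,
                         forced=tuple(forced), fit=final_fit, trail=trail,
                         time_col=time_col, event_col=event_col)
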