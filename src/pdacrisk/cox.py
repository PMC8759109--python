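"""Cox proportional-hazards models with exponentially decaying covariate effects.

The central model: a binary clinical indicator (e.g. prior acute pancreatitis)
recorded ``t`` months before cohort entry contributes

    log HR(t) = beta1 * exp(-beta2 * t)

to the log hazard, so recent diagnoses carry their full effect ``beta1`` while
distant ones fade toward the null.  ``beta2 = 0`` recovers a constant effect.
The pair (beta1, beta2) is estimated by iterative linearization: at each outer
step the nonlinear term is replaced by its first-order expansion in working
covariates and an ordinary linear Cox model is refit (Gauss-Newton on the
partial likelihood).

Everything here operates on plain numpy arrays: ``time`` (months from index),
``event`` (0/1), a design matrix ``X`` of linear covariates, and per-indicator
``(I, T)`` arrays for decay terms.  Ties are handled by the Efron correction by
default (Breslow available for cross-checks).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DecayEffect",
    "CoxFit",
    "ConvergenceError",
    "neg_log_partial_likelihood",
    "decay_linear_predictor",
    "fit_linear_cox",
    "fit_decay_cox",
    "hr_at_lag",
    "schoenfeld_ph_test",
    "breslow_baseline",
]


class ConvergenceError(RuntimeError):
    """Raised when a partial-likelihood maximization fails to converge."""


@dataclass
class DecayEffect:
    """Exponentially decaying log-hazard-ratio effect.

    Parameters
    ----------
    beta1 : float
        Log hazard ratio at lag zero (a diagnosis made at cohort entry).
    beta2 : float
        Decay rate per month of lag; must be >= 0 for a decaying effect.
    cov : (2, 2) ndarray, optional
        Covariance of (beta1, beta2), used for delta-method intervals.
    """

    beta1: float
    beta2: float
    cov: np.ndarray | None = None

    def log_hr(self, t):
        t = np.asarray(t, dtype=float)
        return self.beta1 * np.exp(-self.beta2 * t)

    def hr(self, t):
        return np.exp(self.log_hr(t))


@dataclass
class CoxFit:
    """A fitted Cox model (linear terms plus optional decay effects)."""

    names: list
    beta: np.ndarray
    decay_names: list
    decay_effects: dict                 # name -> DecayEffect
    params: np.ndarray                  # [beta..., b1..., b2...] (free params order)
    param_names: list
    cov: np.ndarray
    se: np.ndarray
    loglik: float                       # maximized log partial likelihood
    n_free_params: int
    tie_method: str
    n: int
    n_events: int
    lp_mean: float
    baseline_times: np.ndarray          # unique event times (months)
    baseline_cumhaz: np.ndarray         # Breslow H0 centered at lp_mean
    baseline_cumhaz_var: np.ndarray     # cumulative d_j / S_j^2
    iterations: int
    converged: bool
    final_score_norm: float
    trace: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free_params

    # -- linear predictor -------------------------------------------------
    def linear_predictor(self, X=None, I=None, T=None):
        """Per-subject log relative hazard, uncentered.

        ``X`` columns must match ``names``; ``I``/``T`` columns match
        ``decay_names`` (indicator and lag in months).
        """
        n = None
        lp = 0.0
        if len(self.names):
            X = np.asarray(X, dtype=float)
            n = X.shape[0]
            lp = X @ self.beta
        if len(self.decay_names):
            I = np.atleast_2d(np.asarray(I, dtype=float).T).T
            T = np.atleast_2d(np.asarray(T, dtype=float).T).T
            n = I.shape[0]
            for k, nm in enumerate(self.decay_names):
                eff = self.decay_effects[nm]
                lp = lp + I[:, k] * eff.beta1 * np.exp(-eff.beta2 * T[:, k])
        if np.isscalar(lp):
            lp = np.zeros(n if n is not None else 0)
        return np.asarray(lp, dtype=float)

    def baseline_cumhaz_at(self, horizon):
        """Breslow baseline cumulative hazard at ``horizon`` months (step)."""
        horizon = float(horizon)
        idx = np.searchsorted(self.baseline_times, horizon, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.baseline_cumhaz[idx])

    def baseline_survival_at(self, horizon):
        return float(np.exp(-self.baseline_cumhaz_at(horizon)))


# ---------------------------------------------------------------------------
# partial-likelihood core
# ---------------------------------------------------------------------------

def _rev_cumsum(a, axis=0):
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


class _SurvOrder:
    """Precomputed ordering/grouping of a right-censored sample."""

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and non-negative")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.e = event[self.order]
        self.n_events = int(self.e.sum())
        self.event_pos = np.flatnonzero(self.e)          # positions in sorted order
        et = self.t[self.event_pos]
        if self.n_events:
            self.uniq, starts, self.d = np.unique(et, return_index=True,
                                                  return_counts=True)
            self.group_starts = starts                   # into event_pos
            self.risk_start = np.searchsorted(self.t, self.uniq, side="left")
            # map each subject to number of event times <= its own time
            self.n_prior_groups = np.searchsorted(self.uniq, self.t, side="right")
            # group index of each event subject
            self.event_group = np.searchsorted(self.uniq, et, side="left")
        else:
            self.uniq = np.empty(0)
            self.d = np.empty(0, dtype=int)


def _cox_core(order: _SurvOrder, lp, Z=None, tie_method="efron"):
    """Negative log partial likelihood, dNLL/dLP, gradient and Hessian.

    ``Z`` is an (n, p) design; gradient/Hessian are with respect to the
    coefficients of ``Z`` evaluated at the supplied per-subject ``lp`` (which
    need not equal ``Z @ beta`` — this is what lets the same core serve both
    the linear model and the chain rule of the nonlinear decay model).

    Returns (nll, g_lp, grad, hess); ``g_lp`` is in the original data order.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {tie_method!r}")
    lp = np.asarray(lp, dtype=float)
    if np.any(~np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    n = order.n
    p = 0 if Z is None else Z.shape[1]
    if order.n_events == 0:
        warnings.warn("no events: partial likelihood is identically 1")
        g = np.zeros(n)
        return 0.0, g, np.zeros(p), np.zeros((p, p))

    lpc = lp - lp.max()
    lps = lpc[order.order]
    eta = np.exp(lps)
    Zs = None if Z is None else np.asarray(Z, dtype=float)[order.order]

    m = order.uniq.size
    S = _rev_cumsum(eta)[order.risk_start]                       # (m,)
    if np.any(S <= 0.0):
        # an extreme linear predictor underflowed every weight in some risk
        # set; report an infinite objective so line searches back off
        return np.inf, np.zeros(n), np.zeros(p), np.eye(p)
    eta_e = eta[order.event_pos]
    Tsum = np.add.reduceat(eta_e, order.group_starts)            # (m,)
    d = order.d.astype(float)

    if Zs is not None:
        ZW = eta[:, None] * Zs
        Sz = _rev_cumsum(ZW, axis=0)[order.risk_start]           # (m, p)
        ZZW = ZW[:, :, None] * Zs[:, None, :]
        Szz = _rev_cumsum(ZZW, axis=0)[order.risk_start]         # (m, p, p)
        Ze = Zs[order.event_pos]
        Tz = np.add.reduceat(eta_e[:, None] * Ze, order.group_starts, axis=0)
        Tzz = np.add.reduceat((eta_e[:, None] * Ze)[:, :, None] * Ze[:, None, :],
                              order.group_starts, axis=0)

    nll = -lps[order.event_pos].sum()
    a = np.zeros(m)      # sum_l 1/denom  (for dNLL/dLP over risk sets)
    b = np.zeros(m)      # sum_l (l/d)/denom  (tied-event correction)
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    if tie_method == "breslow":
        nll += float((d * np.log(S)).sum())
        a[:] = d / S
        if Zs is not None:
            mu = Sz / S[:, None]
            grad = (d[:, None] * mu).sum(axis=0)
            hess = np.einsum("j,jab->ab", d / S, Szz) \
                - np.einsum("j,ja,jb->ab", d, mu, mu)
    else:  # efron
        # l = 0 term for every unique event time
        nll += float(np.log(S).sum())
        a += 1.0 / S
        if Zs is not None:
            mu0 = Sz / S[:, None]
            grad = mu0.sum(axis=0)
            hess = np.einsum("j,jab->ab", 1.0 / S, Szz) \
                - np.einsum("ja,jb->ab", mu0, mu0)
        tied = np.flatnonzero(order.d >= 2)
        for j in tied:
            dj = d[j]
            for l in range(1, int(dj)):
                f = l / dj
                denom = S[j] - f * Tsum[j]
                nll += np.log(denom)
                a[j] += 1.0 / denom
                b[j] += f / denom
                if Zs is not None:
                    mul = (Sz[j] - f * Tz[j]) / denom
                    grad += mul
                    hess += (Szz[j] - f * Tzz[j]) / denom - np.outer(mul, mul)

    # dNLL/dLP per subject: -delta_i + eta_i * (A_i - delta_i * b_{group(i)})
    A = np.concatenate([[0.0], np.cumsum(a)])[order.n_prior_groups]
    g_sorted = eta * A
    if tie_method == "efron" and b.any():
        g_sorted[order.event_pos] -= eta_e * b[order.event_group]
    g_sorted[order.event_pos] -= 1.0
    if Zs is not None:
        grad -= Ze.sum(axis=0)

    g_lp = np.empty(n)
    g_lp[order.order] = g_sorted
    return float(nll), g_lp, grad, hess


def neg_log_partial_likelihood(time, event, lp, tie_method="efron"):
    """Negative log Cox partial likelihood at a given linear predictor.

    Invariant to adding a constant to ``lp``.  Returns 0 (with a warning)
    when the sample contains no events.
    """
    order = _SurvOrder(time, event)
    nll, _, _, _ = _cox_core(order, lp, None, tie_method)
    return nll


def decay_linear_predictor(X, beta, I=None, T=None, beta1=None, beta2=None):
    """Assemble LP = X @ beta + sum_k I_k * beta1_k * exp(-beta2_k * T_k)."""
    X = np.asarray(X, dtype=float)
    lp = X @ np.asarray(beta, dtype=float) if X.size else np.zeros(len(X))
    if I is not None:
        I = np.atleast_2d(np.asarray(I, dtype=float).T).T
        T = np.atleast_2d(np.asarray(T, dtype=float).T).T
        b1 = np.atleast_1d(np.asarray(beta1, dtype=float))
        b2 = np.atleast_1d(np.asarray(beta2, dtype=float))
        lp = lp + (I * b1 * np.exp(-b2 * T)).sum(axis=1)
    return lp


def breslow_baseline(time, event, lp, lp_mean=None):
    """Breslow baseline cumulative hazard, centered at ``lp_mean``.

    Returns (event_times, cumhaz, cumhaz_var) step-function knots, where the
    variance accumulates d_j / S_j^2 (the Poisson/Aalen approximation).  With
    all-zero ``lp`` the estimate is exactly the Nelson-Aalen estimator.
    """
    order = _SurvOrder(time, event)
    lp = np.asarray(lp, dtype=float)
    if lp_mean is None:
        lp_mean = float(lp.mean()) if lp.size else 0.0
    eta = np.exp((lp - lp_mean)[order.order])
    if order.n_events == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    S = _rev_cumsum(eta)[order.risk_start]
    return (order.uniq.copy(), np.cumsum(order.d / S),
            np.cumsum(order.d / S ** 2))


# ---------------------------------------------------------------------------
# linear Cox fit (Newton-Raphson with step halving)
# ---------------------------------------------------------------------------

def _check_design(X, names):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    p = X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length does not match number of columns")
    for j in range(p):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate {names[j]!r} has zero variance")
    return X, names


def _descent_step(hess, grad):
    """Newton step, ridge-regularized until it is a descent direction.

    A near-singular (or, for the nonlinear decay model, indefinite) Hessian
    can yield a numerically non-descent Newton direction; adding a
    Levenberg-style ridge bends the step toward the gradient.
    """
    p = grad.size
    try:
        step = np.linalg.solve(hess, grad)
    except np.linalg.LinAlgError:
        step = np.linalg.lstsq(hess, grad, rcond=None)[0]
    if float(grad @ step) > 0:
        return step
    lam = 1e-8 * max(1.0, float(np.trace(hess)) / max(p, 1))
    for _ in range(12):
        try:
            step = np.linalg.solve(hess + lam * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = None
        if step is not None and float(grad @ step) > 0:
            return step
        lam *= 100.0
    return grad.copy()          # steepest descent as a last resort


def _newton(order, lp_fn, p, beta0, tol, max_iter, names, tie_method,
            coef_bound=None):
    """Minimize NLL over coefficients of a linear design via ``lp_fn``.

    ``lp_fn(beta) -> (lp, Z)`` returns the linear predictor and the design
    whose coefficients are being updated (identical for a plain linear
    model).  With ``coef_bound`` set, coefficients are projected onto
    [-bound, bound] (a separated coefficient pins at the boundary instead of
    raising); the score test for convergence then ignores bound-active
    coordinates.
    """
    beta = beta0.copy()
    lp, Z = lp_fn(beta)
    nll, _, grad, hess = _cox_core(order, lp, Z, tie_method)

    def _active_score(b, g):
        if not p:
            return 0.0
        if coef_bound is None:
            return float(np.abs(g).max())
        pinned = ((b >= coef_bound) & (g < 0)) | ((b <= -coef_bound) & (g > 0))
        return float(np.abs(g[~pinned]).max()) if (~pinned).any() else 0.0

    it = 0
    for it in range(1, max_iter + 1):
        sn = _active_score(beta, grad)
        if sn < tol:
            return beta, nll, grad, hess, it - 1, True
        step = _descent_step(hess, grad)
        ms = float(np.abs(step).max()) if p else 0.0
        if ms > 10.0:        # trust region: huge steps mean a flat direction
            step = step * (10.0 / ms)
        alpha = 1.0
        for _ in range(11):
            cand = beta - alpha * step
            if coef_bound is not None:
                cand = np.clip(cand, -coef_bound, coef_bound)
            lp_c, Z_c = lp_fn(cand)
            nll_c, _, grad_c, hess_c = _cox_core(order, lp_c, Z_c, tie_method)
            if nll_c <= nll + 1e-12:
                break
            alpha *= 0.5
        else:
            # step fully rejected; accept convergence only if score is tiny
            # or the solution is pinned at the coefficient bound
            if sn < 1e-6 * max(1.0, abs(nll)) or (
                    coef_bound is not None
                    and _active_score(beta, grad) < 1e-4 * max(1.0, abs(nll))):
                return beta, nll, grad, hess, it, True
            raise ConvergenceError("step halving failed to reduce the "
                                   "negative log partial likelihood")
        if coef_bound is None and np.abs(cand).max() > 80.0:
            worst = names[int(np.argmax(np.abs(cand)))]
            raise ConvergenceError(
                f"coefficient for {worst!r} is diverging (monotone likelihood /"
                " perfect separation?)")
        rel = abs(nll - nll_c) / max(1.0, abs(nll))
        change = float(np.abs(cand - beta).max()) if p else 0.0
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
        if (_active_score(beta, grad) < tol and rel < tol) or \
                (coef_bound is not None and change < 1e-12):
            return beta, nll, grad, hess, it, True
    sn = _active_score(beta, grad)
    if sn < 1e-6 * max(1.0, abs(nll)):
        return beta, nll, grad, hess, it, True
    raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} "
                           f"iterations (max |score| = {sn:.3g})")


def fit_linear_cox(time, event, X, names=None, tie_method="efron",
                   tol=1e-8, max_iter=100, coef_bound=None):
    """Fit an ordinary (linear) Cox proportional-hazards model.

    Newton-Raphson on the partial likelihood with step halving; standard
    errors from the inverse observed information; Breslow baseline cumulative
    hazard stored centered at the mean linear predictor.  A monotone
    likelihood (perfect separation) raises ConvergenceError naming the
    covariate unless ``coef_bound`` caps the coefficients.
    """
    X, names = _check_design(X, names)
    order = _SurvOrder(time, event)
    if order.n_events < 1:
        raise ValueError("at least one event is required")
    p = X.shape[1]

    def lp_fn(beta):
        return X @ beta, X

    beta, nll, grad, hess, iters, conv = _newton(
        order, lp_fn, p, np.zeros(p), tol, max_iter, names, tie_method,
        coef_bound=coef_bound)
    if coef_bound is None and np.abs(beta).max() > 20.0:
        # the score flattens along a monotone-likelihood direction, so
        # Newton can "converge" at an absurd coefficient; call it out
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"coefficient for {worst!r} is diverging (monotone likelihood /"
            " perfect separation?)")
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    lp = X @ beta
    lp_mean = float(lp.mean())
    bt, bh, bv = breslow_baseline(time, event, lp, lp_mean)
    return CoxFit(
        names=names, beta=beta, decay_names=[], decay_effects={},
        params=beta.copy(), param_names=list(names), cov=cov, se=se,
        loglik=-nll, n_free_params=p, tie_method=tie_method,
        n=order.n, n_events=order.n_events, lp_mean=lp_mean,
        baseline_times=bt, baseline_cumhaz=bh, baseline_cumhaz_var=bv,
        iterations=iters, converged=conv,
        final_score_norm=float(np.abs(grad).max()),
    )


# ---------------------------------------------------------------------------
# decay Cox fit (iterative linearization / Gauss-Newton)
# ---------------------------------------------------------------------------

def _decay_jacobian(X, I, T, b1, b2):
    """Jacobian dLP/dtheta for theta = (beta, b1_1..b1_k, b2_1..b2_k)."""
    w = np.exp(-b2[None, :] * T)
    z1 = I * w                              # dLP/db1
    z2 = -(b1[None, :]) * I * T * w         # dLP/db2
    return np.hstack([X, z1, z2]), z1, z2


def _full_information(order, X, I, T, beta, b1, b2, tie_method, free2):
    """Observed information of the full nonlinear model at (beta, b1, b2).

    Chain rule: H = J' H_lp J + sum_i g_i d2LP_i/dtheta2, where the first
    part is the standard Cox Hessian with the Jacobian as working design and
    the second adds the curvature of the decay terms.  Columns for fixed
    beta2 parameters are dropped.
    """
    p, k = X.shape[1], I.shape[1]
    lp = decay_linear_predictor(X, beta, I, T, b1, b2)
    J, z1, z2 = _decay_jacobian(X, I, T, b1, b2)
    keep = np.concatenate([np.ones(p + k, bool), free2])
    J = J[:, keep]
    nll, g_lp, grad, hess = _cox_core(order, lp, J, tie_method)
    # curvature corrections for free beta2 columns
    w = np.exp(-b2[None, :] * T)
    col2 = p + k
    for j in range(k):
        if not free2[j]:
            continue
        d_b1b2 = -(I[:, j] * T[:, j] * w[:, j])            # d2LP/db1 db2
        d_b2b2 = b1[j] * I[:, j] * T[:, j] ** 2 * w[:, j]  # d2LP/db2^2
        c1 = float(g_lp @ d_b1b2)
        c2 = float(g_lp @ d_b2b2)
        jj = col2 + int(free2[:j].sum())
        hess[p + j, jj] += c1
        hess[jj, p + j] += c1
        hess[jj, jj] += c2
    return nll, grad, hess


def fit_decay_cox(time, event, X, I, T, names=None, decay_names=None,
                  init_beta2=None, tie_method="efron", tol=1e-7,
                  max_iter=100, nonneg_beta2=True, fix_beta2=False,
                  beta2_max=1.0, coef_bound=15.0):
    """Fit a Cox model with exponentially decaying indicator effects.

    Parameters
    ----------
    X : (n, p) array
        Linear covariates (may have zero columns).
    I, T : (n, k) arrays
        Indicator (0/1) and lag in months for each decay covariate.  ``T``
        is ignored where ``I`` is 0.
    init_beta2 : array, optional
        Starting decay rates (default all 0, i.e. constant effects).
    nonneg_beta2 : bool
        Project beta2 onto [0, inf) after each update (decay, not growth).
    beta2_max : float
        Upper bound on the decay rate (default 1/month, i.e. the effect is
        essentially gone within a few months).  Unbounded rates concentrate
        the indicator effect on a vanishing recent-onset subgroup and make
        the working fit separate.
    coef_bound : float
        Cap on |coefficient| in the working linear fits (default 15, i.e.
        HR ~ 3e6).  Rare indicators whose few carriers all have events are
        separable; the cap pins them at a finite boundary with an enormous
        standard error instead of aborting the fit.  ``None`` disables it.
    fix_beta2 : bool or boolean array
        Freeze beta2 at its initial value (per decay covariate); the frozen
        rates are not counted as free parameters.

    Algorithm: iterative linearization.  Given the current rates beta2, the
    nonlinear contribution b1*I*exp(-b2*t) is replaced by working covariates
    z1 = I*exp(-b2*t) and z2 = -b1*I*t*exp(-b2*t); a linear Cox model in
    (X, z1, z2) is fully refit; then b1 <- coef(z1), b2 <- b2 + coef(z2),
    with damping on the exact partial likelihood so the objective never
    deteriorates.  The reported covariance comes from the observed
    information of the full nonlinear model at the solution.
    """
    if X is None or (hasattr(X, "shape") and np.asarray(X).size == 0):
        X = np.empty((len(np.atleast_1d(time)), 0))
        names = []
    else:
        X, names = _check_design(X, names)
    I = np.atleast_2d(np.asarray(I, dtype=float).T).T
    T = np.atleast_2d(np.asarray(T, dtype=float).T).T
    n, p = X.shape
    k = I.shape[1]
    if decay_names is None:
        decay_names = [f"d{i}" for i in range(k)]
    decay_names = list(decay_names)
    for j in range(k):
        if not np.any(I[:, j] > 0):
            raise ValueError(f"decay covariate {decay_names[j]!r} has no "
                             "positive indicators")
    if np.any((I > 0) & (T < 0)):
        raise ValueError("lags must be non-negative where the indicator is 1")
    T = np.where(I > 0, T, 0.0)
    order = _SurvOrder(time, event)
    if order.n_events < 1:
        raise ValueError("at least one event is required")

    b2 = np.zeros(k) if init_beta2 is None else \
        np.array(init_beta2, dtype=float).reshape(k)
    if np.isscalar(fix_beta2) or isinstance(fix_beta2, bool):
        fixed2 = np.full(k, bool(fix_beta2))
    else:
        fixed2 = np.asarray(fix_beta2, dtype=bool).reshape(k)
    free2 = ~fixed2

    def full_nll(beta, b1, b2):
        lp = decay_linear_predictor(X, beta, I, T, b1, b2)
        return _cox_core(order, lp, None, tie_method)[0]

    # initialization: linear fit with z1 columns at the starting rates
    z1 = I * np.exp(-b2[None, :] * T)
    init_fit = fit_linear_cox(time, event, np.hstack([X, z1]),
                              names + [f"{nm}:z1" for nm in decay_names],
                              tie_method=tie_method, tol=tol,
                              max_iter=max_iter, coef_bound=coef_bound)
    beta = init_fit.beta[:p].copy()
    b1 = init_fit.beta[p:].copy()
    cur_nll = -init_fit.loglik
    trace = [("init", cur_nll, b1.copy(), b2.copy())]

    converged = bool(fixed2.all())
    iters = 0
    stall = 0
    if not converged:
        for iters in range(1, max_iter + 1):
            # a z2 column vanishes when b1 is (numerically) 0; skip its rate
            # update this iteration rather than feed a degenerate column in
            act2 = free2 & (np.abs(b1) > 1e-10)
            w = np.exp(-b2[None, :] * T)
            z1 = I * w
            z2 = (-(b1[None, :]) * I * T * w)[:, act2]
            Zw = np.hstack([X, z1, z2])
            wnames = (names + [f"{nm}:z1" for nm in decay_names]
                      + [f"{nm}:z2" for nm, f in zip(decay_names, act2) if f])
            try:
                wfit = fit_linear_cox(time, event, Zw, wnames,
                                      tie_method=tie_method, tol=max(tol, 1e-9),
                                      max_iter=max_iter,
                                      coef_bound=coef_bound)
            except (ConvergenceError, ValueError) as err:
                # a working column of one decay term separating (rare
                # indicator: the likelihood is flat or monotone in its rate)
                # does not invalidate the rest of the model — restart with
                # that term's rate fixed at 0 (a constant effect)
                m = re.search(r"'([^']+):z[12]'", str(err))
                if m is not None and m.group(1) in decay_names:
                    j = decay_names.index(m.group(1))
                    if not fixed2[j]:
                        new_fixed = fixed2.copy()
                        new_fixed[j] = True
                        init2 = (np.zeros(k) if init_beta2 is None
                                 else np.array(init_beta2,
                                               dtype=float).reshape(k))
                        init2[j] = 0.0
                        refit = fit_decay_cox(
                            time, event, X if p else None, I, T,
                            names=names if p else None,
                            decay_names=decay_names, init_beta2=init2,
                            tie_method=tie_method, tol=tol,
                            max_iter=max_iter, nonneg_beta2=nonneg_beta2,
                            fix_beta2=new_fixed, beta2_max=beta2_max,
                            coef_bound=coef_bound)
                        refit.trace = trace + [
                            (iters, cur_nll, "rate-fixed-at-0",
                             decay_names[j], str(err))] + refit.trace
                        return refit
                # the current damped iterate (or the init fit) is a valid
                # monotone point; leave the rest to the full-Newton polish
                trace.append((iters, cur_nll, "working-fit-stop", str(err)))
                break
            prop_beta = wfit.beta[:p]
            prop_b1 = wfit.beta[p:p + k]
            delta2 = np.zeros(k)
            delta2[act2] = wfit.beta[p + k:]
            prop_b2 = b2 + delta2
            if nonneg_beta2:
                prop_b2 = np.clip(prop_b2, 0.0, beta2_max)
            # damped acceptance on the exact partial likelihood
            alpha, accepted = 1.0, False
            for _ in range(12):
                nb = beta + alpha * (prop_beta - beta)
                n1 = b1 + alpha * (prop_b1 - b1)
                n2 = b2 + alpha * (prop_b2 - b2)
                if nonneg_beta2:
                    n2 = np.clip(n2, 0.0, beta2_max)
                nll_c = full_nll(nb, n1, n2)
                if nll_c <= cur_nll + 1e-12:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                nb, n1, n2, nll_c = beta, b1, b2, cur_nll
            delta = 0.0
            if p:
                delta = max(delta, float(np.abs(nb - beta).max()))
            delta = max(delta, float(np.abs(n1 - b1).max()),
                        float(np.abs(n2 - b2).max()))
            improvement = cur_nll - nll_c
            beta, b1, b2, cur_nll = nb, n1, n2, nll_c
            trace.append((iters, cur_nll, b1.copy(), b2.copy()))
            if delta < tol:
                converged = True
                break
            # objective stall: the likelihood is flat along the remaining
            # directions (common at a rate boundary); declare convergence
            if improvement < 1e-10:
                stall += 1
                if stall >= 3:
                    converged = True
                    break
            else:
                stall = 0
    # polish on the full nonlinear likelihood: the Gauss-Newton loop can
    # two-cycle or creep along a flat ridge with a slowly shrinking
    # amplitude, so the solution is finished with bound-constrained
    # L-BFGS-B on the exact partial likelihood (analytic gradient via the
    # chain rule), which also rescues a loop that exhausted its iterations
    n_free = p + k + int(free2.sum())
    free_pos = np.flatnonzero(free2)

    def _nll_grad(theta):
        beta_ = theta[:p]
        b1_ = theta[p:p + k]
        b2_ = b2.copy()
        b2_[free_pos] = theta[p + k:]
        lp = decay_linear_predictor(X, beta_, I, T, b1_, b2_)
        nllv, g_lp, _, _ = _cox_core(order, lp, None, tie_method)
        J, _, _ = _decay_jacobian(X, I, T, b1_, b2_)
        keep = np.concatenate([np.ones(p + k, bool), free2])
        return nllv, J[:, keep].T @ g_lp

    lin_bound = (None, None) if coef_bound is None \
        else (-coef_bound, coef_bound)
    rate_bound = (0.0 if nonneg_beta2 else None,
                  beta2_max if nonneg_beta2 else None)
    bounds = [lin_bound] * (p + k) + [rate_bound] * int(free2.sum())
    x0 = np.concatenate([beta, b1, b2[free_pos]])
    from scipy import optimize
    res = optimize.minimize(
        _nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
    if res.fun <= cur_nll + 1e-9:
        beta = res.x[:p].copy()
        b1 = res.x[p:p + k].copy()
        b2[free_pos] = res.x[p + k:]
        cur_nll = float(res.fun)
        converged = True
        trace.append(("polish", cur_nll, b1.copy(), b2.copy()))

    if not converged:
        err = ConvergenceError(
            f"iterative linearization did not converge in {max_iter} outer "
            f"iterations; last nll={cur_nll:.6f}, trace length {len(trace)}")
        err.trace = trace
        raise err

    # covariance from the observed information of the full nonlinear model
    nll, grad, hess = _full_information(order, X, I, T, beta, b1, b2,
                                        tie_method, free2)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    # assemble per-effect 2x2 covariance blocks
    effects = {}
    free_idx = {j: p + k + int(free2[:j].sum()) for j in range(k) if free2[j]}
    for j, nm in enumerate(decay_names):
        blk = np.full((2, 2), np.nan)
        blk[0, 0] = cov[p + j, p + j]
        if free2[j]:
            fj = free_idx[j]
            blk[0, 1] = blk[1, 0] = cov[p + j, fj]
            blk[1, 1] = cov[fj, fj]
        else:
            blk[0, 1] = blk[1, 0] = 0.0
            blk[1, 1] = 0.0
        effects[nm] = DecayEffect(float(b1[j]), float(b2[j]), blk)

    params = np.concatenate([beta, b1, b2[free2]])
    pnames = (names + [f"{nm}:beta1" for nm in decay_names]
              + [f"{nm}:beta2" for nm, f in zip(decay_names, free2) if f])
    lp = decay_linear_predictor(X, beta, I, T, b1, b2)
    lp_mean = float(lp.mean())
    bt, bh, bv = breslow_baseline(time, event, lp, lp_mean)
    # score of active (interior) parameters; at a beta2=0 boundary the
    # projected solution may have positive score in the constrained direction
    active = np.ones(n_free, bool)
    if nonneg_beta2:
        for j, fj in free_idx.items():
            if (b2[j] == 0.0 and grad[fj] > 0) or \
                    (b2[j] >= beta2_max and grad[fj] < 0):
                active[fj] = False
    score_norm = float(np.abs(grad[active]).max()) if active.any() else 0.0
    return CoxFit(
        names=names, beta=beta, decay_names=decay_names, decay_effects=effects,
        params=params, param_names=pnames, cov=cov, se=se,
        loglik=-nll, n_free_params=n_free, tie_method=tie_method,
        n=order.n, n_events=order.n_events, lp_mean=lp_mean,
        baseline_times=bt, baseline_cumhaz=bh, baseline_cumhaz_var=bv,
        iterations=iters, converged=converged,
        final_score_norm=score_norm, trace=trace,
    )


# ---------------------------------------------------------------------------
# effect curves
# ---------------------------------------------------------------------------

def hr_at_lag(effect: DecayEffect, t, level=0.95):
    """Hazard ratio of a decay effect at lag ``t`` months, with delta-method CI.

    HR(t) = exp(b1*exp(-b2*t)); the variance of g = b1*exp(-b2*t) is
    g' Sigma g' with g' = (exp(-b2*t), -b1*t*exp(-b2*t)).
    """
    t = float(t)
    if t < 0:
        raise ValueError("lag must be non-negative")
    w = np.exp(-effect.beta2 * t)
    g = effect.beta1 * w
    if effect.cov is None:
        return float(np.exp(g)), (np.nan, np.nan)
    gp = np.array([w, -effect.beta1 * t * w])
    var = float(gp @ effect.cov @ gp)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.exp(g)), (float(np.exp(g - half)), float(np.exp(g + half)))


def solve_decay_rate(hr0, hr_at, lag_months=36.0):
    """Decay rate beta2 such that HR(0)=hr0 and HR(lag)=hr_at.

    Inverts hr_at = exp(log(hr0)*exp(-beta2*lag)); both HRs must be on the
    same side of 1 and |log hr_at| <= |log hr0|.
    """
    l0, l1 = np.log(hr0), np.log(hr_at)
    if l0 == 0 or l1 / l0 <= 0 or abs(l1) > abs(l0):
        raise ValueError("HRs incompatible with a non-negative decay rate")
    return float(np.log(l0 / l1) / lag_months)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_residuals(time, event, lp, Z, tie_method="efron"):
    """Schoenfeld residuals (one row per event, in event-time order).

    Residual for an event at time tau: z_i - E[Z | risk set at tau] with the
    risk-set mean weighted by exp(lp).  Under Efron ties each of the d tied
    events uses its own downweighted mean (l = 0..d-1).
    """
    order = _SurvOrder(time, event)
    Z = np.asarray(Z, dtype=float)
    lp = np.asarray(lp, dtype=float)
    lps = (lp - lp.max())[order.order]
    eta = np.exp(lps)
    Zs = Z[order.order]
    S = _rev_cumsum(eta)[order.risk_start]
    Sz = _rev_cumsum(eta[:, None] * Zs, axis=0)[order.risk_start]
    eta_e = eta[order.event_pos]
    Ze = Zs[order.event_pos]
    Tsum = np.add.reduceat(eta_e, order.group_starts)
    Tz = np.add.reduceat(eta_e[:, None] * Ze, order.group_starts, axis=0)
    resid = np.empty_like(Ze)
    times = order.t[order.event_pos]
    for i in range(Ze.shape[0]):
        j = order.event_group[i]
        if tie_method == "efron" and order.d[j] > 1:
            l = i - order.group_starts[j]
            f = l / order.d[j]
            mu = (Sz[j] - f * Tz[j]) / (S[j] - f * Tsum[j])
        else:
            mu = Sz[j] / S[j]
        resid[i] = Ze[i] - mu
    return times, resid


def schoenfeld_ph_test(fit: CoxFit, time, event, X=None, I=None, T=None,
                       transform="identity"):
    """Grambsch-Therneau score test for proportional hazards.

    Scaled Schoenfeld residuals are regressed on (transformed) event time;
    decay terms are represented by their working covariate I*exp(-b2*t) held
    fixed at the solution.  Returns a dict with per-covariate chi-square
    statistics/p-values and a global test.
    """
    order = _SurvOrder(time, event)
    if order.n_events < 3:
        raise ValueError("at least 3 events are required for the PH test")
    cols, Zs = [], []
    if len(fit.names):
        Xa = np.asarray(X, dtype=float)
        Zs.append(Xa)
        cols += list(fit.names)
    if len(fit.decay_names):
        Ia = np.atleast_2d(np.asarray(I, dtype=float).T).T
        Ta = np.atleast_2d(np.asarray(T, dtype=float).T).T
        for kk, nm in enumerate(fit.decay_names):
            eff = fit.decay_effects[nm]
            Zs.append((Ia[:, kk] * np.exp(-eff.beta2 * Ta[:, kk]))[:, None])
            cols.append(nm)
    Z = np.hstack(Zs)
    lp = fit.linear_predictor(X=X, I=I, T=T)
    times, resid = schoenfeld_residuals(time, event, lp, Z, fit.tie_method)

    if transform == "identity":
        g = times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(times).astype(float)
    elif transform == "km":
        # left-continuous KM of the event-time distribution
        from .incidence import km_survival
        st, sv = km_survival(time, event)
        g = 1.0 - np.interp(times, st, sv)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()

    d = resid.shape[0]
    _, _, _, info = _cox_core(order, lp, Z, fit.tie_method)
    vbar = info / d
    vinv = np.linalg.pinv(vbar)
    w = g @ resid                                  # (p,)
    gss = float((g ** 2).sum())
    scaled = resid @ vinv
    out = {}
    for j, nm in enumerate(cols):
        num = float((g * scaled[:, j]).sum()) ** 2
        den = gss * float(vinv[j, j])
        stat = num / den if den > 0 else np.nan
        out[nm] = {"chi2": stat, "p": float(stats.chi2.sf(stat, 1)),
                   "df": 1}
    global_stat = float(w @ vinv @ w) / gss
    out["GLOBAL"] = {"chi2": global_stat,
                     "p": float(stats.chi2.sf(global_stat, len(cols))),
                     "df": len(cols)}
    return out
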