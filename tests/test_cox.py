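"""Partial likelihood, linear/decay Cox fits, effect curves, PH diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdacrisk.cox import (ConvergenceError, DecayEffect, breslow_baseline,
                          decay_linear_predictor, fit_decay_cox,
                          fit_linear_cox, hr_at_lag,
                          neg_log_partial_likelihood, schoenfeld_ph_test,
                          schoenfeld_residuals, solve_decay_rate)

from helpers import brute_force_nll, simulate_cox_data, simulate_decay_data


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

def test_single_event_uniform_risk_set():
    # one event among three at-risk subjects, all at the same hazard
    time = np.array([5.0, 8.0, 9.0])
    event = np.array([1, 0, 0])
    val = neg_log_partial_likelihood(time, event, np.zeros(3))
    assert val == pytest.approx(np.log(3.0), abs=1e-12)


@pytest.mark.parametrize("ties", ["efron", "breslow"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_brute_force_risk_set_products(ties, seed):
    rng = np.random.default_rng(seed)
    n = 8
    time = rng.integers(1, 6, n).astype(float)      # forces ties
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    lp = rng.normal(0, 1.5, n)
    mine = neg_log_partial_likelihood(time, event, lp, ties)
    oracle = brute_force_nll(time, event, lp, ties)
    assert mine == pytest.approx(oracle, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-30, 30), seed=st.integers(0, 100))
def test_shift_invariance(shift, seed):
    rng = np.random.default_rng(seed)
    time = rng.exponential(10, 12)
    event = rng.integers(0, 2, 12)
    event[0] = 1
    lp = rng.normal(size=12)
    a = neg_log_partial_likelihood(time, event, lp)
    b = neg_log_partial_likelihood(time, event, lp + shift)
    assert a == pytest.approx(b, abs=1e-8)


def test_all_censored_is_zero_with_warning():
    with pytest.warns(UserWarning, match="no events"):
        val = neg_log_partial_likelihood(np.array([1.0, 2.0]),
                                         np.array([0, 0]), np.zeros(2))
    assert val == 0.0


# ---------------------------------------------------------------------------
# linear fit
# ---------------------------------------------------------------------------

def test_linear_fit_matches_lifelines_reference():
    from lifelines import CoxPHFitter
    time, event, X = simulate_cox_data(100, [0.5, -0.3], seed=3,
                                       day_ties=True)
    fit = fit_linear_cox(time, event, X, ["a", "b"])
    df = pd.DataFrame(X, columns=["a", "b"])
    df["T"], df["E"] = time, event
    ref = CoxPHFitter().fit(df, "T", "E")
    assert np.abs(fit.beta - ref.params_.values).max() < 1e-6
    assert np.abs(fit.se - ref.standard_errors_.values).max() < 1e-6
    assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-8)


def test_two_group_hazard_ratio_recovery():
    rng = np.random.default_rng(7)
    n = 5000
    g = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(30, n) / np.exp(np.log(2.0) * g)
    time = np.minimum(t, 60.0)
    event = (t <= 60.0).astype(int)
    fit = fit_linear_cox(time, event, g.reshape(-1, 1), ["group"])
    assert abs(fit.beta[0] - np.log(2.0)) < 3 * fit.se[0]


def test_zero_variance_column_is_named():
    time, event, X = simulate_cox_data(50, [0.3], seed=1)
    X = np.column_stack([X, np.zeros(50)])
    with pytest.raises(ValueError, match="deadcol"):
        fit_linear_cox(time, event, X, ["ok", "deadcol"])


def test_perfect_separation_raises_naming_covariate():
    # the indicator carrier has the first event in every risk set it joins
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 0, 1, 0, 0])
    x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    with pytest.raises(ConvergenceError, match="sep"):
        fit_linear_cox(time, event, x.reshape(-1, 1), ["sep"])


def test_baseline_is_nelson_aalen_at_null():
    rng = np.random.default_rng(9)
    time = rng.integers(1, 20, 200).astype(float)
    event = rng.integers(0, 2, 200)
    bt, bh, _ = breslow_baseline(time, event, np.zeros(200), lp_mean=0.0)
    # hand Nelson-Aalen
    na = 0.0
    for t, h in zip(bt, np.diff(np.concatenate([[0.0], bh]))):
        d = ((time == t) & (event == 1)).sum()
        r = (time >= t).sum()
        na = d / r
        assert h == pytest.approx(na, abs=1e-12)


def test_efron_equals_breslow_without_ties():
    time, event, X = simulate_cox_data(300, [0.4], seed=5)
    fe = fit_linear_cox(time, event, X, tie_method="efron")
    fb = fit_linear_cox(time, event, X, tie_method="breslow")
    assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-8)


def test_aic_improves_with_predictive_covariate():
    time, event, X = simulate_cox_data(4000, [0.8], seed=12, day_ties=True)
    rng = np.random.default_rng(0)
    noise = rng.normal(size=(4000, 1))
    small = fit_linear_cox(time, event, noise, ["noise"])
    big = fit_linear_cox(time, event, np.hstack([noise, X]), ["noise", "x"])
    assert big.aic < small.aic


# ---------------------------------------------------------------------------
# decay fit
# ---------------------------------------------------------------------------

def test_decay_free_limit_matches_linear_fit():
    time, event, _, I, T = simulate_decay_data(4000, 1.5, 0.02, seed=21)
    fd = fit_decay_cox(time, event, None, I, T, decay_names=["ind"],
                       fix_beta2=True)
    fl = fit_linear_cox(time, event, I.reshape(-1, 1), ["ind"])
    eff = fd.decay_effects["ind"]
    assert eff.beta2 == 0.0
    assert eff.beta1 == pytest.approx(fl.beta[0], abs=1e-6)
    assert fd.loglik == pytest.approx(fl.loglik, abs=1e-8)


def test_decay_parameter_recovery_moderate_n():
    time, event, X, I, T = simulate_decay_data(
        20000, 2.0, 0.02, seed=33, scale=900.0, with_age=True)
    assert event.sum() >= 500
    fit = fit_decay_cox(time, event, X, I, T, names=["age"],
                        decay_names=["ind"])
    eff = fit.decay_effects["ind"]
    se1, se2 = np.sqrt(eff.cov[0, 0]), np.sqrt(eff.cov[1, 1])
    assert abs(eff.beta1 - 2.0) < 3 * se1
    assert abs(eff.beta2 - 0.02) < 3 * se2


def test_loglik_equals_partial_likelihood_at_solution():
    time, event, X, I, T = simulate_decay_data(4000, 1.5, 0.03, seed=4,
                                               with_age=True)
    fit = fit_decay_cox(time, event, X, I, T, names=["age"],
                        decay_names=["ind"])
    eff = fit.decay_effects["ind"]
    lp = decay_linear_predictor(X, fit.beta, I, T, eff.beta1, eff.beta2)
    assert -fit.loglik == pytest.approx(
        neg_log_partial_likelihood(time, event, lp), abs=1e-9)


def test_solution_is_stationary_by_numerical_differentiation():
    time, event, X, I, T = simulate_decay_data(3000, 1.5, 0.03, seed=6,
                                               with_age=True)
    fit = fit_decay_cox(time, event, X, I, T, names=["age"],
                        decay_names=["ind"], tol=1e-9)
    eff = fit.decay_effects["ind"]
    theta = np.array([fit.beta[0], eff.beta1, eff.beta2])

    def nll_at(th):
        lp = decay_linear_predictor(X, th[:1], I, T, th[1], th[2])
        return neg_log_partial_likelihood(time, event, lp)

    for j in range(3):
        h = 1e-5 * max(1.0, abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        deriv = (nll_at(up) - nll_at(dn)) / (2 * h)
        assert abs(deriv) < 5e-3          # numerical-difference resolution


def test_decay_with_no_positive_indicator_errors():
    time, event, X = simulate_cox_data(100, [0.2], seed=8)
    with pytest.raises(ValueError, match="positive"):
        fit_decay_cox(time, event, X, np.zeros(100), np.zeros(100),
                      decay_names=["empty"])


# ---------------------------------------------------------------------------
# effect curves
# ---------------------------------------------------------------------------

def test_hr_at_lag_zero_uses_beta1_variance_only():
    eff = DecayEffect(np.log(2.0), 0.05, np.array([[0.04, 0.01],
                                                   [0.01, 0.02]]))
    hr, (lo, hi) = hr_at_lag(eff, 0.0)
    assert hr == pytest.approx(2.0)
    z = 1.959963984540054
    assert lo == pytest.approx(np.exp(np.log(2.0) - z * 0.2), rel=1e-9)
    assert hi == pytest.approx(np.exp(np.log(2.0) + z * 0.2), rel=1e-9)


def test_hr_constant_when_rate_zero():
    eff = DecayEffect(0.7, 0.0, np.eye(2) * 0.01)
    assert hr_at_lag(eff, 0.0)[0] == pytest.approx(hr_at_lag(eff, 120.0)[0])


def test_current_and_three_year_presentation_pair():
    # HR 7.26 at diagnosis decaying to 6.63 three years in the past
    b2 = solve_decay_rate(7.26, 6.63, 36.0)
    eff = DecayEffect(np.log(7.26), b2, np.eye(2) * 1e-4)
    hr36, _ = hr_at_lag(eff, 36.0)
    assert hr36 == pytest.approx(6.63, abs=1e-9)


def test_negative_lag_rejected():
    eff = DecayEffect(1.0, 0.01, np.eye(2))
    with pytest.raises(ValueError):
        hr_at_lag(eff, -1.0)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def test_schoenfeld_residuals_sum_to_zero():
    time, event, X = simulate_cox_data(500, [0.5, -0.2], seed=10,
                                       day_ties=True)
    fit = fit_linear_cox(time, event, X, ["a", "b"])
    _, resid = schoenfeld_residuals(time, event, X @ fit.beta, X,
                                    fit.tie_method)
    assert np.abs(resid.sum(axis=0)).max() < 1e-6


def test_ph_test_matches_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test
    time, event, X = simulate_cox_data(400, [0.6, -0.3], seed=13)
    fit = fit_linear_cox(time, event, X, ["a", "b"])
    mine = schoenfeld_ph_test(fit, time, event, X=X, transform="rank")

    df = pd.DataFrame(X, columns=["a", "b"])
    df["T"], df["E"] = time, event
    ref_fit = CoxPHFitter().fit(df, "T", "E")
    ref = proportional_hazard_test(ref_fit, df, time_transform="rank")
    for name in ("a", "b"):
        ref_stat = float(ref.summary.loc[name, "test_statistic"])
        assert mine[name]["chi2"] == pytest.approx(ref_stat, rel=1e-3)


def test_ph_test_type_one_error_near_nominal():
    rejections = 0
    for rep in range(200):
        time, event, X = simulate_cox_data(150, [0.5], seed=1000 + rep)
        fit = fit_linear_cox(time, event, X, ["x"])
        res = schoenfeld_ph_test(fit, time, event, X=X)
        rejections += res["x"]["p"] < 0.05
    # 3 binomial SDs around 5% of 200
    assert 1 <= rejections <= 20


def test_ph_test_detects_time_varying_effect():
    rng = np.random.default_rng(77)
    n = 2000
    x = rng.normal(size=(n, 1))
    # effect reverses over time: early hazard up, late hazard down
    u = rng.random(n)
    t = np.empty(n)
    early = x[:, 0] * 0.8
    t = rng.exponential(20, n) / np.exp(early)
    flip = t > 15
    t[flip] = 15 + rng.exponential(20, flip.sum()) * np.exp(early[flip])
    time = np.minimum(t, 60.0)
    event = (t <= 60.0).astype(int)
    fit = fit_linear_cox(time, event, x, ["x"])
    res = schoenfeld_ph_test(fit, time, event, X=x)
    assert res["x"]["p"] < 0.01


def test_ph_test_requires_three_events():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    event = np.array([1, 1, 0, 0, 0])
    x = np.array([[0.2], [-0.1], [0.3], [-0.2], [0.1]])
    fit = fit_linear_cox(time, event, x, ["x"])
    with pytest.raises(ValueError, match="3 events"):
        schoenfeld_ph_test(fit, time, event, X=x)
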