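import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cfsurv.stats import (FitError, SurvivalCurve, chi_square_2x2, fit_cox,
                          fit_logistic, kaplan_meier, log_rank_test,
                          rmst_from_curve)

# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def test_km_all_events_equals_empirical_survival():
    curve = kaplan_meier([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(curve.surv, [2 / 3, 1 / 3, 0.0])


def test_km_hand_example(km_hand_example):
    times, events = km_hand_example
    curve = kaplan_meier(times, events)
    np.testing.assert_allclose(curve.evaluate([2, 6]), [2 / 3, 1 / 3])


def test_km_all_censored_is_one():
    curve = kaplan_meier([1, 5, 9], [0, 0, 0])
    assert np.all(curve.surv == 1.0)


def test_km_no_censoring_matches_one_minus_ecdf(rng):
    times = rng.exponential(10, size=40)
    curve = kaplan_meier(times, np.ones(40, dtype=int))
    for t in curve.times:
        assert curve.evaluate(t) == pytest.approx((times > t).mean())


def test_km_unit_weights_equal_unweighted(rng):
    times = rng.exponential(10, size=50)
    events = rng.integers(0, 2, size=50)
    events[0] = 1
    a = kaplan_meier(times, events)
    b = kaplan_meier(times, events, weights=np.ones(50))
    np.testing.assert_array_equal(a.surv, b.surv)


def test_km_errors():
    with pytest.raises(ValueError):
        kaplan_meier([], [])
    with pytest.raises(ValueError):
        kaplan_meier([1, 2], [1, 1], weights=[-1, 1])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_log_rank_identical_groups_is_null():
    times = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
    events = np.array([1, 0, 1, 1, 1, 0, 1, 1])
    groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    stat, p = log_rank_test(groups, times, events)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_log_rank_single_group_errors():
    with pytest.raises(ValueError):
        log_rank_test([1, 1, 1], [1, 2, 3], [1, 1, 1])


def test_log_rank_permutation_type_i_error(rng):
    # permutation null calibration on a fixed 40-subject cohort
    times = rng.exponential(12, size=40)
    events = (rng.uniform(size=40) < 0.8).astype(int)
    labels = np.array([0] * 20 + [1] * 20)
    rejections = 0
    n_perm = 2000
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, p = log_rank_test(perm, times, events)
        rejections += p < 0.05
    assert 0.03 < rejections / n_perm < 0.07


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _breslow_pll(beta, x, times, events):
    """Independent partial log-likelihood (single covariate, Breslow ties)."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dying = (times == t) & (events == 1)
        at_risk = times >= t
        ll += beta * x[dying].sum()
        ll -= dying.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def test_cox_matches_grid_search_oracle():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 1, 1, 1, 0])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    grid = np.arange(-3, 3 + 1e-9, 1e-4)
    pll = [_breslow_pll(b, x, times, events) for b in grid]
    beta_star = grid[int(np.argmax(pll))]
    fit = fit_cox(x.reshape(-1, 1), times, events)
    assert fit.beta[0] == pytest.approx(beta_star, abs=1e-3)


def test_cox_constant_column_flagged():
    with pytest.raises(FitError):
        fit_cox(np.ones((6, 1)), [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])


def test_cox_no_events_flagged():
    with pytest.raises(FitError):
        fit_cox(np.arange(6).reshape(-1, 1), np.arange(1.0, 7.0), np.zeros(6, int))


def test_cox_duplication_scales_se(rng):
    n = 80
    x = rng.normal(size=(n, 2))
    times = rng.exponential(np.exp(-x[:, 0] * 0.5), size=n)
    events = np.ones(n, dtype=int)
    fit1 = fit_cox(x, times, events)
    fit2 = fit_cox(np.vstack([x, x]), np.concatenate([times, times]),
                   np.concatenate([events, events]))
    np.testing.assert_allclose(fit2.beta, fit1.beta, atol=1e-6)
    np.testing.assert_allclose(fit2.se, fit1.se / np.sqrt(2), rtol=1e-4)


def test_cox_replication_invariance(rng):
    n = 60
    x = rng.normal(size=(n, 1))
    times = rng.exponential(np.exp(-0.7 * x[:, 0]), size=n)
    events = np.ones(n, dtype=int)
    fit1 = fit_cox(x, times, events)
    k = 3
    fitk = fit_cox(np.tile(x, (k, 1)), np.tile(times, k), np.tile(events, k))
    np.testing.assert_allclose(fitk.beta, fit1.beta, atol=1e-8)


def test_cox_baseline_monotone_and_predictions_valid(small_cohort):
    from cfsurv.encoding import CovariateEncoder
    X = CovariateEncoder().fit_transform(small_cohort.covariates)
    X = X.loc[:, X.nunique() > 1]
    fit = fit_cox(X, small_cohort.time, small_cohort.event)
    assert np.all(np.diff(fit.baseline_hazard) >= 0)
    assert fit.baseline_hazard[0] >= 0
    S = fit.predict_survival(X.to_numpy()[:5])
    assert np.all((S >= 0) & (S <= 1))
    assert np.all(np.diff(S, axis=1) <= 1e-12)


def test_cox_prediction_matches_lifelines(small_cohort):
    # the shifted Breslow baseline must reproduce lifelines' own predictions
    from lifelines import CoxPHFitter
    from cfsurv.encoding import CovariateEncoder
    X = CovariateEncoder().fit_transform(small_cohort.covariates)
    X = X.loc[:, X.nunique() > 1]
    fit = fit_cox(X, small_cohort.time, small_cohort.event)
    df = X.copy()
    df["t"] = small_cohort.time
    df["e"] = small_cohort.event
    cph = CoxPHFitter().fit(df, "t", "e")
    ours = fit.predict_survival(X.to_numpy()[:3], grid=fit.baseline_times)
    theirs = cph.predict_survival_function(X.iloc[:3], times=fit.baseline_times)
    np.testing.assert_allclose(ours, theirs.to_numpy().T, atol=1e-6)


# ---------------------------------------------------------------------------
# Logistic
# ---------------------------------------------------------------------------

def test_logistic_2x2_closed_form():
    a, b, c, d = 20, 10, 5, 15   # (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0)
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    fit = fit_logistic(x.reshape(-1, 1), y)
    assert np.exp(fit.beta[1]) == pytest.approx((a * d) / (b * c), rel=1e-6)


def test_logistic_null_slopes(rng):
    n = 5000
    X = rng.normal(size=(n, 4))
    y = (rng.uniform(size=n) < 0.5).astype(int)
    fit = fit_logistic(X, y)
    z = np.abs(fit.beta[1:] / fit.se[1:])
    assert np.all(z < 3)


def test_logistic_separation_flagged():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    with pytest.raises(FitError):
        fit_logistic(x.reshape(-1, 1), y)


def test_logistic_one_class_errors():
    with pytest.raises(FitError):
        fit_logistic(np.arange(4.0).reshape(-1, 1), np.zeros(4, int))


# ---------------------------------------------------------------------------
# Chi-square and RMST
# ---------------------------------------------------------------------------

def test_chi_square_mortality_table_significant():
    # dead/censored counts per arm: RT 1680/409, CRT 13844/4510
    stat, p = chi_square_2x2([[1680, 409], [13844, 4510]])
    assert p < 0.001


def test_chi_square_equal_proportions_null():
    stat, p = chi_square_2x2([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_equals_squared_z():
    table = np.array([[30, 70], [45, 55]])
    stat, _ = chi_square_2x2(table)
    p1, p2 = table[0, 0] / 100, table[1, 0] / 100
    pool = table[:, 0].sum() / 200
    z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
    assert stat == pytest.approx(z**2, rel=1e-10)


def test_chi_square_zero_margin_errors():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_rmst_constant_curve():
    curve = SurvivalCurve(np.array([100.0]), np.array([1.0]))
    assert rmst_from_curve(curve, 60.0) == pytest.approx(60.0)


def test_rmst_hand_example(km_hand_example):
    curve = kaplan_meier(*km_hand_example)
    assert rmst_from_curve(curve, 6.0) == pytest.approx(2 + 4 * 2 / 3, abs=1e-12)


def test_rmst_zero_tau_and_negative():
    curve = SurvivalCurve(np.array([1.0]), np.array([0.5]))
    assert rmst_from_curve(curve, 0.0) == 0.0
    with pytest.raises(ValueError):
        rmst_from_curve(curve, -1.0)


@pytest.mark.parametrize("tau", [1.0, 3.0, 10.0, 50.0])
def test_rmst_monotone_in_tau_and_bounded(tau, km_hand_example):
    curve = kaplan_meier(*km_hand_example)
    r = rmst_from_curve(curve, tau)
    assert 0 <= r <= tau
    assert r <= rmst_from_curve(curve, tau + 5.0)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def survival_data(draw, max_n=30):
    n = draw(st.integers(2, max_n))
    times = draw(st.lists(st.floats(0.1, 100.0), min_size=n, max_size=n))
    events = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if sum(events) == 0:
        events[0] = 1
    return np.array(times), np.array(events)


@given(survival_data())
@settings(max_examples=60, deadline=None)
def test_km_curve_invariants_property(data):
    times, events = data
    curve = kaplan_meier(times, events)
    assert np.all((curve.surv >= 0) & (curve.surv <= 1))
    assert np.all(np.diff(curve.surv) <= 1e-12)
    assert np.all(np.diff(curve.times) > 0)


@given(survival_data(), st.floats(0.1, 150.0))
@settings(max_examples=60, deadline=None)
def test_rmst_bounded_property(data, tau):
    times, events = data
    curve = kaplan_meier(times, events)
    r = rmst_from_curve(curve, tau)
    assert 0 <= r <= tau + 1e-9
    assert r <= rmst_from_curve(curve, tau * 1.5) + 1e-9
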