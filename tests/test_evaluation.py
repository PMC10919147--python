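import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cfsurv.encoding import CovariateEncoder
from cfsurv.evaluation import (arm_share_percent, cohort_summary,
                               mortality_percent, performance_by_arm,
                               recommendation_effect, within_group_comparison)
from cfsurv.ite import compute_ite_and_recommend
from cfsurv.learners import fit_tlearner
from cfsurv.synthetic import OracleModel, default_params, generate_cohort


@pytest.fixture(scope="module")
def eval_setup():
    p = default_params(n=2000, seed=61)
    cohort = generate_cohort(p)
    oracle = OracleModel(p, horizon=120.0)
    res = compute_ite_and_recommend(oracle, cohort.covariates,
                                    actual_arm=cohort.arm, horizon=120.0)
    X = CovariateEncoder().fit_transform(cohort.covariates)
    X = X.loc[:, X.nunique() > 1]
    return p, cohort, res, X


# ---------------------------------------------------------------------------
# recommendation_effect
# ---------------------------------------------------------------------------

def test_nnt_formula_identity(eval_setup):
    _, cohort, res, X = eval_setup
    rep = recommendation_effect(cohort.time, cohort.event,
                                res["consistent"], X, n_boot=50, seed=0)
    if rep.nnt_defined:
        assert rep.nnt * rep.drmst == pytest.approx(rep.rmst_consistent, rel=1e-12)


def test_oracle_recommender_protective(eval_setup):
    _, cohort, res, X = eval_setup
    rep = recommendation_effect(cohort.time, cohort.event,
                                res["consistent"], X, n_boot=50, seed=0)
    assert rep.hr < 1
    assert rep.hr_ci[1] < 1
    assert rep.drmst > 0


def test_hr_equals_weighted_fit_with_unit_weights(eval_setup):
    _, cohort, res, X = eval_setup
    from cfsurv.stats import fit_cox
    ind = pd.DataFrame({"consistent": res["consistent"].astype(float)})
    plain = fit_cox(ind, cohort.time, cohort.event)
    forced = fit_cox(ind, cohort.time, cohort.event,
                     weights=np.ones(len(cohort)))
    assert plain.beta[0] == pytest.approx(forced.beta[0], abs=1e-12)


def test_drmst_antisymmetric(eval_setup):
    _, cohort, res, X = eval_setup
    rep = recommendation_effect(cohort.time, cohort.event,
                                res["consistent"], X, n_boot=10, seed=0)
    rep_sw = recommendation_effect(cohort.time, cohort.event,
                                   1 - res["consistent"], X, n_boot=10, seed=0)
    assert rep_sw.drmst == pytest.approx(-rep.drmst, abs=1e-12)


def test_null_labels_cover_one(eval_setup):
    # random consistency labels: HR CI covers 1 in most permutations
    _, cohort, res, X = eval_setup
    rng = np.random.default_rng(4)
    sub = np.sort(rng.choice(len(cohort), size=800, replace=False))
    labels = res["consistent"].to_numpy()[sub]
    Xs = X.iloc[sub]
    covered = 0
    n_perm = 40
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        rep = recommendation_effect(cohort.time[sub], cohort.event[sub],
                                    perm, Xs, n_boot=0, seed=0)
        covered += rep.hr_ci[0] <= 1 <= rep.hr_ci[1]
    assert covered / n_perm >= 0.93


def test_no_effect_drmst_near_zero(rng):
    n = 2000
    times = rng.exponential(14, size=n)
    events = (rng.uniform(size=n) < 0.8).astype(int)
    consistent = (rng.uniform(size=n) < 0.5).astype(int)
    X = pd.DataFrame({"a": rng.normal(size=n)})
    rep = recommendation_effect(times, events, consistent, X, n_boot=0, seed=0)
    assert abs(rep.drmst) < 1.0


def test_single_group_errors(eval_setup):
    _, cohort, _, X = eval_setup
    with pytest.raises(ValueError):
        recommendation_effect(cohort.time, cohort.event,
                              np.ones(len(cohort), int), X)


def test_negative_drmst_flags_nnt(rng):
    # construct consistent group with clearly worse survival
    n = 800
    consistent = np.repeat([1, 0], n // 2)
    times = np.where(consistent == 1, rng.exponential(5, n), rng.exponential(25, n))
    events = np.ones(n, int)
    X = pd.DataFrame({"a": rng.normal(size=n)})
    rep = recommendation_effect(times, events, consistent, X, n_boot=0, seed=0)
    assert not rep.nnt_defined
    assert np.isnan(rep.nnt)


# ---------------------------------------------------------------------------
# within-group comparison
# ---------------------------------------------------------------------------

def test_within_group_oracle_shows_crt_benefit(eval_setup):
    _, cohort, res, _ = eval_setup
    out = within_group_comparison(cohort.time, cohort.event, cohort.arm,
                                  res["recommended"].to_numpy())
    assert out["rcrt"]["testable"]
    assert out["rcrt"]["p"] < 0.05
    assert set(out["rcrt"]["curves"]) == {"rt", "crt"}


def test_within_group_single_arm_flagged(rng):
    times = rng.exponential(10, 40)
    events = np.ones(40, int)
    arms = np.ones(40, int)          # only CRT patients
    recommended = np.zeros(40, int)  # all recommended RT
    out = within_group_comparison(times, events, arms, recommended)
    assert not out["rrt"]["testable"]
    assert out["rrt"]["p"] is None
    assert out["rcrt"]["n"] == 0


def test_within_group_null_calibration(rng):
    # permuted arms within RCRT: p-values approximately uniform
    n = 300
    times = rng.exponential(12, n)
    events = (rng.uniform(size=n) < 0.8).astype(int)
    recommended = np.ones(n, int)
    pvals = []
    for _ in range(200):
        arms = (rng.uniform(size=n) < 0.5).astype(int)
        out = within_group_comparison(times, events, arms, recommended)
        pvals.append(out["rcrt"]["p"])
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# performance_by_arm
# ---------------------------------------------------------------------------

def test_performance_oracle_beats_noise():
    # balanced arms and amplified prognostic coefficients so the true
    # risk score carries comfortably more than chance discrimination
    p = default_params(n=2000, seed=62, propensity_target_mean=0.5)
    p.base_hazard = {k: 2.5 * v for k, v in p.base_hazard.items()}
    cohort = generate_cohort(p)
    oracle = OracleModel(p)
    reports = performance_by_arm(oracle, cohort.covariates, cohort.time,
                                 cohort.event, cohort.arm, n_boot=10, seed=0)
    rng = np.random.default_rng(0)

    class Noise:
        def predict_risk(self, cov, arm):
            return rng.normal(size=len(cov))

        def predict_survival(self, cov, arm, grid=None):
            return np.tile(np.linspace(0.99, 0.5, len(grid)), (len(cov), 1))

    noise_reports = performance_by_arm(Noise(), cohort.covariates, cohort.time,
                                       cohort.event, cohort.arm, n_boot=10, seed=0)
    for a in (0, 1):
        assert reports[a].c_index > noise_reports[a].c_index + 0.1
        assert 0 <= reports[a].ibs <= 1


def test_performance_requires_both_arms(eval_setup):
    p, cohort, _, _ = eval_setup
    oracle = OracleModel(p)
    m = cohort.arm == 1
    with pytest.raises(ValueError):
        performance_by_arm(oracle, cohort.covariates[m], cohort.time[m],
                           cohort.event[m], cohort.arm[m])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_mortality_percentages_from_printed_counts():
    assert round(mortality_percent(1680, 409), 1) == 80.4
    assert round(mortality_percent(13844, 4510), 1) == 75.4
    assert round(mortality_percent(1680 + 13844, 409 + 4510), 1) == 75.9
    assert round(arm_share_percent(2089, 18354), 1) == 10.2


def test_cohort_summary_structure(eval_setup):
    _, cohort, _, _ = eval_setup
    s = cohort_summary(cohort)
    assert s["n"]["overall"] == len(cohort)
    assert s["n"]["rt"] + s["n"]["crt"] == s["n"]["overall"]
    assert "median" in s["continuous"]["age"]["overall"]
    sex = s["categorical"]["sex"]["overall"]
    assert sum(v["count"] for v in sex.values()) == len(cohort)
    assert s["mortality"]["overall"]["percent"] == pytest.approx(
        100 * cohort.event.mean())
    assert set(s["chi_square"]) == set(cohort.covariates.columns) - {"age", "tumor_size"}
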