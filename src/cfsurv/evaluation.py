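"""Recommendation-effect evaluation battery.

Consistent-versus-inconsistent hazard ratio (plain and IPTW-adjusted),
the 5-year restricted-mean-survival-time difference, the number needed
to treat (consistent-group RMST divided by the RMST difference),
within-recommendation-group Kaplan–Meier comparisons, per-arm
discrimination/calibration metrics, and descriptive cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import CATEGORICAL, CONTINUOUS
from .learners import CounterfactualModel
from .metrics import MetricReport, bootstrap_ci, integrated_brier, iptw_weights, metric_report
from .stats import fit_cox, kaplan_meier, log_rank_test, rmst_from_curve
from .synthetic import Cohort

TAU_DEFAULT = 60.0


@dataclass
class RecommendationReport:
    hr: float
    hr_ci: tuple[float, float]
    hr_adjusted: float
    hr_adjusted_ci: tuple[float, float]
    drmst: float
    drmst_ci: tuple[float, float]
    nnt: float                      # NaN when dRMST <= 0
    nnt_ci: tuple[float, float]
    nnt_defined: bool
    rmst_consistent: float
    rmst_inconsistent: float
    counts: dict
    logrank_p: float
    logrank_p_weighted: float
    tau: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "hr", "hr_adjusted", "drmst", "nnt", "nnt_defined",
            "rmst_consistent", "rmst_inconsistent",
            "logrank_p", "logrank_p_weighted", "tau")}
        d["hr_ci"] = list(self.hr_ci)
        d["hr_adjusted_ci"] = list(self.hr_adjusted_ci)
        d["drmst_ci"] = list(self.drmst_ci)
        d["nnt_ci"] = list(self.nnt_ci)
        d["counts"] = dict(self.counts)
        return d


def _drmst_parts(times, events, consistent, tau):
    km_c = kaplan_meier(times[consistent == 1], events[consistent == 1])
    km_i = kaplan_meier(times[consistent == 0], events[consistent == 0])
    r_c = rmst_from_curve(km_c, tau)
    r_i = rmst_from_curve(km_i, tau)
    return r_c, r_i, r_c - r_i


def recommendation_effect(times, events, consistent, X_encoded: pd.DataFrame,
                          tau: float = TAU_DEFAULT, n_boot: int = 1000,
                          seed: int = 0) -> RecommendationReport:
    """Evaluate a model's recommendations on an evaluation split.

    ``consistent`` is 1 when the actual treatment matched the
    recommendation.  The hazard ratio comes from a Cox fit on the single
    consistency indicator (reference = inconsistent, so HR < 1 is
    protective); the adjusted version reweights that fit by IPTW on all
    encoded covariates with the consistency indicator as the "treatment",
    using a robust sandwich variance.  dRMST and NNT carry seeded
    percentile-bootstrap CIs.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    consistent = np.asarray(consistent, dtype=int)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.unique(consistent).size < 2:
        raise ValueError("both consistency groups must be non-empty")

    ind = pd.DataFrame({"consistent": consistent.astype(float)})
    cox = fit_cox(ind, times, events)
    hr_row = cox.hazard_ratios().loc["consistent"]

    w = iptw_weights(X_encoded, consistent).weights
    cox_w = fit_cox(ind, times, events, weights=w, robust=True)
    hra_row = cox_w.hazard_ratios().loc["consistent"]

    r_c, r_i, drmst = _drmst_parts(times, events, consistent, tau)
    nnt_defined = drmst > 0
    nnt = r_c / drmst if nnt_defined else float("nan")

    def drmst_stat(idx):
        if np.unique(consistent[idx]).size < 2:
            raise ValueError("degenerate resample")
        return _drmst_parts(times[idx], events[idx], consistent[idx], tau)[2]

    def nnt_stat(idx):
        rc, _, dr = (_drmst_parts(times[idx], events[idx], consistent[idx], tau)
                     if np.unique(consistent[idx]).size == 2 else (None,) * 3)
        if dr is None or dr <= 0:
            raise ValueError("NNT undefined in resample")
        return rc / dr

    n = times.size
    drmst_ci = bootstrap_ci(drmst_stat, n, n_boot, seed)
    nnt_ci = bootstrap_ci(nnt_stat, n, n_boot, seed) if nnt_defined else (float("nan"),) * 2

    _, p_plain = log_rank_test(consistent, times, events)
    _, p_weighted = log_rank_test(consistent, times, events, weights=w)

    return RecommendationReport(
        hr=float(hr_row["hr"]), hr_ci=(float(hr_row["hr_lo"]), float(hr_row["hr_hi"])),
        hr_adjusted=float(hra_row["hr"]),
        hr_adjusted_ci=(float(hra_row["hr_lo"]), float(hra_row["hr_hi"])),
        drmst=float(drmst), drmst_ci=drmst_ci,
        nnt=float(nnt), nnt_ci=nnt_ci, nnt_defined=bool(nnt_defined),
        rmst_consistent=float(r_c), rmst_inconsistent=float(r_i),
        counts={"consistent": int(consistent.sum()),
                "inconsistent": int((1 - consistent).sum())},
        logrank_p=float(p_plain), logrank_p_weighted=float(p_weighted),
        tau=float(tau),
    )


def within_group_comparison(times, events, arms, recommended) -> dict:
    """RT-vs-CRT KM curves and log-rank p inside each recommendation group.

    Groups containing a single actual arm are flagged ``testable: False``
    rather than tested.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arms = np.asarray(arms, dtype=int)
    recommended = np.asarray(recommended, dtype=int)
    out = {}
    for label, rec_arm in (("rrt", 0), ("rcrt", 1)):
        m = recommended == rec_arm
        entry = {"n": int(m.sum()), "testable": False, "p": None, "curves": {}}
        if m.sum() and np.unique(arms[m]).size == 2:
            entry["testable"] = True
            _, entry["p"] = log_rank_test(arms[m], times[m], events[m])
            for a, name in ((0, "rt"), (1, "crt")):
                am = m & (arms == a)
                entry["curves"][name] = kaplan_meier(times[am], events[am])
        out[label] = entry
    return out


def performance_by_arm(model: CounterfactualModel, covariates: pd.DataFrame,
                       times, events, arms, n_boot: int = 200,
                       seed: int = 0) -> dict[int, MetricReport]:
    """C-index and IBS of the model's own-arm predictions, per actual arm.

    The IBS grid is the arm's event-time grid truncated at the 95th
    percentile of that arm's follow-up.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arms = np.asarray(arms, dtype=int)
    out = {}
    for a in (0, 1):
        m = arms == a
        if not m.any():
            raise ValueError(f"arm {a} absent from evaluation split")
        t, e = times[m], events[m]
        grid = np.unique(t[e == 1])
        grid = grid[grid <= np.quantile(t, 0.95)]
        if grid.size == 0:
            grid = np.unique(t[e == 1])[:1]
        if grid.size > 100:   # thin the integration grid; BS(t) is smooth
            grid = grid[np.linspace(0, grid.size - 1, 100).astype(int)]
        risk = model.predict_risk(covariates[m], a)
        surv = model.predict_survival(covariates[m], a, grid=grid)
        out[a] = metric_report(risk, surv, t, e, grid, n_boot=n_boot, seed=seed + a)
    return out


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def mortality_percent(dead: int, censored: int) -> float:
    """Dead / (dead + censored) as a percentage."""
    total = dead + censored
    if total <= 0:
        raise ValueError("empty group")
    return 100.0 * dead / total


def arm_share_percent(n_arm: int, n_other: int) -> float:
    """One arm's share of the cohort as a percentage."""
    if n_arm + n_other <= 0:
        raise ValueError("empty cohort")
    return 100.0 * n_arm / (n_arm + n_other)


def cohort_summary(cohort: Cohort) -> dict:
    """Median (IQR) for continuous covariates, counts (%) per categorical
    level — overall and per arm — plus per-arm mortality and chi-square
    comparisons between arms for every categorical variable."""
    df = cohort.covariates
    arms = np.asarray(cohort.arm, dtype=int)
    events = np.asarray(cohort.event, dtype=int)
    masks = {"overall": np.ones(len(df), bool), "rt": arms == 0, "crt": arms == 1}

    summary: dict = {"n": {k: int(m.sum()) for k, m in masks.items()},
                     "continuous": {}, "categorical": {}, "mortality": {},
                     "chi_square": {}}
    for col in CONTINUOUS:
        summary["continuous"][col] = {
            k: {"median": float(np.median(df[col][m])),
                "iqr": [float(q) for q in np.percentile(df[col][m], [25, 75])]}
            for k, m in masks.items()}
    for col, levels in CATEGORICAL.items():
        summary["categorical"][col] = {
            k: {lvl: {"count": int(c := (df[col][m] == lvl).sum()),
                      "percent": 100.0 * c / max(m.sum(), 1)}
                for lvl in levels}
            for k, m in masks.items()}
        table = np.array([[(df[col][m] == lvl).sum() for lvl in levels]
                          for m in (masks["rt"], masks["crt"])], dtype=float)
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] >= 2 and table.sum(axis=1).min() > 0:
            stat, p, _, _ = sps.chi2_contingency(table, correction=False)
            summary["chi_square"][col] = {"statistic": float(stat), "p": float(p)}
        else:
            summary["chi_square"][col] = {"statistic": None, "p": None}
    for k, m in masks.items():
        dead = int(events[m].sum())
        censored = int(m.sum() - dead)
        summary["mortality"][k] = {
            "dead": dead, "censored": censored,
            "percent": mortality_percent(dead, censored) if m.sum() else None}
    return summary
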