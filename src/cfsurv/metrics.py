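"""Discrimination / calibration metrics and inverse-probability weighting.

Harrell's concordance, the Graf IPCW (integrated) Brier score, and IPTW
weights with standardized-mean-difference balance diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import FitError, SurvivalCurve, fit_logistic, kaplan_meier


def concordance_index(risk, times, events) -> float:
    """Harrell's C over admissible pairs; ties in risk count 1/2.

    A pair (i, j) is admissible when the subject with the smaller observed
    time had an event; concordant when that subject also has the higher risk.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size < 2 or events.sum() == 0:
        raise ValueError("need at least two subjects and one event")
    num = 0.0
    den = 0.0
    order = np.argsort(times, kind="stable")
    risk, times, events = risk[order], times[order], events[order]
    n = times.size
    for i in range(n):
        if events[i] != 1:
            continue
        later = times > times[i]
        den += later.sum()
        num += (risk[i] > risk[later]).sum() + 0.5 * (risk[i] == risk[later]).sum()
    if den == 0:
        raise ValueError("no admissible pairs")
    return float(num / den)


def bootstrap_ci(statistic, n: int, n_boot: int = 200, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI: ``statistic(idx)`` evaluated on resampled indices."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(statistic(idx))
        except (ValueError, FitError):
            continue
    if not vals:
        return (float("nan"), float("nan"))
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _censoring_survival(times, events) -> SurvivalCurve:
    # KM of the censoring distribution: censoring is the "event"
    return kaplan_meier(times, 1 - np.asarray(events, dtype=int))


def brier_scores(surv_matrix, times, events, grid) -> np.ndarray:
    """Graf IPCW Brier score BS(t) at each grid time.

    ``surv_matrix[i, k]`` is subject i's predicted S(grid[k]).  Subjects
    censored before t contribute 0; weights are 1/G(T_i-) for early events
    and 1/G(t) for survivors, with G the censoring-distribution KM.
    """
    surv_matrix = np.asarray(surv_matrix, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid > times.max()):
        raise ValueError("grid time beyond last follow-up")
    G = _censoring_survival(times, events)
    # G evaluated just before each subject's time
    g_at_minus = G.evaluate(times - 1e-9)
    g_at_minus = np.where(g_at_minus > 0, g_at_minus, np.nan)
    g_t = np.asarray(G.evaluate(grid), dtype=float)
    n = times.size
    died = (times[:, None] <= grid[None, :]) & (events[:, None] == 1)
    alive = times[:, None] > grid[None, :]
    contrib = np.where(died, surv_matrix**2 / g_at_minus[:, None], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alive_term = np.where(alive & (g_t[None, :] > 0),
                              (1.0 - surv_matrix) ** 2 / g_t[None, :], 0.0)
    return np.nansum(contrib + alive_term, axis=0) / n


def integrated_brier(surv_matrix, times, events, grid) -> float:
    """Trapezoidal average of BS(t) over the grid (the IBS)."""
    grid = np.asarray(grid, dtype=float)
    bs = brier_scores(surv_matrix, times, events, grid)
    if grid.size == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


@dataclass
class MetricReport:
    c_index: float
    c_index_ci: tuple[float, float]
    ibs: float
    ibs_ci: tuple[float, float]
    grid: np.ndarray

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index, "c_index_ci": list(self.c_index_ci),
            "ibs": self.ibs, "ibs_ci": list(self.ibs_ci),
        }


def metric_report(risk, surv_matrix, times, events, grid,
                  n_boot: int = 200, seed: int = 0) -> MetricReport:
    """C-index and IBS with seeded nonparametric-bootstrap 95% CIs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk, dtype=float)
    surv_matrix = np.asarray(surv_matrix, dtype=float)
    grid = np.asarray(grid, dtype=float)
    c = concordance_index(risk, times, events)
    ibs = integrated_brier(surv_matrix, times, events, grid)
    n = times.size

    def c_stat(idx):
        return concordance_index(risk[idx], times[idx], events[idx])

    def ibs_stat(idx):
        sub_grid = grid[grid <= times[idx].max()]
        if sub_grid.size == 0:
            raise ValueError("degenerate resample")
        return integrated_brier(surv_matrix[idx][:, :sub_grid.size],
                                times[idx], events[idx], sub_grid)

    return MetricReport(
        c_index=c, c_index_ci=bootstrap_ci(c_stat, n, n_boot, seed),
        ibs=ibs, ibs_ci=bootstrap_ci(ibs_stat, n, n_boot, seed + 1),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# IPTW
# ---------------------------------------------------------------------------

@dataclass
class IPTWWeights:
    weights: np.ndarray
    propensity: np.ndarray
    truncation: tuple[float, float] | None
    smd_before: pd.Series
    smd_after: pd.Series


def standardized_mean_differences(X: pd.DataFrame, group, weights=None) -> pd.Series:
    """Per-column |SMD| between the two groups, optionally weighted."""
    group = np.asarray(group, dtype=int)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        stats = []
        for g in (0, 1):
            m = group == g
            wm = w[m]
            mu = np.average(x[m], weights=wm)
            var = np.average((x[m] - mu) ** 2, weights=wm)
            stats.append((mu, var))
        pooled = np.sqrt((stats[0][1] + stats[1][1]) / 2)
        out[col] = abs(stats[1][0] - stats[0][0]) / pooled if pooled > 0 else 0.0
    return pd.Series(out)


def iptw_weights(X: pd.DataFrame, group, stabilize: bool = True,
                 truncate: tuple[float, float] | None = (0.001, 0.999)) -> IPTWWeights:
    """Inverse-probability-of-treatment weights from a logistic propensity model.

    Weight 1/e for group 1 and 1/(1-e) for group 0, optionally stabilized by
    the marginal group probabilities, truncated at the given weight
    percentiles (pass ``None`` to disable).  The default 0.1/99.9
    percentile truncation is mild on purpose: with a ~90/10 arm imbalance
    the minority arm legitimately carries large weights, and clipping at
    1/99 destroys covariate balance.  SMD balance diagnostics are
    reported before and after weighting for every design column.
    """
    group = np.asarray(group, dtype=int)
    if np.unique(group).size < 2:
        raise ValueError("both groups must be present")
    fit = fit_logistic(X, group)
    e = fit.predict_proba(X.to_numpy(dtype=float))
    if truncate is None and (np.any(e <= 0) or np.any(e >= 1)):
        raise FitError("propensity of exactly 0/1 with truncation disabled")
    ec = np.clip(e, 1e-12, 1 - 1e-12) if truncate is not None else e
    w = np.where(group == 1, 1.0 / ec, 1.0 / (1.0 - ec))
    if stabilize:
        p1 = group.mean()
        w *= np.where(group == 1, p1, 1.0 - p1)
    bounds = None
    if truncate is not None:
        lo, hi = np.quantile(w, truncate)
        w = np.clip(w, lo, hi)
        bounds = (float(lo), float(hi))
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise FitError("non-finite or non-positive IPTW weights")
    return IPTWWeights(
        weights=w, propensity=e, truncation=bounds,
        smd_before=standardized_mean_differences(X, group),
        smd_after=standardized_mean_differences(X, group, w),
    )
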