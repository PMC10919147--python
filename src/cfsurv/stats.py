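"""Core survival estimators and tests.

Kaplan–Meier (optionally weighted), the two-group log-rank test, Cox
proportional hazards (Newton–Raphson on the weighted partial likelihood,
Breslow ties and baseline, optional robust sandwich variance), logistic
regression with Wald odds-ratio intervals, the Pearson chi-square test
on 2x2 tables and restricted mean survival time.  Logistic fits are
backed by statsmodels' IRLS behind a thin, contract-checked wrapper;
everything else is implemented directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class FitError(RuntimeError):
    """A model fit failed (non-identifiable design, separation, no events...)."""


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """A right-continuous step survival function.

    ``times`` are strictly increasing; ``surv[i]`` is S(times[i]).  S(t) = 1
    for t before the first grid point.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.shape != self.surv.shape:
            raise ValueError("times and surv must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities outside [0, 1]")
        if self.surv.size and np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (step interpolation, S=1 before grid)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return out if out.shape else float(out)


def kaplan_meier(times, events, weights=None) -> SurvivalCurve:
    """(Weighted) product-limit estimator evaluated at the event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative weight")
    if not np.any(weights > 0):
        raise ValueError("all weights zero")

    order = np.argsort(times, kind="stable")
    ts, es, ws = times[order], events[order], weights[order]
    uniq, first = np.unique(ts, return_index=True)
    at_risk = np.cumsum(ws[::-1])[::-1][first]
    deaths = np.zeros(uniq.size)
    ev = (es == 1) & (ws > 0)
    np.add.at(deaths, np.searchsorted(uniq, ts[ev]), ws[ev])
    has_event = deaths > 0
    if not has_event.any():
        # no events anywhere: S == 1 on the observed-time grid
        return SurvivalCurve(uniq, np.ones_like(uniq))
    surv = np.cumprod(1.0 - deaths[has_event] / at_risk[has_event])
    return SurvivalCurve(uniq[has_event], np.clip(surv, 0.0, 1.0))


def log_rank_test(groups, times, events, weights=None) -> tuple[float, float]:
    """Two-group (optionally weighted) log-rank chi-square with 1 df.

    Returns ``(statistic, p_value)``.  Weighted counts enter the standard
    observed-minus-expected / hypergeometric-variance formula, which gives
    the IPTW-adjusted log-rank when weights are inverse-propensity weights.
    """
    groups = np.asarray(groups, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("log_rank_test requires exactly two non-empty groups")
    g1 = groups == labels[1]

    order = np.argsort(times, kind="stable")
    ts, es, ws, gs = times[order], events[order], weights[order], g1[order]
    uniq, first = np.unique(ts, return_index=True)
    n_all = np.cumsum(ws[::-1])[::-1][first]
    n_grp1 = np.cumsum((ws * gs)[::-1])[::-1][first]
    d_all = np.zeros(uniq.size)
    d_grp1 = np.zeros(uniq.size)
    ev = es == 1
    pos = np.searchsorted(uniq, ts[ev])
    np.add.at(d_all, pos, ws[ev])
    np.add.at(d_grp1, pos, (ws * gs)[ev])
    ok = (d_all > 0) & (n_all > 1)
    frac = n_grp1[ok] / n_all[ok]
    o_minus_e = float(np.sum(d_grp1[ok] - d_all[ok] * frac))
    var = float(np.sum(d_all[ok] * frac * (1 - frac)
                       * (n_all[ok] - d_all[ok]) / (n_all[ok] - 1)))
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox model with Breslow cumulative baseline hazard."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    baseline_times: np.ndarray       # event-time grid
    baseline_hazard: np.ndarray      # H0(t) for raw (unshifted) covariates
    x_offset: np.ndarray = field(default=None)  # centering used internally

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.beta

    def predict_survival(self, X, grid=None) -> np.ndarray:
        """S(t | x) = exp(-H0(t) e^{x'beta}); rows of X, columns grid times."""
        grid = self.baseline_times if grid is None else np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.baseline_times, grid, side="right") - 1
        h0 = np.where(idx >= 0, self.baseline_hazard[np.clip(idx, 0, None)], 0.0)
        lp = self.linear_predictor(X)
        return np.exp(-np.outer(np.exp(lp), h0))

    def hazard_ratios(self) -> pd.DataFrame:
        z = sps.norm.ppf(0.975)
        return pd.DataFrame({
            "coef": self.beta,
            "se": self.se,
            "hr": np.exp(self.beta),
            "hr_lo": np.exp(self.beta - z * self.se),
            "hr_hi": np.exp(self.beta + z * self.se),
            "p": 2 * sps.norm.sf(np.abs(self.beta) / np.where(self.se > 0, self.se, np.inf)),
        }, index=self.names)

    def summary_dict(self) -> dict:
        hr = self.hazard_ratios()
        return {
            "names": self.names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "hr": hr["hr"].tolist(),
            "hr_ci": list(zip(hr["hr_lo"].tolist(), hr["hr_hi"].tolist())),
            "loglik": self.loglik,
        }


def _as_frame(X, names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.reset_index(drop=True)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def _cox_quantities(beta, X, times, events, weights):
    """Weighted Breslow partial log-likelihood, score and information.

    Works on centered covariates; single backward sweep over subjects
    ordered by descending time so risk-set sums are running totals.
    """
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    Xs, ts, es, ws = X[order], times[order], events[order], weights[order]
    eta = Xs @ beta
    shift = eta.max()   # overflow guard; cancels in all risk-set ratios
    r = ws * np.exp(eta - shift)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            s0 += r[j]
            s1 += r[j] * Xs[j]
            s2 += r[j] * np.outer(Xs[j], Xs[j])
            j += 1
        block = slice(i, j)
        dying = es[block] == 1
        if dying.any():
            wd = ws[block][dying]
            xd = Xs[block][dying]
            d = wd.sum()
            loglik += float(wd @ (xd @ beta)) - d * (np.log(s0) + shift)
            xbar = s1 / s0
            score += wd @ xd - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return loglik, score, info


def fit_cox(X, times, events, weights=None, robust=False, names=None,
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Cox PH by Newton–Raphson on the (weighted) partial likelihood.

    Breslow handling of tied event times and Breslow cumulative baseline
    hazard; Wald standard errors from the inverse information, or a
    Lin–Wei sandwich when ``robust=True`` (required for IPTW-weighted
    fits).  Convergence is declared when the score max-norm drops below
    ``tol``; step-halving guards against likelihood decreases.  Raises
    :class:`FitError` on non-identifiable designs, absence of events, or a
    singular information matrix.
    """
    Xf = _as_frame(X, names)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(Xf) != times.size or times.size != events.size:
        raise ValueError("length mismatch")
    if len(Xf) <= Xf.shape[1]:
        raise FitError("fewer subjects than covariates")
    if events.sum() == 0:
        raise FitError("no events")
    for c in Xf.columns:
        if Xf[c].nunique() <= 1:
            raise FitError(f"constant covariate column {c!r} is non-identifiable")
    if weights is None:
        w = np.ones(times.size)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    Xraw = Xf.to_numpy(dtype=float)
    center = Xraw.mean(axis=0)
    Xc = Xraw - center
    p = Xc.shape[1]
    beta = np.zeros(p)
    loglik, score, info = _cox_quantities(beta, Xc, times, events, w)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        # Newton decrement at the numerical noise floor of the summed
        # likelihood: further iterations cannot improve
        if float(score @ step) < 1e-10:
            converged = True
            break
        # step-halving on likelihood decrease
        stalled = False
        for _ in range(40):
            cand = beta + step
            ll_new, sc_new, in_new = _cox_quantities(cand, Xc, times, events, w)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            step = step / 2
        else:
            stalled = True
        if stalled:
            break
        beta, loglik, score, info = cand, ll_new, sc_new, in_new
    if not converged and np.max(np.abs(score)) > 1e-3:
        raise FitError("Newton–Raphson failed to converge")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    if robust:
        cov = _cox_sandwich(beta, Xc, times, events, w, cov)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise FitError("Cox fit produced non-finite estimates")

    bt, bh = _breslow_cumhaz(beta, Xc, times, events, w)
    # shift baseline from centered to raw covariate scale (x = 0)
    bh_raw = bh * np.exp(-float(center @ beta))
    return CoxFit(names=list(Xf.columns), beta=beta, se=se, cov=cov,
                  loglik=float(loglik), baseline_times=bt,
                  baseline_hazard=bh_raw, x_offset=center)


def _breslow_cumhaz(beta, X, times, events, weights):
    r = weights * np.exp(X @ beta)
    ev = np.unique(times[events == 1])
    h = np.empty_like(ev)
    acc = 0.0
    for k, t in enumerate(ev):
        acc += weights[(times == t) & (events == 1)].sum() / r[times >= t].sum()
        h[k] = acc
    return ev, h


def _cox_sandwich(beta, X, times, events, weights, naive_cov):
    """Lin–Wei robust covariance from per-subject score residuals."""
    n, p = X.shape
    wr = weights * np.exp(X @ beta)
    order = np.argsort(times, kind="stable")
    ts, Xs = times[order], X[order]
    wrs = wr[order]
    uniq, first = np.unique(ts, return_index=True)
    s0 = np.cumsum(wrs[::-1])[::-1][first]
    s1 = np.cumsum((wrs[:, None] * Xs)[::-1], axis=0)[::-1][first]
    d = np.zeros(uniq.size)
    ev_mask = events == 1
    pos_ev = np.searchsorted(uniq, times[ev_mask])
    np.add.at(d, pos_ev, weights[ev_mask])
    xbar = s1 / s0[:, None]
    is_event_time = d > 0
    # cumulative hazard-increment sums A(t) = sum_{s<=t} d/s0,
    # B(t) = sum_{s<=t} (d/s0) xbar(s)
    inc = np.where(is_event_time, d / s0, 0.0)
    A = np.cumsum(inc)
    B = np.cumsum(inc[:, None] * xbar, axis=0)
    k = np.searchsorted(uniq, times, side="right") - 1
    U = -np.exp(X @ beta)[:, None] * (X * A[k][:, None] - B[k])
    idx_ev = np.searchsorted(uniq, times[ev_mask])
    U[ev_mask] += X[ev_mask] - xbar[idx_ev]
    Uw = U * weights[:, None]
    meat = Uw.T @ Uw
    return naive_cov @ meat @ naive_cov


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A fitted logistic model with odds ratios and Wald 95% CIs."""

    names: list[str]            # includes "intercept" first
    beta: np.ndarray
    se: np.ndarray

    def odds_ratios(self) -> pd.DataFrame:
        z = sps.norm.ppf(0.975)
        with np.errstate(over="ignore"):
            return pd.DataFrame({
                "or": np.exp(self.beta),
                "or_lo": np.exp(self.beta - z * self.se),
                "or_hi": np.exp(self.beta + z * self.se),
            }, index=self.names)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        lp = self.beta[0] + X @ self.beta[1:]
        return 1.0 / (1.0 + np.exp(-lp))

    def summary_dict(self) -> dict:
        table = self.odds_ratios()
        return {
            "names": self.names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "or": table["or"].tolist(),
            "or_ci": list(zip(table["or_lo"].tolist(), table["or_hi"].tolist())),
        }


def fit_logistic(X, y, weights=None, names=None) -> LogisticFit:
    """Weighted maximum-likelihood logistic regression (IRLS, statsmodels GLM).

    Raises :class:`FitError` when y is single-class or the data are
    (quasi-)separated, in which case the MLE does not exist.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    Xf = _as_frame(X, names)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if np.unique(y).size < 2:
        raise FitError("y contains a single class")
    design = sm.add_constant(Xf.to_numpy(dtype=float), has_constant="add")
    kwargs = {}
    if weights is not None:
        kwargs["freq_weights"] = np.asarray(weights, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial(), **kwargs).fit(maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise FitError("separation detected: logistic MLE diverged")
    if np.max(np.abs(beta)) > 15:
        # huge coefficients mean either true separation (no MLE) or extreme
        # but legitimate structure; flag only when the fit perfectly
        # classifies every observation
        phat = np.asarray(res.fittedvalues, dtype=float)
        if np.all(np.abs(y - phat) < 1e-6):
            raise FitError("complete separation: logistic MLE does not exist")
    return LogisticFit(names=["intercept"] + list(Xf.columns), beta=beta, se=se)


# ---------------------------------------------------------------------------
# Contingency tables and RMST
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def rmst_from_curve(curve: SurvivalCurve, tau: float) -> float:
    """Area under the step survival curve from 0 to tau (last value carried forward)."""
    if tau < 0:
        raise ValueError("negative tau")
    if tau == 0:
        return 0.0
    knots = np.concatenate([[0.0], curve.times[curve.times < tau], [tau]])
    # survival on [knots[i], knots[i+1]) is S evaluated at knots[i]
    s = np.concatenate([[1.0], curve.evaluate(knots[1:-1])]) if knots.size > 2 else np.array([1.0])
    if curve.times.size and curve.times[0] == 0:
        s[0] = curve.surv[0]
    return float(np.sum(np.diff(knots) * s))
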