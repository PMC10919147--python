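"""Counterfactual T-learners: one survival model per treatment arm.

Four base-learner families share one contract — predict a survival curve
for any in-schema covariate row under either arm:

* ``cph``      Cox proportional hazards with a Breslow baseline
* ``tree``     survival tree with log-rank splitting (leaf = KM curve)
* ``rsf``      random survival forest (ensemble-average hazard)
* ``deepsurv`` MLP risk score trained on the Cox partial likelihood with
  decoupled weight decay, Breslow baseline on training data

The tree and forest are backed by scikit-survival; the Cox-loss network
is the in-package NumPy implementation (see :mod:`cfsurv.nn`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .encoding import CovariateEncoder
from .stats import FitError, SurvivalCurve, fit_cox, kaplan_meier
from .synthetic import Cohort

ARM_RT, ARM_CRT = 0, 1
SUPPORTED_KINDS = ("cph", "tree", "rsf", "deepsurv")


def breslow_baseline(risk, times, events) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard from risk scores.

    H0(t) = sum over event times s <= t of d(s) / sum_{j at risk at s} exp(risk_j).
    Returns (event-time grid, H0 values).
    """
    risk = np.asarray(risk, dtype=float).ravel()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        raise FitError("no events")
    m = risk.max()
    h0 = np.empty_like(ev_times)
    acc = 0.0
    for k, t in enumerate(ev_times):
        d = int(((times == t) & (events == 1)).sum())
        denom = np.exp(risk[times >= t] - m).sum()
        acc += d / (denom * np.exp(m))
        h0[k] = acc
    return ev_times, h0


def _step_eval(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray,
               before: float) -> np.ndarray:
    idx = np.searchsorted(xs, grid, side="right") - 1
    return np.where(idx >= 0, ys[np.clip(idx, 0, None)], before)


# ---------------------------------------------------------------------------
# Arm models
# ---------------------------------------------------------------------------

class ArmModel:
    """One treatment arm's survival model."""

    def predict_risk(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_survival(self, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover


class KMArm(ArmModel):
    """Covariate-free arm model: the arm's Kaplan–Meier curve for every x."""

    def __init__(self, times, events):
        self.curve = kaplan_meier(times, events)

    def predict_risk(self, X):
        return np.zeros(len(X))

    def predict_survival(self, X, grid):
        s = self.curve.evaluate(grid)
        return np.tile(s, (len(X), 1))


class CoxArm(ArmModel):
    """Cox PH arm model; design columns constant within the arm (e.g. rare
    one-hot levels absent from the subset) are dropped before fitting."""

    def __init__(self, X, times, events, names=None):
        X = np.asarray(X, dtype=float)
        self.keep = np.flatnonzero(X.std(axis=0) > 0)
        if self.keep.size == 0:
            raise FitError("no identifiable covariates in arm")
        kept_names = [names[i] for i in self.keep] if names else None
        self.fit = fit_cox(X[:, self.keep], times, events, names=kept_names)

    def predict_risk(self, X):
        return self.fit.linear_predictor(np.asarray(X, dtype=float)[:, self.keep])

    def predict_survival(self, X, grid):
        return self.fit.predict_survival(np.asarray(X, dtype=float)[:, self.keep], grid)


class _SksurvArm(ArmModel):
    """Shared wrapper over scikit-survival estimators."""

    def __init__(self, estimator, X, times, events):
        from sksurv.util import Surv
        y = Surv.from_arrays(event=np.asarray(events, dtype=bool),
                             time=np.asarray(times, dtype=float))
        self.model = estimator.fit(np.asarray(X, dtype=float), y)
        self.train_grid = np.asarray(self.model.unique_times_, dtype=float)

    def predict_risk(self, X):
        return self.model.predict(np.asarray(X, dtype=float))

    def predict_survival(self, X, grid):
        s = self.model.predict_survival_function(np.asarray(X, dtype=float),
                                                 return_array=True)
        out = np.empty((len(X), len(grid)))
        for i in range(len(X)):
            out[i] = _step_eval(self.train_grid, s[i], grid, 1.0)
        return out


def make_tree_arm(X, times, events, hyper, seed) -> ArmModel:
    max_depth = hyper.get("max_depth", 5)
    if max_depth == 0:
        return KMArm(times, events)
    from sksurv.tree import SurvivalTree
    est = SurvivalTree(max_depth=max_depth,
                       min_samples_leaf=hyper.get("min_samples_leaf", 30),
                       random_state=seed)
    return _SksurvArm(est, X, times, events)


def make_rsf_arm(X, times, events, hyper, seed) -> ArmModel:
    from sksurv.ensemble import RandomSurvivalForest
    est = RandomSurvivalForest(
        n_estimators=hyper.get("n_estimators", 200),
        max_depth=hyper.get("max_depth", None),
        min_samples_leaf=hyper.get("min_samples_leaf", 30),
        max_features=hyper.get("max_features", "sqrt"),
        bootstrap=hyper.get("bootstrap", True),
        random_state=seed, n_jobs=1)
    return _SksurvArm(est, X, times, events)


@dataclass
class DeepSurvHyper:
    hidden: tuple[int, ...] = (64, 64)
    dropout: float = 0.1
    lr: float = 0.01
    weight_decay: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2


class DeepSurvArm(ArmModel):
    """MLP risk score, Cox partial-likelihood loss, decoupled weight decay."""

    def __init__(self, X, times, events, hyper: DeepSurvHyper, seed: int = 0):
        X = np.asarray(X, dtype=float)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if events.sum() == 0:
            raise FitError("no events in arm")
        self.net = nn.MLP((X.shape[1], *hyper.hidden, 1), seed=seed,
                          dropout=hyper.dropout)
        rng = np.random.default_rng(seed + 1)
        n = len(X)
        n_val = int(round(hyper.val_fraction * n)) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if n_val and events[val_idx].sum() == 0:
            n_val = 0
            tr_idx = perm
        opt = nn.AdamW(self.net.parameters(), lr=hyper.lr,
                       weight_decay=hyper.weight_decay)
        best, best_params, wait = np.inf, None, 0
        for _ in range(hyper.max_epochs):
            order = rng.permutation(len(tr_idx))
            for start in range(0, len(order), hyper.batch_size):
                b = tr_idx[order[start:start + hyper.batch_size]]
                if events[b].sum() == 0 or len(b) < 2:
                    continue
                out, cache = self.net.forward(X[b], train=True, rng=rng)
                loss, d_risk = nn.cox_npll(out.ravel(), times[b], events[b])
                if not np.isfinite(loss):
                    raise FitError("deepsurv training diverged")
                grads, _ = self.net.backward(cache, d_risk[:, None])
                opt.step(self.net.parameters(), grads)
            if n_val:
                val_out, _ = self.net.forward(X[val_idx])
                val_loss, _ = nn.cox_npll(val_out.ravel(), times[val_idx], events[val_idx])
            else:
                tr_out, _ = self.net.forward(X[tr_idx])
                val_loss, _ = nn.cox_npll(tr_out.ravel(), times[tr_idx], events[tr_idx])
            if val_loss < best - 1e-6:
                best, wait = val_loss, 0
                best_params = [p.copy() for p in self.net.parameters()]
            else:
                wait += 1
                if wait >= hyper.patience:
                    break
        if best_params is not None:
            self.net.set_parameters(best_params)
        risk = self.net.forward(X)[0].ravel()
        self.baseline_times, self.baseline_hazard = breslow_baseline(risk, times, events)

    def predict_risk(self, X):
        return self.net.forward(np.asarray(X, dtype=float))[0].ravel()

    def predict_survival(self, X, grid):
        h0 = _step_eval(self.baseline_times, self.baseline_hazard, grid, 0.0)
        return np.exp(-np.outer(np.exp(self.predict_risk(X)), h0))


def fit_arm_model(kind: str, X, times, events, hyper: dict | None = None,
                  seed: int = 0) -> ArmModel:
    """Fit one arm's survival model; see module docstring for the contracts."""
    hyper = hyper or {}
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty arm")
    if events.sum() == 0:
        raise FitError("no events in arm")
    if kind == "cph":
        X = np.asarray(X, dtype=float)
        if X.shape[1] == 0:
            return KMArm(times, events)
        return CoxArm(X, times, events, names=hyper.get("names"))
    if kind == "tree":
        return make_tree_arm(X, times, events, hyper, seed)
    if kind == "rsf":
        return make_rsf_arm(X, times, events, hyper, seed)
    if kind == "deepsurv":
        hp = hyper.get("deepsurv", DeepSurvHyper(**{k: v for k, v in hyper.items()
                                                    if k in DeepSurvHyper.__dataclass_fields__}))
        return DeepSurvArm(X, times, events, hp, seed=seed)
    raise ValueError(f"unknown learner kind {kind!r}")


# ---------------------------------------------------------------------------
# Counterfactual model
# ---------------------------------------------------------------------------

def evaluation_grid(times, events, arms) -> np.ndarray:
    """Union of per-arm training event times, truncated at the 99th
    percentile of follow-up."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arms = np.asarray(arms, dtype=int)
    pts = np.unique(np.concatenate([
        times[(arms == a) & (events == 1)] for a in (0, 1)
    ]))
    cap = np.quantile(times, 0.99)
    grid = pts[pts <= cap]
    return grid if grid.size else pts[:1]


@dataclass
class CounterfactualModel:
    """Two fitted arm components plus the shared covariate encoder."""

    kind: str
    arm_models: dict[int, ArmModel]
    encoder: CovariateEncoder
    grid: np.ndarray
    hyper: dict = field(default_factory=dict)
    seed: int = 0

    def _encode(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.encoder.transform(covariates).to_numpy(dtype=float)

    def predict_survival(self, covariates: pd.DataFrame, arm: int,
                         grid=None) -> np.ndarray:
        grid = self.grid if grid is None else np.asarray(grid, dtype=float)
        return np.clip(self.arm_models[arm].predict_survival(
            self._encode(covariates), grid), 0.0, 1.0)

    def predict_risk(self, covariates: pd.DataFrame, arm: int) -> np.ndarray:
        return self.arm_models[arm].predict_risk(self._encode(covariates))

    def predict_counterfactual_curves(self, covariates: pd.DataFrame,
                                      grid=None):
        """Survival matrices under RT and CRT on a common grid."""
        grid = self.grid if grid is None else np.asarray(grid, dtype=float)
        return (self.predict_survival(covariates, ARM_RT, grid),
                self.predict_survival(covariates, ARM_CRT, grid), grid)

    def curves_for_row(self, covariates_row: pd.DataFrame) -> tuple[SurvivalCurve, SurvivalCurve]:
        s0, s1, grid = self.predict_counterfactual_curves(covariates_row)
        return (SurvivalCurve(grid, np.minimum.accumulate(s0[0])),
                SurvivalCurve(grid, np.minimum.accumulate(s1[0])))


def fit_tlearner(kind: str, cohort: Cohort, hyper: dict | None = None,
                 seed: int = 0, encoder: CovariateEncoder | None = None) -> CounterfactualModel:
    """Fit one survival model per arm on the arm's own subset."""
    if kind not in SUPPORTED_KINDS:
        raise ValueError(f"unknown learner kind {kind!r}")
    arms = np.asarray(cohort.arm, dtype=int)
    if not (np.any(arms == 0) and np.any(arms == 1)):
        raise ValueError("both treatment arms must be present in training data")
    if encoder is None:
        encoder = CovariateEncoder().fit(cohort.covariates)
    X = encoder.transform(cohort.covariates).to_numpy(dtype=float)
    grid = evaluation_grid(cohort.time, cohort.event, arms)
    arm_models = {}
    hyper = dict(hyper or {})
    if kind == "cph":
        hyper.setdefault("names", encoder.feature_names)
    for a in (0, 1):
        m = arms == a
        arm_models[a] = fit_arm_model(kind, X[m], cohort.time[m],
                                      cohort.event[m], hyper=hyper,
                                      seed=seed + a)
    return CounterfactualModel(kind=kind, arm_models=arm_models,
                               encoder=encoder, grid=grid,
                               hyper=dict(hyper or {}), seed=seed)
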