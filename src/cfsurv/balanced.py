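"""Balanced twin-head survival network.

A shared trunk extracts a latent representation; an integral probability
metric (IPM) penalty pulls the two arms' latent distributions together;
two Cox-loss risk heads — one per arm — are trained end-to-end with the
trunk:

    L = NPLL_arm0 + NPLL_arm1 + alpha * IPM(phi(X_arm0), phi(X_arm1))

The optimizer is Adam with decoupled weight decay.  After training, a
Breslow baseline is computed per arm from the final training risk
scores, so the fitted object satisfies the same counterfactual-model
contract as the T-learners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .encoding import CovariateEncoder
from .learners import (ArmModel, CounterfactualModel, FitError, _step_eval,
                       breslow_baseline, evaluation_grid)
from .metrics import concordance_index
from .synthetic import Cohort


@dataclass
class BitesHyper:
    trunk: tuple[int, ...] = (32, 32)
    heads: tuple[int, ...] = (16,)
    ipm: str = "mmd_rbf"                 # or "wasserstein_sinkhorn"
    alpha: float = 1.0
    lr: float = 0.01
    weight_decay: float = 1e-4
    dropout: float = 0.1
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.lr <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")


def ipm_distance(rep0: np.ndarray, rep1: np.ndarray, kind: str = "mmd_rbf") -> float:
    """Distance between two latent samples; nonnegative (MMD clipped at 0)."""
    if kind == "mmd_rbf":
        return max(nn.mmd2_rbf(rep0, rep1), 0.0)
    if kind == "wasserstein_sinkhorn":
        return nn.sinkhorn_distance(rep0, rep1)
    raise ValueError(f"unknown IPM kind {kind!r}")


class _BitesArm(ArmModel):
    """View of the trained network under one fixed arm."""

    def __init__(self, net: "BitesNetwork", arm: int, baseline):
        self.net = net
        self.arm = arm
        self.baseline_times, self.baseline_hazard = baseline

    def predict_risk(self, X):
        return self.net.risk(np.asarray(X, dtype=float), self.arm)

    def predict_survival(self, X, grid):
        h0 = _step_eval(self.baseline_times, self.baseline_hazard,
                        np.asarray(grid, dtype=float), 0.0)
        return np.exp(-np.outer(np.exp(self.predict_risk(X)), h0))


class BitesNetwork:
    """Trunk + two risk heads with joint backward pass."""

    def __init__(self, n_features: int, hyper: BitesHyper):
        latent = hyper.trunk[-1] if hyper.trunk else n_features
        self.has_trunk = bool(hyper.trunk)
        self.trunk = nn.MLP((n_features, *hyper.trunk), seed=hyper.seed,
                            dropout=hyper.dropout) if self.has_trunk else None
        self.heads = {a: nn.MLP((latent, *hyper.heads, 1), seed=hyper.seed + 1 + a,
                                dropout=hyper.dropout) for a in (0, 1)}

    def parameters(self):
        ps = list(self.trunk.parameters()) if self.has_trunk else []
        return ps + self.heads[0].parameters() + self.heads[1].parameters()

    def set_parameters(self, params):
        i = 0
        if self.has_trunk:
            k = len(self.trunk.parameters())
            self.trunk.set_parameters(params[:k])
            i = k
        for a in (0, 1):
            k = len(self.heads[a].parameters())
            self.heads[a].set_parameters(params[i:i + k])
            i += k

    def latent(self, X, train=False, rng=None):
        if not self.has_trunk:
            return np.asarray(X, dtype=float), None
        out, cache = self.trunk.forward(X, train=train, rng=rng)
        # trunk output passes through SELU so the latent space is nonlinear
        return nn.selu(out), (cache, out)

    def risk(self, X, arm):
        z, _ = self.latent(X)
        return self.heads[arm].forward(z)[0].ravel()


def _total_loss(net: BitesNetwork, X, times, events, arms, hyper: BitesHyper):
    z, _ = net.latent(X)
    total, parts = 0.0, {}
    for a in (0, 1):
        m = arms == a
        r = net.heads[a].forward(z[m])[0].ravel()
        loss, _ = nn.cox_npll(r, times[m], events[m])
        parts[f"npll{a}"] = loss
        total += loss
    parts["ipm"] = ipm_distance(z[arms == 0], z[arms == 1], hyper.ipm)
    total += hyper.alpha * parts["ipm"]
    parts["total"] = total
    return total, parts


def fit_bites(cohort: Cohort, hyper: BitesHyper,
              encoder: CovariateEncoder | None = None,
              log: list | None = None) -> CounterfactualModel:
    """Train the balanced network end-to-end; returns a counterfactual model.

    Early stopping watches the total loss (both arm likelihoods plus the
    weighted IPM term) on an arm-stratified validation split; the best
    epoch's weights are restored.  Raises :class:`FitError` on divergence
    or a missing arm.
    """
    arms = np.asarray(cohort.arm, dtype=int)
    if not (np.any(arms == 0) and np.any(arms == 1)):
        raise FitError("both arms must be present")
    for a in (0, 1):
        if cohort.event[arms == a].sum() == 0:
            raise FitError(f"no events in arm {a}")
    if encoder is None:
        encoder = CovariateEncoder().fit(cohort.covariates)
    X = encoder.transform(cohort.covariates).to_numpy(dtype=float)
    times, events = cohort.time, cohort.event

    rng = np.random.default_rng(hyper.seed)
    # arm-stratified train/validation split
    val_mask = np.zeros(len(X), dtype=bool)
    for a in (0, 1):
        idx = np.flatnonzero(arms == a)
        n_val = int(round(hyper.val_fraction * idx.size))
        if idx.size >= 10 and n_val >= 2:
            val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    tr_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    for a in (0, 1):
        if val_idx.size and events[val_idx][arms[val_idx] == a].sum() == 0:
            val_idx = np.empty(0, dtype=int)   # validation split unusable
            tr_idx = np.arange(len(X))

    net = BitesNetwork(X.shape[1], hyper)
    opt = nn.AdamW(net.parameters(), lr=hyper.lr, weight_decay=hyper.weight_decay)
    best, best_params, wait = np.inf, None, 0
    for epoch in range(hyper.max_epochs):
        order = tr_idx[rng.permutation(tr_idx.size)]
        for start in range(0, order.size, hyper.batch_size):
            b = order[start:start + hyper.batch_size]
            ab = arms[b]
            # batches must contain both arms with at least one event each
            if any(events[b][ab == a].sum() == 0 for a in (0, 1)):
                continue
            z, trunk_cache = net.latent(X[b], train=True, rng=rng)
            dz = np.zeros_like(z)
            head_grads = {}
            loss_val = 0.0
            for a in (0, 1):
                m = ab == a
                out, cache = net.heads[a].forward(z[m], train=True, rng=rng)
                loss, d_risk = nn.cox_npll(out.ravel(), times[b][m], events[b][m])
                loss_val += loss
                g, d_in = net.heads[a].backward(cache, d_risk[:, None])
                head_grads[a] = g
                dz[m] += d_in
            if hyper.alpha > 0:
                m0, m1 = ab == 0, ab == 1
                ipm_val, d0, d1 = nn.mmd2_rbf(z[m0], z[m1], with_grad=True)
                loss_val += hyper.alpha * ipm_val
                dz[m0] += hyper.alpha * d0
                dz[m1] += hyper.alpha * d1
            if not np.isfinite(loss_val):
                raise FitError("training diverged: non-finite loss")
            grads = []
            if net.has_trunk:
                cache, pre_act = trunk_cache
                trunk_g, _ = net.trunk.backward(cache, dz * nn.selu_grad(pre_act))
                grads += trunk_g
            grads += head_grads[0] + head_grads[1]
            opt.step(net.parameters(), grads)

        eval_idx = val_idx if val_idx.size else tr_idx
        val_loss, parts = _total_loss(net, X[eval_idx], times[eval_idx],
                                      events[eval_idx], arms[eval_idx], hyper)
        if log is not None:
            log.append({"epoch": epoch, **parts})
        if not np.isfinite(val_loss):
            raise FitError("training diverged: non-finite validation loss")
        if val_loss < best - 1e-6:
            best, wait = val_loss, 0
            best_params = [p.copy() for p in net.parameters()]
        else:
            wait += 1
            if wait >= hyper.patience:
                break
    if best_params is not None:
        net.set_parameters(best_params)

    grid = evaluation_grid(times, events, arms)
    arm_models = {}
    for a in (0, 1):
        m = arms == a
        baseline = breslow_baseline(net.risk(X[m], a), times[m], events[m])
        arm_models[a] = _BitesArm(net, a, baseline)
    model = CounterfactualModel(kind="bites", arm_models=arm_models,
                                encoder=encoder, grid=grid,
                                hyper={"alpha": hyper.alpha, "ipm": hyper.ipm,
                                       "trunk": list(hyper.trunk),
                                       "heads": list(hyper.heads)},
                                seed=hyper.seed)
    model.network = net
    return model


# ---------------------------------------------------------------------------
# Cross-validated hyperparameter selection
# ---------------------------------------------------------------------------

def _fold_assignment(arms: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic arm-stratified fold labels."""
    rng = np.random.default_rng(seed)
    folds = np.empty(arms.size, dtype=int)
    for a in (0, 1):
        idx = np.flatnonzero(arms == a)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def cv_select(cohort: Cohort, grid: list[BitesHyper] | list[dict],
              n_folds: int = 3, seed: int = 0,
              base: BitesHyper | None = None) -> BitesHyper:
    """Pick the grid point with the best mean per-arm validation C-index.

    Grid points may be ``BitesHyper`` objects or dicts of field overrides on
    ``base``.  A point whose training fails on any fold is flagged with a
    score of -inf and never selected; ties break toward smaller ``alpha``,
    then smaller total network size.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    hypers = [h if isinstance(h, BitesHyper) else replace(base or BitesHyper(), **h)
              for h in grid]
    arms = np.asarray(cohort.arm, dtype=int)
    folds = _fold_assignment(arms, n_folds, seed)
    scores = []
    for h in hypers:
        fold_scores = []
        ok = True
        for f in range(n_folds):
            train = cohort.subset(np.flatnonzero(folds != f))
            val = cohort.subset(np.flatnonzero(folds == f))
            try:
                model = fit_bites(train, replace(h, seed=seed + f))
                per_arm = []
                for a in (0, 1):
                    m = val.arm == a
                    if m.sum() < 2 or val.event[m].sum() == 0:
                        continue
                    per_arm.append(concordance_index(
                        model.predict_risk(val.covariates[m], a),
                        val.time[m], val.event[m]))
                fold_scores.append(float(np.mean(per_arm)))
            except (FitError, ValueError):
                ok = False
                break
        scores.append(float(np.mean(fold_scores)) if ok and fold_scores else -np.inf)

    def tie_key(i):
        h = hypers[i]
        return (-scores[i], h.alpha, sum(h.trunk) + sum(h.heads))

    return hypers[min(range(len(hypers)), key=tie_key)]
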