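"""Time-dependent Shapley attributions for survival predictions.

A feature's "absence" is realized by substituting its value from a
background sample (marginal expectation), so the explainer is fully
model-agnostic: it only needs a callable mapping a covariate table to a
matrix of survival probabilities on a time grid.  Attributions are
computed per source variable (a categorical variable is substituted as a
whole, never dummy-by-dummy), satisfy local accuracy in exact mode, and
can be aggregated into rank matrices across patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .encoding import CovariateEncoder
from .stats import FitError, LogisticFit, fit_logistic

EXACT_FEATURE_LIMIT = 12


@dataclass
class AttributionSeries:
    """Per-feature attribution functions phi_j(t) for one patient."""

    features: list[str]
    grid: np.ndarray
    phi: np.ndarray          # (n_features, n_times)
    baseline: np.ndarray     # background-average prediction, (n_times,)
    prediction: np.ndarray   # model prediction for the explained row

    def local_accuracy_residual(self) -> float:
        return float(np.max(np.abs(self.baseline + self.phi.sum(axis=0)
                                   - self.prediction)))

    def importance(self) -> pd.Series:
        """Time-integrated absolute attribution per feature."""
        if self.grid.size > 1:
            vals = np.trapezoid(np.abs(self.phi), self.grid, axis=1)
        else:
            vals = np.abs(self.phi[:, 0])
        return pd.Series(vals, index=self.features)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "time": t, "value": self.phi[j, k]}
                for j, f in enumerate(self.features)
                for k, t in enumerate(self.grid)]
        return pd.DataFrame(rows)


def _coalition_value(predict_fn, x_row: pd.DataFrame, background: pd.DataFrame,
                     subset: tuple[str, ...]) -> np.ndarray:
    z = background.copy()
    for col in subset:
        z[col] = x_row.iloc[0][col]
    return np.asarray(predict_fn(z), dtype=float).mean(axis=0)


def survshap_t(predict_fn, x_row: pd.DataFrame, background: pd.DataFrame,
               grid, features=None, mode: str = "exact",
               n_perm: int = 200, seed: int = 0) -> AttributionSeries:
    """Shapley attribution of a survival prediction over a time grid.

    ``predict_fn(table) -> (n, len(grid))`` survival matrix.  In ``exact``
    mode all 2^p coalitions are enumerated (p <= 12); ``sampled`` mode
    averages marginal contributions over ``n_perm`` seeded permutations.
    """
    if len(background) == 0:
        raise ValueError("empty background sample")
    if len(x_row) != 1:
        raise ValueError("x_row must be a single row")
    features = list(features) if features is not None else list(x_row.columns)
    p = len(features)
    if mode == "exact" and p > EXACT_FEATURE_LIMIT:
        raise ValueError(f"exact mode limited to {EXACT_FEATURE_LIMIT} features")
    grid = np.asarray(grid, dtype=float)

    cache: dict[frozenset, np.ndarray] = {}

    def value(subset) -> np.ndarray:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = _coalition_value(predict_fn, x_row, background, tuple(subset))
        return cache[key]

    baseline = value(())
    phi = np.zeros((p, grid.size))
    if mode == "exact":
        for j, feat in enumerate(features):
            others = [f for f in features if f != feat]
            for k in range(p):
                w = factorial(k) * factorial(p - k - 1) / factorial(p)
                for subset in combinations(others, k):
                    phi[j] += w * (value(subset + (feat,)) - value(subset))
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            order = [features[i] for i in rng.permutation(p)]
            prev = value(())
            included: list[str] = []
            for feat in order:
                included.append(feat)
                cur = value(tuple(included))
                phi[features.index(feat)] += cur - prev
                prev = cur
        phi /= n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    prediction = np.asarray(predict_fn(x_row), dtype=float)[0]
    return AttributionSeries(features=features, grid=grid, phi=phi,
                             baseline=baseline, prediction=prediction)


def aggregate_rankings(attributions: list[AttributionSeries]) -> pd.DataFrame:
    """Rank-position counts over patients (features x rank positions).

    Each patient contributes one permutation of the features, ranked by
    time-integrated absolute attribution (rank 1 = most important).
    """
    if not attributions:
        raise ValueError("need at least one patient")
    features = attributions[0].features
    p = len(features)
    counts = pd.DataFrame(0, index=features,
                          columns=[f"rank_{r}" for r in range(1, p + 1)])
    for attr in attributions:
        if attr.features != features:
            raise ValueError("inconsistent feature sets")
        order = attr.importance().sort_values(ascending=False, kind="stable").index
        for r, feat in enumerate(order, start=1):
            counts.loc[feat, f"rank_{r}"] += 1
    return counts


def behavior_odds_ratios(covariates: pd.DataFrame, recommended,
                         encoder: CovariateEncoder | None = None) -> LogisticFit | None:
    """Multivariate logistic fit of recommended-CRT on all covariates.

    An odds ratio below 1 marks a feature pushing the model toward
    recommending RT.  Returns ``None`` (flagged not-estimable) when every
    patient got the same recommendation — models like a plain Cox
    T-learner can recommend CRT for everyone.
    """
    recommended = np.asarray(recommended, dtype=int)
    if np.unique(recommended).size < 2:
        return None
    if encoder is None:
        encoder = CovariateEncoder().fit(covariates)
    X = encoder.transform(covariates)
    # drop constant dummies (levels absent from this split)
    X = X.loc[:, X.nunique() > 1]
    try:
        return fit_logistic(X, recommended)
    except FitError:
        return None
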