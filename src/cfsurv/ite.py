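"""Individual treatment effects and per-patient recommendations.

The effect for one patient is the difference in predicted median
survival (first time the predicted curve drops to or below 0.5) between
the two arms, capped at an evaluation horizon.  The recommended arm is
the one with the larger predicted median; ties go to CRT, the guideline
standard of care.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .learners import ARM_CRT, CounterfactualModel
from .stats import SurvivalCurve

DEFAULT_HORIZON = 60.0   # months; the 5-year evaluation window


def median_survival(curve: SurvivalCurve, horizon: float = DEFAULT_HORIZON):
    """Smallest grid time with S(t) <= 0.5, or (horizon, False) if not reached."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    hit = np.flatnonzero(curve.surv <= 0.5)
    if hit.size and curve.times[hit[0]] <= horizon:
        return float(curve.times[hit[0]]), True
    return float(horizon), False


def _median_from_matrix(surv: np.ndarray, grid: np.ndarray, horizon: float):
    """Vectorized median extraction for a survival matrix (rows = patients)."""
    below = surv <= 0.5
    within = grid <= horizon
    any_hit = (below & within).any(axis=1)
    first = np.argmax(below & within, axis=1)
    med = np.where(any_hit, grid[np.clip(first, 0, len(grid) - 1)], horizon)
    return med, any_hit


def compute_ite_and_recommend(model: CounterfactualModel,
                              covariates: pd.DataFrame,
                              actual_arm=None,
                              horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Per-patient medians, ITE, recommendation and (optional) consistency.

    Returns a frame with columns ``median_rt, median_crt, ite, rt_reached,
    crt_reached, recommended`` plus ``actual`` and ``consistent`` when the
    actual arm is supplied.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    s0, s1, grid = model.predict_counterfactual_curves(covariates)
    m0, r0 = _median_from_matrix(s0, grid, horizon)
    m1, r1 = _median_from_matrix(s1, grid, horizon)
    ite = m1 - m0
    out = pd.DataFrame({
        "median_rt": m0, "median_crt": m1, "ite": ite,
        "rt_reached": r0, "crt_reached": r1,
        "recommended": np.where(ite >= 0, ARM_CRT, 1 - ARM_CRT).astype(int),
    }, index=covariates.index)
    if actual_arm is not None:
        actual = np.asarray(actual_arm, dtype=int)
        if actual.size != len(out):
            raise ValueError("actual_arm length mismatch")
        out["actual"] = actual
        out["consistent"] = (out["recommended"].to_numpy() == actual).astype(int)
    return out


def label_consistency(recommended, actual) -> dict:
    """Group sizes: Consis./Inconsis. and recommended-RT / recommended-CRT."""
    recommended = np.asarray(recommended, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if recommended.size != actual.size:
        raise ValueError("length mismatch")
    consistent = recommended == actual
    return {
        "n": int(recommended.size),
        "consistent": int(consistent.sum()),
        "inconsistent": int((~consistent).sum()),
        "rrt": int((recommended == 0).sum()),
        "rcrt": int((recommended == 1).sum()),
    }
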