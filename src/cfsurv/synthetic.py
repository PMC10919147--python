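"""Synthetic observational GBM-like cohorts with known ground truth.

Covariates are drawn from configurable marginals (truncated normals for
the continuous ones), treatment from a logistic propensity whose
intercept is calibrated to a target treated fraction, and event times
from per-arm Weibull proportional-hazards models whose log-hazard may
include treatment-by-covariate interactions.  Because the survival law
is Weibull, the per-arm median survival — and hence the true individual
treatment effect (difference in medians) — is available in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .encoding import CATEGORICAL, validate_covariates


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic cohort generator.

    Coefficient dictionaries key features either by a continuous covariate
    name (entered standardized by the configured mean/sd) or by
    ``"variable=level"`` indicators.
    """

    n: int = 5000
    seed: int = 0
    horizon: float = 120.0
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    propensity_target_mean: float = 0.898
    propensity_coefficients: dict = field(default_factory=dict)
    shape: tuple[float, float] = (1.1, 1.1)
    scale: tuple[float, float] = (10.5, 10.5)
    base_hazard: dict = field(default_factory=dict)
    treatment_intercept: float = 0.0
    treatment_modifiers: dict = field(default_factory=dict)
    censoring_rate: float = 0.016

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.scale):
            raise ValueError("Weibull shape and scale must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(
            n=int(d.get("n", 5000)),
            seed=int(d.get("seed", 0)),
            horizon=float(d.get("horizon", 120.0)),
            continuous=d.get("continuous", {}),
            categorical=d.get("categorical", {}),
            propensity_target_mean=float(d["propensity"]["target_mean"]),
            propensity_coefficients=dict(d["propensity"].get("coefficients", {})),
            shape=tuple(float(s) for s in d["weibull"]["shape"]),
            scale=tuple(float(s) for s in d["weibull"]["scale"]),
            base_hazard=dict(d["hazard"].get("base", {})),
            treatment_intercept=float(d["hazard"].get("treatment_intercept", 0.0)),
            treatment_modifiers=dict(d["hazard"].get("treatment_modifiers", {})),
            censoring_rate=float(d["censoring"]["rate"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_params(**overrides) -> GeneratorParams:
    """Load the versioned default configuration, with field overrides."""
    text = resources.files("cfsurv.data").joinpath("default_cohort.yaml").read_text()
    params = GeneratorParams.from_dict(yaml.safe_load(text))
    for k, v in overrides.items():
        if not hasattr(params, k):
            raise TypeError(f"unknown GeneratorParams field {k!r}")
        setattr(params, k, v)
    params.__post_init__()   # re-validate after overrides
    return params


@dataclass
class Cohort:
    """Covariates, treatment arm, outcome, and (synthetic-only) ground truth."""

    covariates: pd.DataFrame
    arm: np.ndarray            # 0 = RT, 1 = CRT
    time: np.ndarray           # months
    event: np.ndarray          # 1 = cancer-specific death
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.covariates)
        for name in ("arm", "time", "event"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match covariates")
        if self.ground_truth is not None and len(self.ground_truth) != n:
            raise ValueError("ground_truth length does not match covariates")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("times must be finite and positive")

    def __len__(self) -> int:
        return len(self.covariates)

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df["arm"] = self.arm.astype(int)
        df["time"] = self.time
        df["event"] = self.event.astype(int)
        return df

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            arm=self.arm[idx], time=self.time[idx], event=self.event[idx],
            ground_truth=None if self.ground_truth is None
            else self.ground_truth.iloc[idx].reset_index(drop=True),
        )

    def save(self, cohort_path, ground_truth_path=None) -> None:
        self.to_frame().to_csv(cohort_path, index=False, float_format="%.10g")
        if ground_truth_path is not None and self.ground_truth is not None:
            self.ground_truth.to_csv(ground_truth_path, index=False, float_format="%.10g")

    @classmethod
    def load(cls, cohort_path, ground_truth_path=None) -> "Cohort":
        df = pd.read_csv(cohort_path)
        gt = pd.read_csv(ground_truth_path) if ground_truth_path else None
        cov = df.drop(columns=["arm", "time", "event"])
        validate_covariates(cov)
        return cls(covariates=cov, arm=df["arm"].to_numpy(int),
                   time=df["time"].to_numpy(float),
                   event=df["event"].to_numpy(int), ground_truth=gt)


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _feature_value(params: GeneratorParams, cov: pd.DataFrame, key: str) -> np.ndarray:
    if "=" in key:
        var, level = key.split("=", 1)
        return (cov[var].to_numpy() == level).astype(float)
    spec = params.continuous[key]
    x = cov[key].to_numpy(dtype=float)
    return (x - float(spec["mean"])) / float(spec["sd"])


def _linear_predictor(params: GeneratorParams, cov: pd.DataFrame, coefs: dict) -> np.ndarray:
    lp = np.zeros(len(cov))
    for key, c in coefs.items():
        lp += float(c) * _feature_value(params, cov, key)
    return lp


def _arm_log_hazard(params: GeneratorParams, cov: pd.DataFrame, arm: int) -> np.ndarray:
    lp = _linear_predictor(params, cov, params.base_hazard)
    if arm == 1:
        lp = lp + params.treatment_intercept
        lp = lp + _linear_predictor(params, cov, params.treatment_modifiers)
    return lp


def weibull_median(shape: float, scale: float, lp: np.ndarray) -> np.ndarray:
    """Median of S(t) = exp(-(t/scale)^shape * e^lp): scale (ln2 / e^lp)^(1/shape)."""
    return scale * (np.log(2.0) / np.exp(lp)) ** (1.0 / shape)


def true_medians(params: GeneratorParams, cov: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-arm median survival for each covariate row."""
    m0 = weibull_median(params.shape[0], params.scale[0], _arm_log_hazard(params, cov, 0))
    m1 = weibull_median(params.shape[1], params.scale[1], _arm_log_hazard(params, cov, 1))
    return m0, m1


def true_ite(params: GeneratorParams, cov: pd.DataFrame) -> np.ndarray:
    """Ground-truth treatment effect: median under arm 1 minus under arm 0."""
    m0, m1 = true_medians(params, cov)
    return m1 - m0


class OracleModel:
    """Counterfactual "model" backed by the generator's true survival laws.

    Satisfies the same prediction contract as the fitted models and is used
    to benchmark recommenders: its recommendations equal the ground-truth
    optimal arm.  The evaluation grid is augmented with the queried rows'
    exact median times so median extraction is not blurred by grid
    discretization.
    """

    kind = "oracle"

    def __init__(self, params: GeneratorParams, horizon: float = 60.0, step: float = 0.5):
        self.params = params
        self.grid = np.arange(step, horizon + step, step)

    def _survival(self, cov: pd.DataFrame, arm: int, grid: np.ndarray) -> np.ndarray:
        lp = _arm_log_hazard(self.params, cov, arm)
        shape = self.params.shape[arm]
        scale = self.params.scale[arm]
        return np.exp(-np.outer(np.exp(lp), (grid / scale) ** shape))

    def predict_survival(self, cov: pd.DataFrame, arm: int, grid=None) -> np.ndarray:
        grid = self.grid if grid is None else np.asarray(grid, dtype=float)
        return self._survival(cov, arm, grid)

    def predict_risk(self, cov: pd.DataFrame, arm: int) -> np.ndarray:
        return _arm_log_hazard(self.params, cov, arm)

    def predict_counterfactual_curves(self, cov: pd.DataFrame, grid=None):
        if grid is None:
            m0, m1 = true_medians(self.params, cov)
            grid = np.unique(np.concatenate([self.grid, m0.ravel(), m1.ravel()]))
            grid = grid[grid <= self.grid[-1]]
        else:
            grid = np.asarray(grid, dtype=float)
        return (self._survival(cov, 0, grid), self._survival(cov, 1, grid), grid)


def calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(sigmoid(lp + c)) = target."""
    if not 0 < target < 1:
        raise ValueError("target mean propensity must be in (0, 1)")
    return brentq(lambda c: expit(lp + c).mean() - target, -30.0, 30.0)


def _draw_covariates(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n
    cols: dict[str, np.ndarray] = {}
    for name, spec in params.continuous.items():
        lo, hi = float(spec["low"]), float(spec["high"])
        x = rng.normal(float(spec["mean"]), float(spec["sd"]), size=n)
        # redraw out-of-range values (truncated normal)
        bad = (x < lo) | (x > hi)
        while bad.any():
            x[bad] = rng.normal(float(spec["mean"]), float(spec["sd"]), size=bad.sum())
            bad = (x < lo) | (x > hi)
        cols[name] = np.round(x, 1)
    for name, marg in params.categorical.items():
        levels = [lvl for lvl in CATEGORICAL[name] if lvl in marg]
        probs = np.array([float(marg[lvl]) for lvl in levels])
        probs = probs / probs.sum()
        cols[name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols)


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``params.seed``.

    Per-stage generators are spawned from one seed sequence so each stage
    (covariates, treatment, event times, censoring) has its own stream.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_cov, rng_arm, rng_event, rng_cens = (np.random.default_rng(s) for s in ss.spawn(4))

    cov = _draw_covariates(params, rng_cov)
    validate_covariates(cov)

    lp_prop = _linear_predictor(params, cov, params.propensity_coefficients)
    intercept = calibrate_intercept(lp_prop, params.propensity_target_mean)
    propensity = expit(lp_prop + intercept)
    if propensity.min() > 0.999 or propensity.max() < 0.001:
        warnings.warn("degenerate propensity: one arm has vanishing probability")
    arm = (rng_arm.uniform(size=params.n) < propensity).astype(int)

    lp0 = _arm_log_hazard(params, cov, 0)
    lp1 = _arm_log_hazard(params, cov, 1)
    lp = np.where(arm == 1, lp1, lp0)
    shape = np.where(arm == 1, params.shape[1], params.shape[0])
    scale = np.where(arm == 1, params.scale[1], params.scale[0])
    u = rng_event.uniform(size=params.n)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)

    if params.censoring_rate > 0:
        t_cens = rng_cens.exponential(1.0 / params.censoring_rate, size=params.n)
    else:
        t_cens = np.full(params.n, np.inf)
    t_cens = np.minimum(t_cens, params.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    m0, m1 = true_medians(params, cov)
    gt = pd.DataFrame({
        "propensity": propensity,
        "median_rt": m0,
        "median_crt": m1,
        "true_ite": m1 - m0,
        "optimal_arm": (m1 >= m0).astype(int),   # tie goes to CRT
    })
    return Cohort(covariates=cov, arm=arm, time=time, event=event, ground_truth=gt)
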