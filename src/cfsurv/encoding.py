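"""Shared covariate schema and design-matrix encoder.

Every model in the package sees the same design matrix: continuous
covariates standardized to mean 0 / sd 1 (statistics learned from the
training split), categorical covariates one-hot encoded with the first
level as reference.  The encoder also records, for each source variable,
which design-matrix columns it owns — attribution and balance diagnostics
aggregate over those groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Continuous covariates, in canonical order.
CONTINUOUS: tuple[str, ...] = ("age", "tumor_size")

#: Categorical covariates with their full level sets (first level = reference).
CATEGORICAL: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "race": ("white", "other"),
    "married": ("no", "yes"),
    "urban": ("no", "yes"),
    "region": ("midwest", "east", "south", "oversea"),
    "income": ("low", "high"),
    "location": (
        "frontal", "temporal", "parietal", "occipital", "cerebellum",
        "cerebrum", "brainstem", "ventricle", "overlapping",
    ),
    "laterality": ("left", "mid", "right"),
    "extension": ("confined", "ventricular_system", "midline"),
    "metastasis": ("no", "yes"),
    "eor": ("biopsy", "STR", "GTR", "SpTR"),
}

COVARIATE_COLUMNS: tuple[str, ...] = CONTINUOUS + tuple(CATEGORICAL)


class SchemaError(ValueError):
    """Raised when a table does not match the covariate schema."""


def validate_covariates(df: pd.DataFrame) -> None:
    """Check a covariate table against the schema; raise SchemaError on violation."""
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing covariate columns: {missing}")
    for col in COVARIATE_COLUMNS:
        if df[col].isna().any():
            raise SchemaError(f"column {col!r} contains missing values")
    if (df["age"] < 18).any():
        raise SchemaError("age below 18")
    if (df["tumor_size"] <= 0).any():
        raise SchemaError("non-positive tumor_size")
    for col, levels in CATEGORICAL.items():
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise SchemaError(f"column {col!r} has out-of-schema levels: {sorted(bad)}")


@dataclass
class CovariateEncoder:
    """Standardize continuous and one-hot (drop-first) categorical covariates.

    Fit once on the training split and reused everywhere so that every model
    sees an identical design matrix.
    """

    continuous: tuple[str, ...] = CONTINUOUS
    categorical: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(CATEGORICAL))
    means_: dict[str, float] = field(default_factory=dict)
    sds_: dict[str, float] = field(default_factory=dict)

    def fit(self, df: pd.DataFrame) -> "CovariateEncoder":
        validate_covariates(df)
        for col in self.continuous:
            x = df[col].to_numpy(dtype=float)
            self.means_[col] = float(x.mean())
            sd = float(x.std(ddof=0))
            self.sds_[col] = sd if sd > 0 else 1.0
        return self

    @property
    def feature_names(self) -> list[str]:
        names = list(self.continuous)
        for col, levels in self.categorical.items():
            names.extend(f"{col}={lvl}" for lvl in levels[1:])
        return names

    @property
    def groups(self) -> dict[str, list[int]]:
        """Map each source variable to the design-matrix columns it owns."""
        out: dict[str, list[int]] = {}
        for i, name in enumerate(self.feature_names):
            var = name.split("=", 1)[0]
            out.setdefault(var, []).append(i)
        return out

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.means_:
            raise RuntimeError("encoder not fitted")
        validate_covariates(df)
        cols: dict[str, np.ndarray] = {}
        for col in self.continuous:
            x = df[col].to_numpy(dtype=float)
            cols[col] = (x - self.means_[col]) / self.sds_[col]
        for col, levels in self.categorical.items():
            vals = df[col].to_numpy()
            for lvl in levels[1:]:
                cols[f"{col}={lvl}"] = (vals == lvl).astype(float)
        return pd.DataFrame(cols, index=df.index)[self.feature_names]

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)

    def to_dict(self) -> dict:
        return {"means": self.means_, "sds": self.sds_}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateEncoder":
        enc = cls()
        enc.means_ = {k: float(v) for k, v in d["means"].items()}
        enc.sds_ = {k: float(v) for k, v in d["sds"].items()}
        return enc
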