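"""Fold-internal imputation and standardization.

The contract is strict fit-on-train / apply-to-held-out: every imputation
value and standardization moment is estimated from the training fold only
and then applied unchanged to the corresponding held-out fold, so no
statistic of a held-out row can leak into preprocessing.

Continuous features are median-imputed (median of the observed training
values) and standardized. By default the mean/SD are computed on the
imputed training matrix — the matrix the optimizer actually consumes — so
the transformed training fold has exactly zero mean and unit SD; a
``moments="observed"`` switch computes them from observed values only.
Binary lifestyle items are mode-imputed (ties broken toward 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateFeatureError, SchemaError

_MOMENT_MODES = ("post_impute", "observed")


@dataclass
class PreprocessParams:
    """Training-fold imputation values and standardization moments.

    One entry per feature, keyed by name; ``fold_id`` records which training
    fold the parameters were fit on, for audit logging.
    """

    medians: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    modes: dict[str, int]
    continuous_features: list[str]
    lifestyle_features: list[str]
    moments: str = "post_impute"
    fold_id: str | None = None

    @property
    def feature_names(self) -> list[str]:
        return self.continuous_features + self.lifestyle_features

    def to_json(self) -> str:
        return json.dumps(
            {
                "medians": self.medians,
                "means": self.means,
                "sds": self.sds,
                "modes": self.modes,
                "continuous_features": self.continuous_features,
                "lifestyle_features": self.lifestyle_features,
                "moments": self.moments,
                "fold_id": self.fold_id,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessParams":
        d = json.loads(text)
        d["modes"] = {k: int(v) for k, v in d["modes"].items()}
        return cls(**d)


def _median_even_lower_mid(values: np.ndarray) -> float:
    """Median as the average of the two central order statistics (the
    documented convention for even counts; equals numpy's default)."""
    return float(np.median(values))


def fit_preprocess(
    train: pd.DataFrame,
    continuous_features: list[str],
    lifestyle_features: list[str] | None = None,
    moments: str = "post_impute",
    fold_id: str | None = None,
) -> PreprocessParams:
    """Fit imputation values and standardization moments on training rows.

    Raises :class:`DegenerateFeatureError` (naming the feature) if a feature
    is entirely missing in the training fold or has zero variance.
    """
    if lifestyle_features is None:
        lifestyle_features = []
    if moments not in _MOMENT_MODES:
        raise ValueError(f"moments must be one of {_MOMENT_MODES}")
    if len(train) == 0:
        raise SchemaError("training fold is empty")
    missing = [c for c in continuous_features + lifestyle_features if c not in train.columns]
    if missing:
        raise SchemaError(f"training rows lack features: {missing}")

    medians: dict[str, float] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in continuous_features:
        col = train[name].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise DegenerateFeatureError(f"feature '{name}' fully missing in training fold")
        med = _median_even_lower_mid(observed)
        medians[name] = med
        if moments == "post_impute":
            filled = np.where(np.isnan(col), med, col)
            mu, sd = float(filled.mean()), float(filled.std(ddof=0))
        else:
            mu, sd = float(observed.mean()), float(observed.std(ddof=0))
        if sd <= 0.0:
            raise DegenerateFeatureError(f"feature '{name}' has zero variance in training fold")
        means[name], sds[name] = mu, sd

    modes: dict[str, int] = {}
    for name in lifestyle_features:
        col = train[name].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise DegenerateFeatureError(f"feature '{name}' fully missing in training fold")
        # mode of a binary item; ties broken toward 0
        modes[name] = int(observed.mean() > 0.5)

    return PreprocessParams(
        medians, means, sds, modes,
        list(continuous_features), list(lifestyle_features),
        moments=moments, fold_id=fold_id,
    )


def apply_preprocess(params: PreprocessParams, rows: pd.DataFrame) -> np.ndarray:
    """Impute and standardize ``rows`` with frozen training-fold parameters.

    Returns an (n, d) matrix ordered continuous-then-lifestyle. Continuous:
    missing -> training median, then (x - training mean) / training SD.
    Lifestyle: missing -> training mode, passed through otherwise.
    """
    missing = [c for c in params.feature_names if c not in rows.columns]
    if missing:
        raise SchemaError(f"rows lack features: {missing}")
    n = len(rows)
    X = np.empty((n, len(params.feature_names)), dtype=float)
    j = 0
    for name in params.continuous_features:
        col = rows[name].to_numpy(dtype=float)
        col = np.where(np.isnan(col), params.medians[name], col)
        X[:, j] = (col - params.means[name]) / params.sds[name]
        j += 1
    for name in params.lifestyle_features:
        col = rows[name].to_numpy(dtype=float)
        X[:, j] = np.where(np.isnan(col), params.modes[name], col)
        j += 1
    return X
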