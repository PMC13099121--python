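"""Refit-free percentile bootstrap and the HbA1c ON/OFF sensitivity analysis.

Uncertainty for the OOF metrics is quantified by resampling participants
with replacement and recomputing AUC / Brier from the already-generated
(probability, label) pairs only — the models are never refit, which
preserves the internal validation of the original cross-validated
predictions. Confidence intervals are the empirical 2.5th/97.5th
percentiles over ``n_boot`` resamples (2000 by default).

The ON/OFF sensitivity analysis reruns the *entire* nested pipeline twice —
predictor sets differing only by HbA1c — on an identical fold plan, and
bootstraps the metric difference with *paired* resampling (the same
participant draw applied to both conditions), which is the tighter interval
when the two conditions are positively correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import SchemaError, StratificationError
from .ga import GAConfig
from .oof import FoldPlan, OOFResult, make_folds, run_oof
from .metrics import auc, brier
from .synthetic import Cohort

logger = logging.getLogger(__name__)

_METRICS = ("auc", "brier")
_CHUNK = 200  # bootstrap rows per block, bounds peak memory


@dataclass
class MetricEstimate:
    """Point estimate with a 95% percentile-bootstrap interval."""

    metric: str
    point: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int
    n: int

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.point <= self.ci_upper:
            logger.warning(
                "%s point estimate %.6f outside percentile CI [%.6f, %.6f]",
                self.metric, self.point, self.ci_lower, self.ci_upper,
            )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
        }


def _metric_rows(P: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    """Metric per bootstrap row of aligned (n_rows, n) prediction/label blocks."""
    if metric == "brier":
        return np.mean((P - Y) ** 2, axis=1)
    n = P.shape[1]
    ranks = rankdata(P, method="average", axis=1)
    n_pos = Y.sum(axis=1)
    n_neg = n - n_pos
    rank_sum_pos = (ranks * Y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _resample_indices(
    n: int, n_boot: int, rng: np.random.Generator, y: np.ndarray, need_both_classes: bool
) -> np.ndarray:
    """Participant-level resample index matrix; single-class rows are redrawn.

    If more than 1% of the initial draws are single-class, resampling is
    hopeless at this sample size and an error advising a larger cohort is
    raised instead.
    """
    idx = rng.integers(0, n, size=(n_boot, n))
    if not need_both_classes:
        return idx
    pos = y[idx].sum(axis=1)
    bad = (pos == 0) | (pos == n)
    n_bad = int(bad.sum())
    if n_bad > max(1, 0.01 * n_boot):
        raise StratificationError(
            f"{n_bad}/{n_boot} resamples were single-class; metric undefined too "
            "often — use a larger cohort"
        )
    attempts = 0
    while n_bad:
        logger.info("redrawing %d single-class bootstrap resamples", n_bad)
        idx[bad] = rng.integers(0, n, size=(n_bad, n))
        pos = y[idx].sum(axis=1)
        bad = (pos == 0) | (pos == n)
        n_bad = int(bad.sum())
        attempts += 1
        if attempts > 1000:  # pragma: no cover - astronomically unlikely
            raise StratificationError("could not draw two-class resamples")
    return idx


def _bootstrap_matrix(
    preds: list[np.ndarray], y: np.ndarray, metric: str, n_boot: int, seed: int
) -> np.ndarray:
    """(n_boot, len(preds)) metric values over shared participant resamples."""
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(n, n_boot, rng, y, need_both_classes=(metric == "auc"))
    out = np.empty((n_boot, len(preds)))
    for start in range(0, n_boot, _CHUNK):
        block = idx[start : start + _CHUNK]
        Y = y[block].astype(float)
        for j, p in enumerate(preds):
            out[start : start + _CHUNK, j] = _metric_rows(p[block], Y, metric)
    return out


def _point(p: np.ndarray, y: np.ndarray, metric: str) -> float:
    return auc(p, y) if metric == "auc" else brier(p, y)


def _as_pairs(oof) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(oof, OOFResult):
        return oof.probabilities, oof.labels.astype(int)
    p, y = oof
    return np.asarray(p, dtype=float), np.asarray(y, dtype=int)


def percentile_bootstrap(
    oof, metric: str = "auc", n_boot: int = 2000, seed: int = 0
) -> MetricEstimate:
    """95% percentile-bootstrap interval for an OOF metric, refit-free.

    ``oof`` is an :class:`OOFResult` or a ``(probabilities, labels)`` pair.
    ``n_boot`` participant-level resamples with replacement; the metric is
    recomputed on each resample's (probability, label) pairs only.
    Single-class resamples (AUC undefined) are redrawn and logged.
    """
    if metric not in _METRICS:
        raise SchemaError(f"metric must be one of {_METRICS}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    p, y = _as_pairs(oof)
    vals = _bootstrap_matrix([p], y, metric, n_boot, seed)[:, 0]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return MetricEstimate(metric, _point(p, y, metric), float(lo), float(hi),
                          n_boot, seed, len(y))


@dataclass
class SensitivityResult:
    """HbA1c ON/OFF comparison under an identical evaluation pipeline."""

    on: dict[str, MetricEstimate]
    off: dict[str, MetricEstimate]
    delta: dict[str, MetricEstimate]  # ON - OFF, paired-resample CI
    fold_hash: str
    paired_resamples: bool = True
    oof_on: OOFResult | None = None
    oof_off: OOFResult | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in _METRICS:
            for cond, est in (("HBA1C_ON", self.on[metric]),
                              ("HBA1C_OFF", self.off[metric]),
                              ("DELTA_ON_MINUS_OFF", self.delta[metric])):
                d = est.to_dict()
                d["condition"] = cond
                rows.append(d)
        return pd.DataFrame(rows)


def run_on_off(
    cohort: Cohort,
    labels,
    ga_config: GAConfig | None = None,
    outer_k: int = 5,
    seed: int = 42,
    n_boot: int = 2000,
    hba1c_feature: str = "hba1c",
) -> SensitivityResult:
    """Prespecified sensitivity analysis: full pipeline with vs without HbA1c.

    Both conditions run on the identical fold plan and seeds; predictor sets
    differ only by the HbA1c column. Deltas (ON - OFF) are bootstrapped with
    paired resampling: the same participant draw is applied to both
    conditions, which is valid because the two OOF vectors are aligned on
    the same participants.
    """
    if hba1c_feature not in cohort.feature_names:
        raise SchemaError(f"cohort has no '{hba1c_feature}' feature")
    if ga_config is None:
        ga_config = GAConfig()
    features_on = list(cohort.feature_names)
    features_off = [f for f in features_on if f != hba1c_feature]

    oof_on = run_oof(cohort, labels, ga_config, outer_k, features_on, seed, "HBA1C_ON")
    oof_off = run_oof(
        cohort, labels, ga_config, outer_k, features_off, seed, "HBA1C_OFF",
        fold_plan=oof_on.fold_plan,
    )
    if oof_on.fold_plan != oof_off.fold_plan:  # pragma: no cover - construction
        raise SchemaError("ON and OFF fold plans diverged")
    if not np.array_equal(oof_on.frame["participant_id"], oof_off.frame["participant_id"]):
        raise SchemaError("ON and OFF participant alignment lost")

    y = oof_on.labels.astype(int)
    p_on, p_off = oof_on.probabilities, oof_off.probabilities
    on: dict[str, MetricEstimate] = {}
    off: dict[str, MetricEstimate] = {}
    delta: dict[str, MetricEstimate] = {}
    for metric in _METRICS:
        vals = _bootstrap_matrix([p_on, p_off], y, metric, n_boot, seed)
        lo_on, hi_on = np.percentile(vals[:, 0], [2.5, 97.5])
        lo_off, hi_off = np.percentile(vals[:, 1], [2.5, 97.5])
        d = vals[:, 0] - vals[:, 1]
        lo_d, hi_d = np.percentile(d, [2.5, 97.5])
        pt_on, pt_off = _point(p_on, y, metric), _point(p_off, y, metric)
        on[metric] = MetricEstimate(metric, pt_on, float(lo_on), float(hi_on), n_boot, seed, len(y))
        off[metric] = MetricEstimate(metric, pt_off, float(lo_off), float(hi_off), n_boot, seed, len(y))
        delta[metric] = MetricEstimate(
            f"delta_{metric}", pt_on - pt_off, float(lo_d), float(hi_d), n_boot, seed, len(y)
        )
    return SensitivityResult(
        on, off, delta, oof_on.fold_plan.fold_hash(), True, oof_on, oof_off
    )
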