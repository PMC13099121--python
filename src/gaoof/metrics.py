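"""Discrimination and calibration metrics computed from OOF predictions.

AUC follows the Mann-Whitney concordance definition with midrank handling of
ties: over all positive-negative pairs, a concordant pair scores 1, a tied
pair 0.5. The Brier score is the mean squared difference between predicted
probability and the binary outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import StratificationError


def _check_binary(y: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise StratificationError("AUC undefined: both outcome classes must be present")
    return n_pos, n_neg


def auc(scores, y) -> float:
    """Midrank (Mann-Whitney) AUC of ``scores`` against binary ``y``.

    Equals (sum over positive-negative pairs of 1[s_pos > s_neg] +
    0.5*1[s_pos == s_neg]) / (n_pos * n_neg), computed in O(n log n) via
    average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos, n_neg = _check_binary(y)
    ranks = rankdata(scores, method="average")
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_columns(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Midrank AUC of each column of ``S`` against ``y`` (vectorized; used to
    score a whole GA population in one pass)."""
    y = np.asarray(y)
    n_pos, n_neg = _check_binary(y)
    ranks = rankdata(S, method="average", axis=0)
    rank_sum_pos = ranks[y == 1].sum(axis=0)
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def brier(p, y) -> float:
    """Mean squared error between predicted probability and binary outcome."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same shape")
    return float(np.mean((p - y) ** 2))


def calibration_bins(p, y, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration-bin table on [0, 1].

    One row per bin: count, mean predicted probability, observed event
    fraction (NaN for empty bins, which are reported with count 0). This is
    the tabular form of a reliability diagram.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        count = int(in_bin.sum())
        rows.append(
            {
                "bin": b,
                "lower": b / n_bins,
                "upper": (b + 1) / n_bins,
                "count": count,
                "mean_predicted": float(p[in_bin].mean()) if count else np.nan,
                "observed_fraction": float(y[in_bin].mean()) if count else np.nan,
            }
        )
    return pd.DataFrame(rows)
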