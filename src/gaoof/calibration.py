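"""Platt scaling: mapping composite scores to calibrated probabilities.

A univariate logistic regression p = sigmoid(a + b*s) is fit by Newton
iteration on the training-fold scores only, with a small ridge penalty
(lambda = 1e-6 on both coefficients) so that perfectly separating scores —
which a GA-optimized composite can produce on small folds — yield finite
coefficients instead of divergence. Because the sigmoid is strictly
monotone, calibration changes no rank: the AUC of the calibrated
probabilities equals the AUC of the raw scores whenever b > 0. If the GA
happens to return an inverted score the fitted b is negative; the model is
kept as-is (the probabilities are still correct) and a warning is logged.

An optional post-hoc Bayesian prior-odds update is provided purely as a
reporting layer; it never feeds back into optimization or the metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import StratificationError

logger = logging.getLogger(__name__)

_RIDGE = 1e-6
_MAX_EXP = 36.0  # |a + b*s| clip; keeps probabilities strictly inside (0, 1)


@dataclass
class PlattModel:
    a: float
    b: float
    converged: bool
    n_iter: int
    log_likelihood: float

    def to_json_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
        }


def fit_platt(
    s,
    y,
    ridge: float = _RIDGE,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PlattModel:
    """Fit p = sigmoid(a + b*s) by ridge-penalized Newton iteration.

    Converged when the penalized gradient's max-norm drops below ``tol``;
    after ``max_iter`` iterations the best iterate is returned with
    ``converged=False`` and a logged warning.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise StratificationError("Platt fit needs both outcome classes")

    # standardize the score internally for Newton stability, back-transform at the end
    mu, sd = float(s.mean()), float(s.std(ddof=0))
    if sd == 0.0:
        sd = 1.0
    z = (s - mu) / sd
    D = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(np.clip(D @ beta, -_MAX_EXP, _MAX_EXP))
        grad = D.T @ (y - p) - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (D * w[:, None]).T @ D + ridge * np.eye(2)
        beta = beta + np.linalg.solve(H, grad)
    if not converged:
        logger.warning("Platt fit did not converge in %d iterations", max_iter)

    a_z, b_z = float(beta[0]), float(beta[1])
    b = b_z / sd
    a = a_z - b * mu
    if b < 0:
        logger.warning("Platt slope is negative (b=%.4g): inverted score kept as-is", b)
    p = expit(np.clip(a + b * s, -_MAX_EXP, _MAX_EXP))
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return PlattModel(a=a, b=b, converged=converged, n_iter=it, log_likelihood=ll)


def predict_prob(model: PlattModel, s) -> np.ndarray:
    """Calibrated probability sigmoid(a + b*s), strictly inside (0, 1)."""
    s = np.asarray(s, dtype=float)
    return expit(np.clip(model.a + model.b * s, -_MAX_EXP, _MAX_EXP))


def bayes_update(p, prior_odds_ratio: float) -> np.ndarray:
    """Post-hoc prior-odds update: odds' = prior_odds_ratio * p/(1-p).

    A transparent interpretability layer only; monotone in p, so it changes
    no rank (AUC is invariant). Off by default everywhere and excluded from
    all reported metrics.
    """
    if prior_odds_ratio <= 0:
        raise ValueError("prior_odds_ratio must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must be strictly inside (0, 1)")
    odds = prior_odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)
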