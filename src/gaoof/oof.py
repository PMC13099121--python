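"""Nested out-of-fold (OOF) orchestration.

Per outer fold, everything that can learn from data is fit on the training
subset only: preprocessing parameters, the GA weight vector (re-evolved from
scratch inside every outer training fold — the only leakage-free reading of
"train on the training subset"), and the Platt calibration. The held-out
fold receives a probability from a model that never saw it; aggregating
those gives each labeled participant exactly one internally validated OOF
prediction.

``run_oof_leaky`` is a deliberately broken negative control — preprocessing
fit on the full cohort and a single GA evolved on the full matrix (labels
included) — kept only so tests can demonstrate the leakage inflation the
nested design prevents. It must never be used for reported metrics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .calibration import PlattModel, fit_platt, predict_prob
from .errors import DegenerateFeatureError, SchemaError, StratificationError
from .ga import EvolutionResult, GAConfig, composite_score, evolve
from .grading import OutcomeLabels
from .metrics import auc, brier, calibration_bins
from .preprocessing import apply_preprocess, fit_preprocess
from .synthetic import Cohort


@dataclass
class FoldPlan:
    """Stratified, shuffled partition of the labeled cohort into outer folds."""

    outer_k: int
    participant_ids: np.ndarray
    fold_index: np.ndarray
    seed: int
    stratified: bool = True

    def fold_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.fold_index, dtype=np.int64).tobytes())
        h.update("|".join(map(str, self.participant_ids)).encode())
        return h.hexdigest()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FoldPlan)
            and self.outer_k == other.outer_k
            and self.fold_hash() == other.fold_hash()
        )


def _as_label_series(labels) -> pd.Series:
    if isinstance(labels, OutcomeLabels):
        return labels.labels
    if isinstance(labels, pd.Series):
        return labels.astype(int)
    raise SchemaError("labels must be OutcomeLabels or a participant-indexed Series")


def make_folds(labels, outer_k: int = 5, seed: int = 42) -> FoldPlan:
    """Stratified K-fold assignment with shuffling, deterministic given seed.

    Raises :class:`StratificationError` when either class has fewer members
    than ``outer_k`` (which would force single-class folds).
    """
    lab = _as_label_series(labels)
    y = lab.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both outcome classes must be present")
    if counts.min() < outer_k:
        raise StratificationError(
            f"minority class has {counts.min()} members; cannot build {outer_k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_index[test_idx] = f
    return FoldPlan(outer_k, lab.index.to_numpy(), fold_index, seed)


@dataclass
class FoldAudit:
    """Per-fold provenance: what was fit on which training fold."""

    fold: int
    n_train: int
    n_test: int
    preprocess_json: str
    weights: np.ndarray
    platt: PlattModel
    ga_log: pd.DataFrame


@dataclass
class OOFResult:
    """Aggregated out-of-fold predictions with full run metadata."""

    frame: pd.DataFrame  # participant_id, fold, condition, probability, label, year
    fold_plan: FoldPlan
    feature_set: list[str]
    ga_config: GAConfig
    seed: int
    condition: str
    fold_audits: list[FoldAudit] = field(default_factory=list)

    @property
    def probabilities(self) -> np.ndarray:
        return self.frame["probability"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def auc(self) -> float:
        return auc(self.probabilities, self.labels)

    def brier(self) -> float:
        return brier(self.probabilities, self.labels)

    def calibration_table(self, n_bins: int = 10) -> pd.DataFrame:
        return calibration_bins(self.probabilities, self.labels, n_bins)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _labeled_frame(cohort: Cohort, labels) -> tuple[pd.DataFrame, np.ndarray]:
    lab = _as_label_series(labels)
    df = cohort.data
    known = df["participant_id"].isin(lab.index)
    sub = df.loc[known].reset_index(drop=True)
    y = lab.loc[sub["participant_id"]].to_numpy()
    return sub, y


def _split_feature_set(cohort: Cohort, feature_set: list[str]) -> tuple[list[str], list[str]]:
    unknown = [f for f in feature_set if f not in cohort.feature_names]
    if unknown:
        raise SchemaError(f"feature_set not in cohort: {unknown}")
    cont = [f for f in cohort.continuous_features if f in feature_set]
    life = [f for f in cohort.lifestyle_features if f in feature_set]
    return cont, life


def run_oof(
    cohort: Cohort,
    labels,
    ga_config: GAConfig | None = None,
    outer_k: int = 5,
    feature_set: list[str] | None = None,
    seed: int = 42,
    condition: str | None = None,
    fold_plan: FoldPlan | None = None,
) -> OOFResult:
    """Run the full nested OOF pipeline and aggregate the predictions.

    For each outer fold: fit preprocessing on the training rows, apply it to
    train and held-out rows, evolve GA weights on the training matrix, fit
    Platt calibration on the training composite scores, and predict the
    held-out fold. No statistic of any held-out row enters preprocessing, GA
    fitness or Platt fitting for its fold.
    """
    if ga_config is None:
        ga_config = GAConfig()
    if feature_set is None:
        feature_set = cohort.feature_names
    cont, life = _split_feature_set(cohort, feature_set)
    if condition is None:
        condition = "HBA1C_ON" if "hba1c" in feature_set else "HBA1C_OFF"

    sub, y = _labeled_frame(cohort, labels)
    if fold_plan is None:
        fold_plan = make_folds(pd.Series(y, index=sub["participant_id"]), outer_k, seed)
    else:
        if len(fold_plan.fold_index) != len(sub):
            raise SchemaError("fold_plan does not cover the labeled cohort")

    probs = np.full(len(sub), np.nan)
    audits: list[FoldAudit] = []
    for f in range(fold_plan.outer_k):
        test_mask = fold_plan.fold_index == f
        train_df = sub.loc[~test_mask]
        test_df = sub.loc[test_mask]
        try:
            params = fit_preprocess(train_df, cont, life, fold_id=f"outer_{f}")
        except DegenerateFeatureError as err:
            raise DegenerateFeatureError(f"outer fold {f}: {err}") from err
        X_train = apply_preprocess(params, train_df)
        X_test = apply_preprocess(params, test_df)
        y_train = y[~test_mask]

        result = evolve(X_train, y_train, ga_config)
        s_train = composite_score(result.weights, X_train)
        platt = fit_platt(s_train, y_train)
        probs[test_mask] = predict_prob(platt, composite_score(result.weights, X_test))
        audits.append(
            FoldAudit(
                fold=f,
                n_train=len(train_df),
                n_test=len(test_df),
                preprocess_json=params.to_json(),
                weights=result.weights,
                platt=platt,
                ga_log=result.log,
            )
        )

    frame = pd.DataFrame(
        {
            "participant_id": sub["participant_id"].to_numpy(),
            "fold": fold_plan.fold_index,
            "condition": condition,
            "probability": probs,
            "label": y,
            "year": sub["year"].to_numpy() if "year" in sub.columns else -1,
        }
    )
    return OOFResult(frame, fold_plan, list(feature_set), ga_config, seed, condition, audits)


def run_oof_leaky(
    cohort: Cohort,
    labels,
    ga_config: GAConfig | None = None,
    outer_k: int = 5,
    feature_set: list[str] | None = None,
    seed: int = 42,
) -> OOFResult:
    """Deliberately broken variant: global preprocessing + non-nested GA.

    Preprocessing parameters are fit on the *entire* labeled cohort and a
    single GA is evolved on the full matrix, so every "held-out" prediction
    comes from a model that has already seen that participant's features and
    label through the inner-CV fitness. On null-signal data this inflates
    the apparent OOF AUC above chance — the failure mode the nested pipeline
    exists to prevent. Negative control for tests only.
    """
    if ga_config is None:
        ga_config = GAConfig()
    if feature_set is None:
        feature_set = cohort.feature_names
    cont, life = _split_feature_set(cohort, feature_set)
    sub, y = _labeled_frame(cohort, labels)
    fold_plan = make_folds(pd.Series(y, index=sub["participant_id"]), outer_k, seed)

    # leakage #1: preprocessing fit on all rows, held-out included
    params = fit_preprocess(sub, cont, life, fold_id="GLOBAL")
    X_all = apply_preprocess(params, sub)
    # leakage #2: one GA sees every label through its CV fitness
    result = evolve(X_all, y, ga_config)
    s_all = composite_score(result.weights, X_all)

    probs = np.full(len(sub), np.nan)
    for f in range(fold_plan.outer_k):
        test_mask = fold_plan.fold_index == f
        platt = fit_platt(s_all[~test_mask], y[~test_mask])
        probs[test_mask] = predict_prob(platt, s_all[test_mask])

    frame = pd.DataFrame(
        {
            "participant_id": sub["participant_id"].to_numpy(),
            "fold": fold_plan.fold_index,
            "condition": "LEAKY_CONTROL",
            "probability": probs,
            "label": y,
            "year": sub["year"].to_numpy() if "year" in sub.columns else -1,
        }
    )
    return OOFResult(frame, fold_plan, list(feature_set), ga_config, seed, "LEAKY_CONTROL", [])
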