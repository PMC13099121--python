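"""Threshold-based A-D domain grading and the OR-rule composite outcome.

Each clinical domain (glucose metabolism, blood pressure, lipids, liver
enzymes, anthropometric indices) grades its contributing indicators through
ordered threshold intervals into A (no abnormality), B (mild abnormality /
lifestyle guidance), C (follow-up or re-evaluation) or D (referral for
diagnosis or treatment); the domain receives the worst grade among its
indicators. The composite outcome is the OR rule over domains: positive iff
any domain reaches grade B or higher. Participants flagged grade E (already
under active treatment) are excluded from labelling.

The shipped rule set (``default_rules``) is a synthetic fixture with
round-number thresholds loosely modeled on Japanese screening conventions;
it is explicitly non-authoritative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import Cohort

logger = logging.getLogger(__name__)

GRADES = ["A", "B", "C", "D"]
_GRADE_ORD = {g: i for i, g in enumerate(GRADES)}
_SEX_KEYS = {0: "female", 1: "male"}


@dataclass
class IndicatorRule:
    """Ordered threshold intervals for one indicator.

    ``breakpoints`` (strictly increasing, length k) split the real line into
    k+1 contiguous intervals; ``grades`` (length k+1) names the grade of each
    interval. A value equal to a breakpoint falls in the upper interval, so
    breakpoints act as inclusive lower bounds of the next interval.
    """

    breakpoints: np.ndarray
    grades: list[str]

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.breakpoints.ndim != 1 or len(self.grades) != len(self.breakpoints) + 1:
            raise SchemaError("need len(grades) == len(breakpoints) + 1")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise SchemaError("breakpoints must be strictly increasing")
        unknown = set(self.grades) - set(GRADES)
        if unknown:
            raise SchemaError(f"unknown grades {sorted(unknown)}; must be A-D")

    def grade_ordinal(self, values: np.ndarray) -> np.ndarray:
        """Ordinal grade (A=0 .. D=3) per value; NaN values yield -1."""
        idx = np.searchsorted(self.breakpoints, values, side="right")
        ords = np.array([_GRADE_ORD[g] for g in self.grades])
        out = np.where(np.isnan(values), -1, ords[np.clip(idx, 0, len(self.grades) - 1)])
        return out.astype(int)


@dataclass
class GradingRuleSet:
    """Per-domain grading rules; values are either an IndicatorRule or a
    dict of sex-key ("male"/"female") to IndicatorRule for sex-specific
    thresholds."""

    domains: dict[str, dict[str, IndicatorRule | dict[str, IndicatorRule]]]
    description: str = ""

    @property
    def domain_names(self) -> list[str]:
        return list(self.domains)

    @classmethod
    def from_dict(cls, d: dict) -> "GradingRuleSet":
        domains: dict = {}
        for dom, indicators in d["domains"].items():
            domains[dom] = {}
            for ind, entry in indicators.items():
                if "by_sex" in entry:
                    domains[dom][ind] = {
                        sex: IndicatorRule(v["breakpoints"], v["grades"])
                        for sex, v in entry["by_sex"].items()
                    }
                else:
                    domains[dom][ind] = IndicatorRule(entry["breakpoints"], entry["grades"])
        return cls(domains, d.get("description", ""))

    @classmethod
    def from_json(cls, path: str | Path) -> "GradingRuleSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        out: dict = {"description": self.description, "domains": {}}
        for dom, indicators in self.domains.items():
            out["domains"][dom] = {}
            for ind, rule in indicators.items():
                if isinstance(rule, dict):
                    out["domains"][dom][ind] = {
                        "by_sex": {
                            s: {"breakpoints": r.breakpoints.tolist(), "grades": r.grades}
                            for s, r in rule.items()
                        }
                    }
                else:
                    out["domains"][dom][ind] = {
                        "breakpoints": rule.breakpoints.tolist(),
                        "grades": rule.grades,
                    }
        return out

    def indicators(self) -> set[str]:
        return {ind for doms in self.domains.values() for ind in doms}


def default_rules() -> GradingRuleSet:
    """The shipped synthetic fixture rule set (non-authoritative)."""
    text = resources.files("gaoof.data").joinpath("grading_rules.json").read_text()
    return GradingRuleSet.from_dict(json.loads(text))


@dataclass
class OutcomeLabels:
    """Binary composite labels for non-excluded participants."""

    labels: pd.Series  # participant_id -> 0/1
    excluded_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.labels.index) & set(self.excluded_ids):
            raise SchemaError("excluded participants must not carry labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


def _indicator_ordinals(
    rule: IndicatorRule | dict[str, IndicatorRule],
    values: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    if isinstance(rule, dict):
        out = np.full(len(values), -1, dtype=int)
        for code, key in _SEX_KEYS.items():
            if key not in rule:
                raise SchemaError(f"sex-specific rule missing variant '{key}'")
            mask = sex == code
            out[mask] = rule[key].grade_ordinal(values[mask])
        return out
    return rule.grade_ordinal(values)


def assign_grades(cohort: Cohort, rules: GradingRuleSet) -> Cohort:
    """Grade every domain for every participant (worst-case aggregation).

    Adds one ``grade_<domain>`` column per domain with letters A-D and a
    boolean ``grade_<domain>_defaulted`` column marking participants whose
    contributing indicators were all missing: those default to grade A (the
    OR rule across the remaining domains still ascertains the outcome) and
    are flagged for sensitivity checking rather than dropped.
    """
    df = cohort.data.copy()
    missing_cols = rules.indicators() - set(df.columns)
    if missing_cols:
        raise SchemaError(f"rules reference unknown indicators: {sorted(missing_cols)}")
    sex = df["sex"].to_numpy() if "sex" in df.columns else np.zeros(len(df), dtype=int)
    for dom, indicators in rules.domains.items():
        worst = np.full(len(df), -1, dtype=int)
        for ind, rule in indicators.items():
            ords = _indicator_ordinals(rule, df[ind].to_numpy(dtype=float), sex)
            worst = np.maximum(worst, ords)
        defaulted = worst < 0
        if defaulted.any():
            logger.warning(
                "domain %s: %d participants with all indicators missing "
                "graded A by default",
                dom,
                int(defaulted.sum()),
            )
        worst = np.where(defaulted, 0, worst)
        df[f"grade_{dom}"] = np.array(GRADES)[worst]
        df[f"grade_{dom}_defaulted"] = defaulted
    return Cohort(df, cohort.continuous_features, cohort.lifestyle_features, cohort.config)


def binarize_or_rule(cohort: Cohort) -> OutcomeLabels:
    """OR-rule composite label: 1 iff any domain grade is B or higher.

    Grade-E participants (under active treatment, ``grade_e`` flag) are
    excluded from labelling entirely. Requires grades assigned first.
    """
    df = cohort.data
    grade_cols = [
        c for c in df.columns if c.startswith("grade_") and not c.endswith("_defaulted")
        and c != "grade_e"
    ]
    if not grade_cols:
        raise SchemaError("no domain grades present; run assign_grades first")
    if df[grade_cols].isna().any().any():
        raise SchemaError("missing domain grades; run assign_grades first")
    grade_e = df["grade_e"].astype(bool) if "grade_e" in df.columns else pd.Series(
        False, index=df.index
    )
    positive = (df[grade_cols] != "A").any(axis=1).astype(int)
    keep = ~grade_e.to_numpy()
    labels = pd.Series(
        positive.to_numpy()[keep],
        index=pd.Index(df["participant_id"].to_numpy()[keep], name="participant_id"),
    )
    excluded = frozenset(df["participant_id"].to_numpy()[~keep])
    return OutcomeLabels(labels, excluded)
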