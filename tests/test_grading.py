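"""A-D domain grading and the OR-rule composite outcome."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gaoof import (
    Cohort,
    GradingRuleSet,
    SchemaError,
    assign_grades,
    binarize_or_rule,
    default_rules,
)
from gaoof.grading import GRADES, IndicatorRule


def _toy_cohort(rows: dict) -> Cohort:
    """Build a minimal cohort from explicit per-column lists."""
    n = len(next(iter(rows.values())))
    df = pd.DataFrame(rows)
    if "participant_id" not in df:
        df["participant_id"] = [f"T{i}" for i in range(n)]
    if "sex" not in df:
        df["sex"] = 1
    cont = [c for c in rows if c not in ("participant_id", "sex", "grade_e")]
    return Cohort(df, cont, [], None)


class TestIndicatorRule:
    def test_interval_lookup_inclusive_lower_bound(self):
        rule = IndicatorRule([130, 140, 160], ["A", "B", "C", "D"])
        vals = np.array([129.9, 130.0, 135.0, 140.0, 200.0])
        assert [GRADES[i] for i in rule.grade_ordinal(vals)] == ["A", "B", "B", "C", "D"]

    def test_descending_grades_for_protective_indicator(self):
        # HDL-style: low values are the abnormal ones
        rule = IndicatorRule([30, 35, 40], ["D", "C", "B", "A"])
        assert [GRADES[i] for i in rule.grade_ordinal(np.array([25, 32, 38, 60]))] == [
            "D", "C", "B", "A",
        ]

    def test_invalid_rules_rejected(self):
        with pytest.raises(SchemaError):
            IndicatorRule([140, 130], ["A", "B", "C"])
        with pytest.raises(SchemaError):
            IndicatorRule([130], ["A", "B", "C"])
        with pytest.raises(SchemaError):
            IndicatorRule([130], ["A", "E"])


class TestAssignGrades:
    def test_all_values_in_a_interval_grade_a(self, rules):
        # midpoints of every A interval -> grade A everywhere
        cohort = _toy_cohort({
            "fpg": [90.0], "hba1c": [5.0], "sbp": [110.0], "dbp": [70.0],
            "tg": [80.0], "hdl": [60.0], "ldl": [100.0],
            "ast": [20.0], "alt": [20.0], "ggt": [30.0],
            "bmi": [22.0], "waist": [75.0],
        })
        graded = assign_grades(cohort, rules)
        for dom in rules.domain_names:
            assert graded.data[f"grade_{dom}"].iloc[0] == "A"

    def test_sbp_135_grades_blood_pressure_b(self, rules):
        cohort = _toy_cohort({
            "fpg": [90.0], "hba1c": [5.0], "sbp": [135.0], "dbp": [70.0],
            "tg": [80.0], "hdl": [60.0], "ldl": [100.0],
            "ast": [20.0], "alt": [20.0], "ggt": [30.0],
            "bmi": [22.0], "waist": [75.0],
        })
        graded = assign_grades(cohort, rules)
        assert graded.data["grade_blood_pressure"].iloc[0] == "B"

    def test_waist_threshold_is_sex_specific(self, rules):
        # waist 85 crosses the male threshold (85) but not the female one (90)
        cohort = _toy_cohort({
            "fpg": [90.0, 90.0], "hba1c": [5.0, 5.0], "sbp": [110.0, 110.0],
            "dbp": [70.0, 70.0], "tg": [80.0, 80.0], "hdl": [60.0, 60.0],
            "ldl": [100.0, 100.0], "ast": [20.0, 20.0], "alt": [20.0, 20.0],
            "ggt": [30.0, 30.0], "bmi": [22.0, 22.0], "waist": [85.0, 85.0],
            "sex": [1, 0],
        })
        graded = assign_grades(cohort, rules)
        assert graded.data["grade_anthropometric"].tolist() == ["B", "A"]

    def test_domain_takes_worst_indicator_grade(self, rules):
        cohort = _toy_cohort({
            "fpg": [90.0], "hba1c": [6.2], "sbp": [110.0], "dbp": [70.0],
            "tg": [80.0], "hdl": [60.0], "ldl": [100.0],
            "ast": [20.0], "alt": [20.0], "ggt": [30.0],
            "bmi": [22.0], "waist": [75.0],
        })
        graded = assign_grades(cohort, rules)
        # fpg is A but hba1c 6.2 is C -> glucose domain C
        assert graded.data["grade_glucose_metabolism"].iloc[0] == "C"

    def test_all_missing_domain_defaults_to_a_with_flag(self, rules):
        cohort = _toy_cohort({
            "fpg": [np.nan], "hba1c": [np.nan], "sbp": [135.0], "dbp": [70.0],
            "tg": [80.0], "hdl": [60.0], "ldl": [100.0],
            "ast": [20.0], "alt": [20.0], "ggt": [30.0],
            "bmi": [22.0], "waist": [75.0],
        })
        graded = assign_grades(cohort, rules)
        assert graded.data["grade_glucose_metabolism"].iloc[0] == "A"
        assert bool(graded.data["grade_glucose_metabolism_defaulted"].iloc[0])
        assert not bool(graded.data["grade_blood_pressure_defaulted"].iloc[0])

    def test_unknown_indicator_raises_schema_error(self):
        rules = GradingRuleSet.from_dict(
            {"domains": {"glucose": {"nonexistent": {
                "breakpoints": [1.0], "grades": ["A", "B"]}}}}
        )
        cohort = _toy_cohort({"fpg": [90.0]})
        with pytest.raises(SchemaError, match="nonexistent"):
            assign_grades(cohort, rules)

    def test_rules_json_round_trip(self, tmp_path, rules):
        path = tmp_path / "rules.json"
        import json

        path.write_text(json.dumps(rules.to_dict()))
        back = GradingRuleSet.from_json(path)
        assert back.domain_names == rules.domain_names
        assert back.to_dict() == rules.to_dict()


def _grades_cohort(grade_rows: list[dict], grade_e=None) -> Cohort:
    n = len(grade_rows)
    df = pd.DataFrame({"participant_id": [f"G{i}" for i in range(n)]})
    for dom in grade_rows[0]:
        df[f"grade_{dom}"] = [r[dom] for r in grade_rows]
    df["grade_e"] = grade_e if grade_e is not None else [False] * n
    return Cohort(df, [], [], None)


class TestBinarizeOrRule:
    def test_all_clear_is_negative(self):
        labels = binarize_or_rule(_grades_cohort(
            [{"glucose": "A", "bp": "A", "lipid": "A", "liver": "A", "anthro": "A"}]
        ))
        assert labels.labels.iloc[0] == 0

    def test_single_grade_b_is_positive(self):
        labels = binarize_or_rule(_grades_cohort(
            [{"glucose": "A", "bp": "B", "lipid": "A", "liver": "A", "anthro": "A"}]
        ))
        assert labels.labels.iloc[0] == 1

    def test_hand_counted_toy_table(self):
        # 10 participants, 4 with at least one grade >= B, one grade-E:
        # 4 positives among 9 labeled (the grade-E row is one of the negatives)
        rows = [
            {"g": "A", "b": "A"}, {"g": "B", "b": "A"}, {"g": "A", "b": "C"},
            {"g": "A", "b": "A"}, {"g": "D", "b": "A"}, {"g": "A", "b": "A"},
            {"g": "A", "b": "B"}, {"g": "A", "b": "A"}, {"g": "A", "b": "A"},
            {"g": "A", "b": "A"},
        ]
        grade_e = [False] * 10
        grade_e[9] = True
        labels = binarize_or_rule(_grades_cohort(rows, grade_e))
        assert labels.n == 9
        assert labels.labels.sum() == 4
        assert labels.excluded_ids == frozenset({"G9"})

    def test_exhaustive_or_rule_equivalence(self):
        # label == 1 - prod(grade == A) over all 4^5 five-domain combinations
        doms = ["d1", "d2", "d3", "d4", "d5"]
        combos = list(itertools.product(GRADES, repeat=5))
        rows = [dict(zip(doms, combo)) for combo in combos]
        labels = binarize_or_rule(_grades_cohort(rows))
        expected = [1 - int(all(g == "A" for g in combo)) for combo in combos]
        assert labels.labels.tolist() == expected

    def test_monotonicity_worsening_never_flips_positive_to_negative(self):
        doms = ["d1", "d2", "d3"]
        combos = list(itertools.product(GRADES, repeat=3))
        rows = [dict(zip(doms, combo)) for combo in combos]
        labels = binarize_or_rule(_grades_cohort(rows)).labels
        ordinal = {g: i for i, g in enumerate(GRADES)}
        for i, ci in enumerate(combos):
            for j, cj in enumerate(combos):
                if all(ordinal[a] <= ordinal[b] for a, b in zip(ci, cj)):
                    assert labels.iloc[i] <= labels.iloc[j]

    def test_requires_grades(self):
        cohort = _toy_cohort({"fpg": [90.0]})
        with pytest.raises(SchemaError, match="assign_grades"):
            binarize_or_rule(cohort)

    def test_excluded_disjoint_from_labeled(self, rules):
        from gaoof import SyntheticConfig, generate_cohort

        cohort = generate_cohort(SyntheticConfig(n_participants=500, seed=2,
                                                 grade_e_fraction=0.1))
        labels = binarize_or_rule(assign_grades(cohort, rules))
        assert not set(labels.labels.index) & set(labels.excluded_ids)
        assert labels.n + len(labels.excluded_ids) == 500
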