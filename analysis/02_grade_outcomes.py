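"""Grade each cohort A-D per clinical domain and build the OR-rule outcome.

Applies the shipped (synthetic, non-authoritative) grading rule set to the
simulated cohorts, excludes grade-E (under-treatment) participants, and
labels everyone else positive iff any domain reaches grade B or higher.
Writes results/outcome_prevalence.csv.
"""

from pathlib import Path

import pandas as pd

from gaoof import assign_grades, binarize_or_rule, default_rules, validate_cohort_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rules = default_rules()
    rows = []
    for path in sorted((ROOT / "cohorts").glob("cohort_*.csv")):
        cohort = validate_cohort_csv(path)
        year = int(cohort.data["year"].iloc[0])
        labels = binarize_or_rule(assign_grades(cohort, rules))
        rows.append(
            {
                "year": year,
                "n_examined": cohort.n,
                "n_grade_e_excluded": len(labels.excluded_ids),
                "n_labeled": labels.n,
                "prevalence": round(labels.prevalence, 4),
            }
        )
        print(
            f"{year}: {labels.n} labeled ({len(labels.excluded_ids)} grade-E "
            f"excluded), OR-rule prevalence {labels.prevalence:.3f}"
        )
    pd.DataFrame(rows).to_csv(ROOT / "outcome_prevalence.csv", index=False)


if __name__ == "__main__":
    main()
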