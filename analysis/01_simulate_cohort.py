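"""Simulate the synthetic training and validation cohorts and summarize them.

Writes results/cohort_summary.csv (per-group patient/ear counts, gender and
grade distributions) and the two cohort tables with landmark files.
"""

import pandas as pd

import earmorph as em
from common import RESULTS, training_config, validation_config


def summarize(cohort: em.Cohort, label: str) -> pd.DataFrame:
    frame = cohort.to_frame()
    rows = []
    for group, sub in frame.groupby("group"):
        rows.append(
            {
                "cohort": label,
                "group": group,
                "n_ears": len(sub),
                "n_patients": sub["patient_id"].nunique(),
                "pct_female": round(
                    sub.drop_duplicates("patient_id")["gender"].eq("female").mean(), 2
                ),
                "mean_age": round(sub["age"].mean(), 1),
                "pct_grade_0_1": round(sub["marx_grade"].le(1).mean(), 2),
                "pct_annotated": round(sub["has_landmarks"].mean(), 2),
            }
        )
    return pd.DataFrame(rows)


def main() -> None:
    out = RESULTS / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    training = em.simulate_cohort(training_config())
    validation = em.simulate_cohort(validation_config())
    em.write_cohort_table(training, out / "cohort_training.csv",
                          landmark_dir="landmarks_training")
    em.write_cohort_table(validation, out / "cohort_validation.csv",
                          landmark_dir="landmarks_validation")
    summary = pd.concat(
        [summarize(training, "training"), summarize(validation, "validation")]
    )
    summary.to_csv(out / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\ntraining: {len(training)} ears; validation: {len(validation)} ears")


if __name__ == "__main__":
    main()
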