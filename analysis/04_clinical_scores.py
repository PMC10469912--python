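"""Severity and asymmetry scores per patient, compared between groups.

Writes results/analysis/patient_scores.csv and group_comparisons.csv
(MFDM-referenced contrasts with t tests).
"""

import warnings

import pandas as pd

import earmorph as em
from common import RESULTS, training_config


def main() -> None:
    out = RESULTS / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    training = em.simulate_cohort(training_config())
    scores, fa_max = em.compute_patient_scores(training)
    group_of = {r.patient_id: r.group for r in training.records}
    frame = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "group": group_of[s.patient_id],
                "severity": s.severity,
                "asymmetry": s.asymmetry,
            }
            for s in scores.values()
        ]
    )
    frame.to_csv(out / "patient_scores.csv", index=False)

    tables = []
    for score_name in ("severity", "asymmetry"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparison = em.compare_scores_between_groups(
                frame[score_name], frame["group"], reference_group="MFDM"
            )
        table = comparison.table.copy()
        table.insert(0, "score", score_name)
        tables.append(table)
    result = pd.concat(tables)
    result.to_csv(out / "group_comparisons.csv")
    print(f"scored {len(frame)} patients (FA normalization constant {fa_max:.4f})")
    print("\nMFDM-referenced contrasts (negative estimate = lower than MFDM):")
    print(result.round(4).to_string())


if __name__ == "__main__":
    main()
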