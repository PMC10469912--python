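"""Metric engine applied to the built-in reference validation confusion
matrices; reproduces the published metric tables cell by cell.

Writes results/analysis/fixture_metrics.csv.
"""

import pandas as pd

import earmorph as em
from common import RESULTS


def main() -> None:
    out = RESULTS / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for design, fixture in em.reference_confusion_matrices().items():
        report = em.metrics_from_confusion(fixture.matrix, list(fixture.labels))
        rows.append(
            {
                "design": design, "metric": "accuracy", "class": "",
                "value": round(report.accuracy, 3),
                "extra": f"[{report.ci_lower:.3f}-{report.ci_upper:.3f}] "
                         f"p={report.nir_p_value:.2g}",
            }
        )
        for cls in fixture.labels:
            for metric in ("sensitivity", "specificity", "balanced_accuracy"):
                rows.append(
                    {
                        "design": design, "metric": metric, "class": cls,
                        "value": round(float(report.per_class.loc[cls, metric]), 3),
                        "extra": "",
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(out / "fixture_metrics.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
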