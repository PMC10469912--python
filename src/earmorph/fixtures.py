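"""Reference confusion matrices from the original clinical validation study.

These three integer matrices (prediction rows x reference columns, label
order as printed in the source study's validation tables) are evaluation
fixtures: the metric engine must reproduce every metric derivable from them.
They are data, not computed output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionFixture:
    design: str
    labels: tuple[str, ...]
    matrix: np.ndarray  # prediction rows x reference columns


def reference_confusion_matrices() -> dict[str, ConfusionFixture]:
    """The three validation confusion matrices, keyed by design id."""
    return {
        "1": ConfusionFixture(
            design="1",
            labels=("MFDM", "Control"),
            matrix=np.array([[10, 0], [1, 21]]),
        ),
        "2.1": ConfusionFixture(
            design="2.1",
            labels=("MFDM", "Control", "CHARGE", "TC"),
            matrix=np.array(
                [
                    [4, 0, 1, 0],
                    [0, 21, 2, 0],
                    [1, 0, 4, 1],
                    [2, 0, 0, 1],
                ]
            ),
        ),
        "2.2": ConfusionFixture(
            design="2.2",
            labels=("MFDM", "CHARGE", "TC"),
            matrix=np.array(
                [
                    [7, 0, 1],
                    [0, 6, 1],
                    [0, 1, 0],
                ]
            ),
        ),
    }
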