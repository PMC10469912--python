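"""Fluctuating-asymmetry index for bilateral grade 0–I ears.

The raw index of a left/right ear pair is the full Procrustes distance
between the mirrored left configuration and the right configuration —
translation, scale and rotation are removed, so what remains is the shape
difference between the two sides. Within a training cohort the raw values
are normalized to [0, 1] by the cohort maximum; that constant is frozen and
re-applied (with clipping) to new data.
"""

from __future__ import annotations

import numpy as np

from .procrustes import align_pair, reflect_to_reference_side
from .types import EarLandmarks


def fluctuating_asymmetry_index(left: EarLandmarks, right: EarLandmarks) -> float:
    """Raw FA: Procrustes distance between mirrored left and right ears."""
    if left.side != "left" or right.side != "right":
        raise ValueError("expected a (left, right) ear pair")
    mirrored = reflect_to_reference_side(left)
    return align_pair(right.points, mirrored.points)[1]


def normalize_fa(
    raw: np.ndarray, training_max: float | None = None
) -> tuple[np.ndarray, float]:
    """Normalize raw FA values to [0, 1].

    With ``training_max=None`` the divisor is the maximum of *raw* (training
    behaviour; the maximum maps to 1). Passing a frozen ``training_max``
    applies it to new data, clipping to [0, 1].
    """
    values = np.asarray(raw, dtype=float)
    if values.size == 0:
        raise ValueError("no FA values to normalize")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("raw FA values must be finite and non-negative")
    divisor = float(np.max(values)) if training_max is None else float(training_max)
    if divisor <= 0:
        # perfectly symmetric cohort: everything maps to 0
        return np.zeros_like(values), 0.0
    return np.clip(values / divisor, 0.0, 1.0), divisor
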