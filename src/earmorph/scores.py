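"""Marx-grade severity and the 0–3 mixed asymmetry scale.

Per patient, severity is the sum of the two ears' microtia grades (0–8).
Asymmetry uses a mixed scale: when at least one ear is grade II or worse it
is the absolute grade difference |left - right| (0–3 in practice); when both
ears are grade 0–I it is the normalized fluctuating-asymmetry index in
[0, 1], computed from landmarks. Grades 0 and I are pooled for this rule,
mirroring how grade distributions are reported clinically.

Patients with one ear of grade >= 2 and no information on the contralateral
ear get missing scores and are excluded from score-using analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .types import ValidationError


@dataclass
class PatientScores:
    patient_id: str
    severity: int  # 0..8, left grade + right grade
    asymmetry: float  # [0, 3]; FA index in [0, 1] when both grades <= 1


def _check_grade(grade: int, name: str) -> int:
    grade = int(grade)
    if not 0 <= grade <= 4:
        raise ValidationError(f"{name} grade {grade} outside 0..4")
    return grade


def severity_score(left_grade: int, right_grade: int) -> int:
    """Sum of the two ears' microtia grades."""
    return _check_grade(left_grade, "left") + _check_grade(right_grade, "right")


def asymmetry_score(
    left_grade: int, right_grade: int, fa_index: float | None = None
) -> float:
    """Mixed 0–3 asymmetry scale.

    |left - right| when the worse ear is grade >= II; otherwise the
    patient's normalized FA index (required, in [0, 1]).
    """
    lg = _check_grade(left_grade, "left")
    rg = _check_grade(right_grade, "right")
    if max(lg, rg) >= 2:
        return float(abs(lg - rg))
    if fa_index is None:
        raise ValidationError("fa_index required when both grades are <= 1")
    if not 0.0 <= fa_index <= 1.0:
        raise ValidationError(f"fa_index {fa_index} outside [0, 1]")
    return float(fa_index)


@dataclass
class GroupComparison:
    """Coefficient table of score ~ group contrasts against a reference group."""

    table: pd.DataFrame  # index: group; columns estimate, se, t, p
    reference_group: str
    degenerate: bool  # all scores identical (zero variance)
    mixed: bool  # patient random intercept engaged (repeated rows)


def compare_scores_between_groups(
    scores,
    groups,
    patient_ids=None,
    reference_group: str = "MFDM",
) -> GroupComparison:
    """Compare a score between groups with the reference group as baseline.

    Fits score ~ group indicators; when repeated rows per patient are
    present (and patient ids are given) a patient-level random intercept is
    added. Coefficients are tested against 0 by two-sided t tests. Groups
    with fewer than 2 patients are excluded with a warning.
    """
    frame = pd.DataFrame({"score": np.asarray(scores, dtype=float), "group": list(groups)})
    frame["patient"] = (
        list(patient_ids) if patient_ids is not None else [f"p{i}" for i in range(len(frame))]
    )
    if reference_group not in set(frame["group"]):
        raise ValidationError(f"reference group {reference_group!r} absent from data")

    sizes = frame.groupby("group")["patient"].nunique()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 patients: {small}", stacklevel=2)
        frame = frame[~frame["group"].isin(small)]
    if frame["group"].nunique() < 2:
        raise ValidationError("need at least 2 groups with >= 2 patients")

    degenerate = bool(np.allclose(frame["score"], frame["score"].iloc[0]))
    repeated = bool(frame["patient"].duplicated().any())
    formula = f"score ~ C(group, Treatment(reference={reference_group!r}))"
    if degenerate:
        # zero variance: coefficients are exactly 0 with no testable error
        others = [g for g in sorted(frame["group"].unique()) if g != reference_group]
        table = pd.DataFrame(
            {"estimate": 0.0, "se": np.nan, "t": np.nan, "p": np.nan}, index=others
        )
        return GroupComparison(table, reference_group, degenerate=True, mixed=False)

    if repeated:
        model = smf.mixedlm(formula, frame, groups=frame["patient"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        params, bse, tvals, pvals = fit.params, fit.bse, fit.tvalues, fit.pvalues
    else:
        fit = smf.ols(formula, frame).fit()
        params, bse, tvals, pvals = fit.params, fit.bse, fit.tvalues, fit.pvalues

    rows = {}
    prefix = f"C(group, Treatment(reference={reference_group!r}))[T."
    for name in params.index:
        if name.startswith(prefix):
            group = name[len(prefix):-1]
            rows[group] = {
                "estimate": float(params[name]),
                "se": float(bse[name]),
                "t": float(tvals[name]),
                "p": float(pvals[name]),
            }
    table = pd.DataFrame(rows).T[["estimate", "se", "t", "p"]].sort_index()
    return GroupComparison(table, reference_group, degenerate=False, mixed=repeated)
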