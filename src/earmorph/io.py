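"""Cohort-table and landmark-file input/output.

Two landmark encodings are supported and are interchangeable:

* a JSON dialect ``{"version": 1, "side": "right", "points": [[x, y], ...]}``
  (modelled on web annotation-tool exports), and
* a plain delimited fallback of 41 ``x<TAB>y`` lines.

The cohort table is a CSV with header
``patient_id,photo_id,side,age,gender,group,genotype_class,marx_grade,landmark_file``;
``landmark_file`` is a path relative to the table (empty for grade II–IV
ears, which cannot be annotated). Rows violating a record invariant are
rejected with row-addressed messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .template import EarTemplate, default_template
from .types import Cohort, EarLandmarks, EarRecord, FormatError, ValidationError

COHORT_COLUMNS = [
    "patient_id",
    "photo_id",
    "side",
    "age",
    "gender",
    "group",
    "genotype_class",
    "marx_grade",
    "landmark_file",
]

LANDMARK_JSON_VERSION = 1


def read_landmarks(
    path: str | Path,
    template: EarTemplate | None = None,
    side: str | None = None,
) -> EarLandmarks:
    """Read one ear's landmarks from JSON or delimited text.

    The format is chosen by suffix (``.json`` vs anything else). ``side``
    overrides any side stored in the file; the delimited fallback stores no
    side, so ``side`` defaults to ``"right"`` there.
    """
    path = Path(path)
    template = template or default_template()
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        if "points" not in payload:
            raise FormatError(f"{path}: missing 'points' key")
        pts = np.asarray(payload["points"], dtype=float)
        file_side = payload.get("side")
    else:
        try:
            pts = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse delimited landmarks ({exc})") from exc
        file_side = None
    if pts.ndim != 2 or pts.shape != (template.n_points, 2):
        raise FormatError(
            f"{path}: expected {template.n_points} points x 2 coordinates, got {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise FormatError(f"{path}: non-finite coordinate")
    return EarLandmarks(points=pts, side=side or file_side or "right", template=template)


def write_landmarks(landmarks: EarLandmarks, path: str | Path) -> None:
    """Write landmarks as JSON (``.json`` suffix) or tab-delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "version": LANDMARK_JSON_VERSION,
            "side": landmarks.side,
            "points": [[float(x), float(y)] for x, y in landmarks.points],
        }
        path.write_text(json.dumps(payload, indent=None, separators=(",", ":")) + "\n")
    else:
        lines = [f"{x:.12g}\t{y:.12g}" for x, y in landmarks.points]
        path.write_text("\n".join(lines) + "\n")


def read_cohort_table(
    path: str | Path,
    role: str = "training",
    template: EarTemplate | None = None,
) -> Cohort:
    """Read and validate a cohort CSV, loading any referenced landmark files.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` (with the offending row number) for rows that
    violate a record invariant.
    """
    path = Path(path)
    template = template or default_template()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    records: list[EarRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        lm_file = row.landmark_file.strip()
        try:
            grade = int(row.marx_grade)
        except ValueError as exc:
            raise ValidationError(f"{path} row {i}: marx_grade {row.marx_grade!r}") from exc
        if grade >= 2 and lm_file:
            raise ValidationError(
                f"{path} row {i}: grade {grade} ear references landmark file {lm_file!r}"
            )
        landmarks = None
        if lm_file:
            landmarks = read_landmarks(path.parent / lm_file, template, side=row.side)
        try:
            records.append(
                EarRecord(
                    patient_id=row.patient_id,
                    photo_id=row.photo_id,
                    side=row.side,
                    age=float(row.age),
                    gender=row.gender,
                    group=row.group,
                    genotype_class=row.genotype_class or "none",
                    marx_grade=grade,
                    landmarks=landmarks,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return Cohort(records=records, role=role)


def write_cohort_table(cohort: Cohort, path: str | Path, landmark_dir: str = "landmarks") -> None:
    """Write a cohort as CSV plus one JSON landmark file per annotated ear.

    Landmark files go in ``landmark_dir`` next to the CSV and are referenced
    relatively, so the pair round-trips through :func:`read_cohort_table`.
    """
    path = Path(path)
    lmdir = path.parent / landmark_dir
    rows = []
    for rec in cohort.records:
        lm_file = ""
        if rec.landmarks is not None:
            lmdir.mkdir(parents=True, exist_ok=True)
            lm_file = f"{landmark_dir}/{rec.photo_id}.json"
            write_landmarks(rec.landmarks, path.parent / lm_file)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "photo_id": rec.photo_id,
                "side": rec.side,
                "age": f"{rec.age:.6g}",
                "gender": rec.gender,
                "group": rec.group,
                "genotype_class": rec.genotype_class,
                "marx_grade": rec.marx_grade,
                "landmark_file": lm_file,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
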