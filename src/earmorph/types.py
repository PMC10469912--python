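"""Domain types: landmark sets, ear records and cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .template import EarTemplate, default_template

SIDES = ("left", "right")
GENDERS = ("female", "male")
GROUPS = ("control", "MFDM", "NAFD", "TC", "CHARGE")
GENOTYPE_CLASSES = ("none", "splice", "frameshift", "nonsense", "deletion")


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class FormatError(ValueError):
    """A file cannot be parsed as the expected format."""


class GeometryError(ValueError):
    """A landmark configuration is degenerate for the requested operation."""


@dataclass
class EarLandmarks:
    """One ear's 41 named 2D points (image pixels, y downward).

    ``points`` has shape (41, 2); ``side`` records which ear was
    photographed. Coordinates must be finite and not all identical
    (the centroid size must be positive).
    """

    points: np.ndarray
    side: str
    template: EarTemplate = field(default_factory=default_template)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (self.template.n_points, 2):
            raise ValidationError(
                f"expected {self.template.n_points}x2 coordinates, got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if np.allclose(self.points, self.points[0]):
            raise ValidationError("degenerate landmark set: all points identical")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        return float(np.linalg.norm(self.points - self.centroid))


@dataclass
class EarRecord:
    """One photographed ear with its clinical covariates.

    Invariants: landmarks are present if and only if the Marx grade is at
    most I (grades II–IV lack the structures needed for annotation), and a
    genotype class other than ``none`` is only allowed in the MFDM group.
    """

    patient_id: str
    photo_id: str
    side: str
    age: float
    gender: str
    group: str
    genotype_class: str = "none"
    marx_grade: int = 0
    landmarks: EarLandmarks | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"{self.photo_id}: invalid side {self.side!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"{self.photo_id}: invalid gender {self.gender!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"{self.photo_id}: invalid group {self.group!r}")
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValidationError(
                f"{self.photo_id}: invalid genotype_class {self.genotype_class!r}"
            )
        if not np.isfinite(self.age) or self.age < 0:
            raise ValidationError(f"{self.photo_id}: age must be >= 0")
        if not (0 <= int(self.marx_grade) <= 4):
            raise ValidationError(f"{self.photo_id}: marx_grade must be in 0..4")
        self.marx_grade = int(self.marx_grade)
        if self.genotype_class != "none" and self.group != "MFDM":
            raise ValidationError(
                f"{self.photo_id}: genotype_class {self.genotype_class!r} outside MFDM"
            )
        if self.marx_grade >= 2 and self.landmarks is not None:
            raise ValidationError(
                f"{self.photo_id}: grade {self.marx_grade} ears cannot carry landmarks"
            )

    @property
    def annotatable(self) -> bool:
        """Grades 0–I can be landmarked; II–IV cannot."""
        return self.marx_grade <= 1


@dataclass
class Cohort:
    """A set of ear records with a role (training or validation).

    Photo ids are unique; a validation cohort holds at most one photograph
    per (patient, side).
    """

    records: list[EarRecord]
    role: str = "training"

    def __post_init__(self) -> None:
        if self.role not in ("training", "validation"):
            raise ValidationError(f"invalid cohort role {self.role!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.photo_id in seen:
                raise ValidationError(f"duplicate photo_id {rec.photo_id!r}")
            seen.add(rec.photo_id)
        if self.role == "validation":
            pairs: set[tuple[str, str]] = set()
            for rec in self.records:
                key = (rec.patient_id, rec.side)
                if key in pairs:
                    raise ValidationError(
                        f"validation cohort has repeated photographs for {key}"
                    )
                pairs.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patients(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.patient_id not in out:
                out.append(rec.patient_id)
        return out

    def with_landmarks(self) -> list[EarRecord]:
        return [r for r in self.records if r.landmarks is not None]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the cohort (one row per photographed ear)."""
        rows = [
            {
                "patient_id": r.patient_id,
                "photo_id": r.photo_id,
                "side": r.side,
                "age": r.age,
                "gender": r.gender,
                "group": r.group,
                "genotype_class": r.genotype_class,
                "marx_grade": r.marx_grade,
                "has_landmarks": r.landmarks is not None,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)
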