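"""Synthetic landmark-cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without clinical photographs:

* a stylized 41-point "mean ear" polyline (hand-placed on elliptical arcs;
  only relative deformations matter downstream, since superimposition
  removes position, scale and orientation);
* fixed group-specific displacement fields scaled by one effect parameter —
  MFDM: concha rotation + vertical concha shift + enlarged lobe + thickened
  helix; CHARGE: triangular concha + reduced lobe + thinner helix; TC and
  NAFD get their own distinct fields;
* covariate effects: a fixed age slope and a gender offset on designated
  deformation axes, plus a per-individual random age slope;
* directional asymmetry (a systematic left/right field) and fluctuating
  asymmetry (a per-ear random field, stable across that ear's photographs),
  plus per-photograph landmark measurement noise and an arbitrary similarity
  jitter standing in for uncalibrated camera framing;
* per-group gender, age, Marx-grade and (for MFDM) genotype-class
  distributions matching the clinical training population; grade II–IV ears
  carry no landmarks;
* repeated photographs per patient at strictly increasing ages (training
  role), or exactly one photograph per ear (validation role).

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .template import EarTemplate, default_template
from .types import Cohort, EarLandmarks, EarRecord, GROUPS, ValidationError

# patients per group in the emulated training population
DEFAULT_GROUP_SIZES = {"control": 471, "MFDM": 31, "NAFD": 9, "TC": 15, "CHARGE": 24}
# patients per group in the emulated validation population
DEFAULT_VALIDATION_SIZES = {"control": 21, "MFDM": 11, "NAFD": 2, "TC": 6, "CHARGE": 8}
DEFAULT_FEMALE_PROB = {"control": 0.53, "MFDM": 0.52, "NAFD": 0.56, "TC": 0.40, "CHARGE": 0.42}
# per-ear Marx grade distributions; the pooled grade 0-1 mass is split 70/30
DEFAULT_GRADE_PROBS = {
    "control": {0: 0.70, 1: 0.30},
    "MFDM": {0: 0.62, 1: 0.30, 2: 0.03, 3: 0.05},
    "NAFD": {0: 0.70, 1: 0.30},
    "TC": {0: 0.50, 1: 0.30, 2: 0.17, 3: 0.03},
    "CHARGE": {0: 0.70, 1: 0.30},
}
DEFAULT_GENOTYPE_PROBS = {
    "splice": 11 / 31,
    "frameshift": 9 / 31,
    "nonsense": 7 / 31,
    "deletion": 4 / 31,
}
# per-group fluctuating-asymmetry SD (px); syndromic ears are more asymmetric
DEFAULT_FA_SD = {"control": 0.5, "MFDM": 1.5, "NAFD": 1.1, "TC": 1.1, "CHARGE": 0.8}

AGE_MEAN = 7.2  # years
AGE_SD = 5.9
AGE_MAX = 60.7


def _arc(center, a, b, start_deg, stop_deg, n) -> np.ndarray:
    """n points on an elliptical arc (y grows downward)."""
    phi = np.deg2rad(np.linspace(start_deg, stop_deg, n))
    return np.column_stack([center[0] + a * np.cos(phi), center[1] + b * np.sin(phi)])


def base_ear_shape(template: EarTemplate | None = None) -> np.ndarray:
    """Stylized right-ear mean polyline, in pixels (y downward), 41 x 2."""
    template = template or default_template()
    parts = {
        "outer_helix": _arc((100, 95), 34, 56, 170, 450, 12),
        "inner_helix": _arc((100, 95), 23, 42, 190, 430, 8),
        "concha": _arc((96, 106), 14, 16, 120, 420, 6),
        "lobe": _arc((96, 156), 15, 12, 0, 180, 5),
        "tragus": np.array([[72.0, 98.0], [77.0, 107.0], [74.0, 116.0]]),
        "antitragus": np.array([[86.0, 135.0], [94.0, 139.0], [103.0, 134.0]]),
        "crus_helicis": np.array([[79.0, 90.0], [87.0, 95.0], [93.0, 101.0]]),
    }
    pts = np.zeros((template.n_points, 2))
    for name, run in template.segments.items():
        pts[list(run)] = parts[name]
    pts[template.point_names.index("incisura_intertragica")] = [79.0, 123.0]
    return pts


def _unit_field(displaced: np.ndarray, base: np.ndarray) -> np.ndarray:
    field = displaced - base
    norm = np.linalg.norm(field)
    if norm < 1e-12:
        raise ValueError("degenerate deformation field")
    return field / norm


def _rotate_about(points: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def _scale_about(points: np.ndarray, center: np.ndarray, factor: float) -> np.ndarray:
    return center + factor * (points - center)


def deformation_fields(template: EarTemplate | None = None) -> dict[str, np.ndarray]:
    """Unit-norm 41 x 2 displacement fields for groups, covariates and asymmetry."""
    template = template or default_template()
    base = base_ear_shape(template)
    seg = template.segments
    concha = list(seg["concha"])
    lobe = list(seg["lobe"])
    outer = list(seg["outer_helix"])
    inner = list(seg["inner_helix"])
    tragus = list(seg["tragus"])
    antitragus = list(seg["antitragus"])
    ear_center = base.mean(axis=0)

    fields: dict[str, np.ndarray] = {}

    # MFDM: clockwise concha rotation + vertical concha shift + enlarged lobe
    # + thickened (outward) helix
    d = base.copy()
    cc = base[concha].mean(axis=0)
    d[concha] = _rotate_about(d[concha], cc, 0.35) + [0.0, 6.0]
    lc = base[lobe].mean(axis=0)
    d[lobe] = _scale_about(d[lobe], lc, 1.45)
    out_dir = base[outer] - ear_center
    d[outer] = d[outer] + 2.0 * out_dir / np.linalg.norm(out_dir, axis=1, keepdims=True)
    fields["MFDM"] = _unit_field(d, base)

    # CHARGE: triangular concha, reduced lobe, thinner helix
    d = base.copy()
    tri = cc + np.array([[0.0, -16.0], [14.0, 11.0], [-14.0, 11.0]])
    perimeter = np.vstack([tri, tri[:1]])
    frac = np.linspace(0.0, 1.0, len(concha), endpoint=False)
    seg_len = np.linalg.norm(np.diff(perimeter, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)]) / seg_len.sum()
    tri_pts = np.empty((len(concha), 2))
    for i, f in enumerate(frac):
        j = int(np.searchsorted(cum, f, side="right") - 1)
        t = (f - cum[j]) / (cum[j + 1] - cum[j])
        tri_pts[i] = (1 - t) * perimeter[j] + t * perimeter[j + 1]
    d[concha] = 0.5 * d[concha] + 0.5 * tri_pts
    d[lobe] = _scale_about(d[lobe], lc, 0.65)
    d[outer] = d[outer] - 1.5 * out_dir / np.linalg.norm(out_dir, axis=1, keepdims=True)
    fields["CHARGE"] = _unit_field(d, base)

    # TC: strongly reduced lobe, vertically stretched ear, displaced tragus
    d = base.copy()
    d[lobe] = _scale_about(d[lobe], lc, 0.55)
    d[:, 1] = ear_center[1] + 1.12 * (d[:, 1] - ear_center[1])
    d[tragus] = d[tragus] + [3.0, -2.0]
    fields["TC"] = _unit_field(d, base)

    # NAFD: expanded upper helix, lowered inner helix, prominent antitragus
    d = base.copy()
    upper = [i for i in outer if base[i, 1] < ear_center[1]]
    up_dir = base[upper] - ear_center
    d[upper] = d[upper] + 4.0 * up_dir / np.linalg.norm(up_dir, axis=1, keepdims=True)
    d[inner] = d[inner] + [0.0, 3.0]
    d[antitragus] = _scale_about(d[antitragus], ear_center, 1.12)
    fields["NAFD"] = _unit_field(d, base)

    fields["control"] = np.zeros_like(base)

    # age: lobe elongation with growth (shape change, not global size)
    d = base.copy()
    d[lobe] = _scale_about(d[lobe], lc, 1.3) + [0.0, 2.0]
    fields["age"] = _unit_field(d, base)

    # gender: slightly wider concha and helix roll in males
    d = base.copy()
    d[concha] = _scale_about(d[concha], cc, 1.15)
    d[outer] = d[outer] + [1.0, 0.0]
    fields["gender"] = _unit_field(d, base)

    # directional asymmetry: small whole-ear shear/rotation
    d = _rotate_about(base, ear_center, 0.03)
    d[tragus] = d[tragus] + [1.0, 1.0]
    fields["directional"] = _unit_field(d, base)
    return fields


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    group_sizes: dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    size_scale: float = 1.0  # multiplies group_sizes (rounded, min 1 where nonzero)
    photos_per_patient: tuple[int, int] = (1, 5)  # uniform inclusive range
    female_prob: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_FEMALE_PROB))
    grade_probs: dict[str, dict[int, float]] = dc_field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_GRADE_PROBS.items()}
    )
    genotype_probs: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROBS)
    )
    effect_scale: float = 18.0  # px, norm of the group displacement field
    beta_age: float = 0.35  # px/year on the age field
    beta_gender: float = 2.0  # px offset on the gender field (male)
    random_slope_sd: float = 0.12  # px/year, per-individual age slope
    directional_asymmetry: float = 1.5  # px, +right / -left on the directional field
    fa_sd: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_FA_SD))
    measurement_sd: float = 0.7  # px per coordinate per photograph
    jitter_rotation: float = 0.25  # rad, uniform +/- camera-orientation jitter
    jitter_log_scale: float = 0.2  # uniform +/- log scale jitter
    jitter_translation: float = 30.0  # px uniform +/- framing jitter
    paired_sides: bool = True  # photographs come in left/right pairs per visit
    left_prob: float = 0.5  # probability an unpaired photograph shows the left ear
    age_increment_mean: float = 1.2  # years between successive photographs
    role: str = "training"
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS or n < 0:
                raise ValidationError(f"invalid group size {g}={n}")
        for g, p in self.female_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"female_prob[{g}]={p} outside [0,1]")
        for g, dist in self.grade_probs.items():
            if any(not 0.0 <= p <= 1.0 for p in dist.values()) or abs(
                sum(dist.values()) - 1.0
            ) > 1e-9:
                raise ValidationError(f"grade_probs[{g}] must be a distribution over 0..4")
            if any(k not in (0, 1, 2, 3, 4) for k in dist):
                raise ValidationError(f"grade_probs[{g}] has grades outside 0..4")
        if abs(sum(self.genotype_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("genotype_probs must sum to 1")
        for name in ("random_slope_sd", "measurement_sd", "effect_scale",
                     "directional_asymmetry", "size_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.fa_sd.values()):
            raise ValidationError("fa_sd values must be >= 0")
        lo, hi = self.photos_per_patient
        if not (1 <= lo <= hi):
            raise ValidationError("photos_per_patient must be an increasing range from >= 1")
        if not 0.0 <= self.left_prob <= 1.0:
            raise ValidationError("left_prob outside [0,1]")
        if self.role not in ("training", "validation"):
            raise ValidationError(f"invalid role {self.role!r}")


def _draw_age(rng: np.random.Generator) -> float:
    """Truncated log-normal baseline age matched to mean 7.2, SD 5.9 years."""
    sigma2 = np.log(1.0 + (AGE_SD / AGE_MEAN) ** 2)
    mu = np.log(AGE_MEAN) - sigma2 / 2.0
    while True:
        age = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if age <= AGE_MAX:
            return age


def _draw_from(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort of ear records with landmark sets.

    Training role: each patient contributes 1–5 photographs at strictly
    increasing ages, each showing one (random) side. Validation role: each
    patient contributes exactly one photograph per side, both at the same
    age. Grade II–IV ears carry no landmarks. Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    template = default_template()
    base = base_ear_shape(template)
    fields = deformation_fields(template)
    records: list[EarRecord] = []
    prefix = "t" if config.role == "training" else "v"

    for group in GROUPS:
        n_raw = config.group_sizes.get(group, 0)
        n_patients = int(round(n_raw * config.size_scale)) if n_raw else 0
        if n_raw > 0 and n_patients == 0:
            n_patients = 1
        for i in range(n_patients):
            pid = f"{prefix}_{group}_{i:04d}"
            female = rng.random() < config.female_prob[group]
            gender = "female" if female else "male"
            genotype = (
                str(_draw_from(rng, config.genotype_probs)) if group == "MFDM" else "none"
            )
            grades = {
                side: int(_draw_from(rng, config.grade_probs[group]))
                for side in ("left", "right")
            }
            b_i = rng.normal(0.0, config.random_slope_sd) if config.random_slope_sd else 0.0
            fa_field = {
                side: rng.normal(0.0, config.fa_sd[group], size=base.shape)
                if config.fa_sd[group]
                else np.zeros_like(base)
                for side in ("left", "right")
            }
            base_age = _draw_age(rng)

            if config.role == "training":
                lo, hi = config.photos_per_patient
                n_photos = int(rng.integers(lo, hi + 1))
                if config.paired_sides:
                    # both profiles are photographed at each visit; an odd
                    # count leaves one single-sided visit
                    n_sessions = (n_photos + 1) // 2
                    session_ages = base_age + np.concatenate(
                        [[0.0],
                         np.cumsum(rng.exponential(config.age_increment_mean,
                                                   n_sessions - 1))]
                    )
                    photos = []
                    for s_idx in range(n_sessions):
                        first_left = rng.random() < config.left_prob
                        order = ("left", "right") if first_left else ("right", "left")
                        for side in order:
                            if len(photos) < n_photos:
                                photos.append((session_ages[s_idx], side))
                else:
                    ages = np.sort(
                        base_age
                        + np.concatenate(
                            [[0.0],
                             np.cumsum(rng.exponential(config.age_increment_mean,
                                                       n_photos - 1))]
                        )
                    )
                    sides = [
                        "left" if rng.random() < config.left_prob else "right"
                        for _ in range(n_photos)
                    ]
                    photos = list(zip(ages, sides))
            else:
                photos = [(base_age, "left"), (base_age, "right")]

            for j, (age, side) in enumerate(photos):
                grade = grades[side]
                landmarks = None
                if grade <= 1:
                    shape = (
                        base
                        + config.effect_scale * fields[group]
                        + (config.beta_age + b_i) * age * fields["age"]
                        + config.beta_gender * (0.0 if female else 1.0) * fields["gender"]
                        + (1.0 if side == "right" else -1.0)
                        * config.directional_asymmetry
                        * fields["directional"]
                        + fa_field[side]
                    )
                    if config.measurement_sd:
                        shape = shape + rng.normal(0.0, config.measurement_sd, size=shape.shape)
                    center = shape.mean(axis=0)
                    if config.jitter_rotation:
                        shape = _rotate_about(
                            shape, center, rng.uniform(-config.jitter_rotation,
                                                       config.jitter_rotation)
                        )
                    if config.jitter_log_scale:
                        shape = _scale_about(
                            shape, center,
                            float(np.exp(rng.uniform(-config.jitter_log_scale,
                                                     config.jitter_log_scale))),
                        )
                    if config.jitter_translation:
                        shape = shape + rng.uniform(
                            -config.jitter_translation, config.jitter_translation, size=2
                        )
                    if side == "left":  # mirror about the ear's vertical axis
                        shape = shape.copy()
                        shape[:, 0] = 2.0 * shape[:, 0].mean() - shape[:, 0]
                    landmarks = EarLandmarks(points=shape, side=side, template=template)
                records.append(
                    EarRecord(
                        patient_id=pid,
                        photo_id=f"{pid}_ph{j:02d}_{side[0]}",
                        side=side,
                        age=float(age),
                        gender=gender,
                        group=group,
                        genotype_class=genotype,
                        marx_grade=grade,
                        landmarks=landmarks,
                    )
                )
    return Cohort(records=records, role=config.role)
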