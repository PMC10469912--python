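"""End-to-end orchestration: simulate -> superimpose -> adjust -> score ->
train -> evaluate -> embed.

Each stage is a plain function over in-memory objects so tests and analysis
scripts can drive any slice of the pipeline; :func:`run_pipeline` wires them
together from a single config, writes serialized intermediates to a run
directory, and logs row counts in and out of every stage. Re-running with an
identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .asymmetry import fluctuating_asymmetry_index, normalize_fa
from .classify import (
    ClassifierBundle,
    DesignSpec,
    assemble_features,
    predict_label,
    predict_proba,
    train_classifier,
)
from .metrics import EvaluationReport, confusion_and_metrics, roc_auc_one_vs_all
from .mixedmodel import PCMixedFit, ResidualSet, fit_all_components, residualize_all
from .procrustes import reflect_to_reference_side
from .scores import PatientScores, asymmetry_score, severity_score
from .semilandmarks import slide_semilandmarks, bending_energy_matrix, _slide_one
from .shapespace import ShapeSpace, align_to_consensus, shape_pca
from .simulate import DEFAULT_VALIDATION_SIZES, SimulationConfig, simulate_cohort
from .template import default_template
from .types import Cohort, EarRecord, ValidationError

logger = logging.getLogger(__name__)


def _json_default(obj):
    """Serialize numpy scalars/arrays transparently."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# morphometrics stage

@dataclass
class MorphometricState:
    """Everything frozen by the training superimposition."""

    records: list[EarRecord]  # training records with landmarks, row-aligned
    aligned: np.ndarray  # (n, p, 2)
    consensus: np.ndarray
    shapespace: ShapeSpace
    slide_mode: str | None  # None = sliding disabled


def process_landmarks(
    cohort: Cohort,
    mode: str = "bending_energy",
    variance_target: float = 0.90,
    slide: bool = True,
) -> MorphometricState:
    """Reflect, superimpose (with optional semilandmark sliding) and run PCA."""
    records = cohort.with_landmarks()
    if len(records) < 3:
        raise ValidationError("need at least 3 annotated ears")
    template = default_template()
    configs = np.stack(
        [reflect_to_reference_side(r.landmarks).points for r in records]
    )
    if slide:
        result = slide_semilandmarks(configs, template, mode=mode)
        aligned_set = result.aligned
        slide_mode = mode
    else:
        from .procrustes import gpa

        aligned_set = gpa(configs)
        slide_mode = None
    space = shape_pca(aligned_set, variance_target=variance_target)
    logger.info(
        "landmarks-process: %d ears in, %d aligned, k=%d components retained",
        len(cohort), aligned_set.n, space.k,
    )
    return MorphometricState(
        records=records,
        aligned=aligned_set.aligned,
        consensus=aligned_set.consensus,
        shapespace=space,
        slide_mode=slide_mode,
    )


def project_validation(
    state: MorphometricState, cohort: Cohort
) -> tuple[list[EarRecord], np.ndarray]:
    """Carry validation ears into the frozen training shape space.

    Each validation configuration is reflected to the reference side,
    superimposed on the training consensus, slid once against the frozen
    consensus (when sliding was enabled in training), re-superimposed, and
    projected onto the retained components.
    """
    records = cohort.with_landmarks()
    if not records:
        raise ValidationError("validation cohort has no annotated ears")
    template = default_template()
    configs = np.stack(
        [reflect_to_reference_side(r.landmarks).points for r in records]
    )
    aligned = align_to_consensus(state.consensus, configs)
    if state.slide_mode is not None:
        be = (
            bending_energy_matrix(state.consensus)
            if state.slide_mode == "bending_energy"
            else None
        )
        slid = np.stack(
            [_slide_one(cfg, state.consensus, template, be) for cfg in aligned]
        )
        aligned = align_to_consensus(state.consensus, slid)
    scores = state.shapespace.transform(aligned)
    return records, scores


# ---------------------------------------------------------------------------
# covariate-adjust stage

def fit_component_models(
    state: MorphometricState, random_intercept: bool = False
) -> list[PCMixedFit]:
    recs = state.records
    return fit_all_components(
        state.shapespace.scores,
        [r.age for r in recs],
        [r.gender for r in recs],
        [r.patient_id for r in recs],
        random_intercept=random_intercept,
    )


def residuals_for(
    fits: list[PCMixedFit],
    score_matrix: np.ndarray,
    records: list[EarRecord],
    mode: str,
) -> ResidualSet:
    return residualize_all(
        fits,
        score_matrix,
        [r.age for r in records],
        [r.gender for r in records],
        [r.patient_id for r in records],
        mode=mode,
        photo_ids=[r.photo_id for r in records],
    )


# ---------------------------------------------------------------------------
# scoring stage

def _patient_side_info(cohort: Cohort) -> dict[str, dict[str, list[EarRecord]]]:
    out: dict[str, dict[str, list[EarRecord]]] = {}
    for rec in cohort.records:
        out.setdefault(rec.patient_id, {"left": [], "right": []})[rec.side].append(rec)
    return out


def compute_patient_scores(
    cohort: Cohort, fa_max: float | None = None
) -> tuple[dict[str, PatientScores], float]:
    """Severity and asymmetry per patient; returns (scores, frozen FA maximum).

    Patients lacking information on one side (no photographs of it) get no
    scores. For bilateral grade 0–I patients the FA index needs an annotated
    left/right pair (the closest in age); the raw index is normalized by the
    cohort maximum (training) or by a frozen ``fa_max`` (validation), with
    clipping to [0, 1].
    """
    sides = _patient_side_info(cohort)
    grades: dict[str, tuple[int, int]] = {}
    raw_fa: dict[str, float] = {}
    for pid, by_side in sides.items():
        if not by_side["left"] or not by_side["right"]:
            continue  # no contralateral information
        lg = by_side["left"][0].marx_grade
        rg = by_side["right"][0].marx_grade
        grades[pid] = (lg, rg)
        if max(lg, rg) <= 1:
            lefts = [r for r in by_side["left"] if r.landmarks is not None]
            rights = [r for r in by_side["right"] if r.landmarks is not None]
            if not lefts or not rights:
                del grades[pid]
                continue
            pair = min(
                ((l, r) for l in lefts for r in rights),
                key=lambda lr: abs(lr[0].age - lr[1].age),
            )
            raw_fa[pid] = fluctuating_asymmetry_index(
                pair[0].landmarks, pair[1].landmarks
            )
    if raw_fa:
        normed, divisor = normalize_fa(
            np.array(list(raw_fa.values())), training_max=fa_max
        )
        fa_index = dict(zip(raw_fa.keys(), normed))
    else:
        fa_index, divisor = {}, (fa_max if fa_max is not None else 0.0)

    scores: dict[str, PatientScores] = {}
    for pid, (lg, rg) in grades.items():
        if max(lg, rg) <= 1:
            asym = asymmetry_score(lg, rg, fa_index[pid])
        else:
            asym = asymmetry_score(lg, rg)
        scores[pid] = PatientScores(
            patient_id=pid, severity=severity_score(lg, rg), asymmetry=asym
        )
    logger.info(
        "score: %d patients in, %d with scores (%d FA-based)",
        len(sides), len(scores), len(raw_fa),
    )
    return scores, float(divisor)


def select_validation_ears(
    cohort: Cohort, rng: np.random.Generator
) -> list[EarRecord]:
    """One randomly selected annotatable ear per validation patient.

    Scores are computed from both ears beforehand; classification then uses
    a single side per patient, drawn at random among the sides that carry
    landmarks.
    """
    chosen: list[EarRecord] = []
    for pid in cohort.patients:
        candidates = [
            r for r in cohort.records if r.patient_id == pid and r.landmarks is not None
        ]
        if candidates:
            chosen.append(candidates[int(rng.integers(len(candidates)))])
    return chosen


# ---------------------------------------------------------------------------
# train / evaluate stage

def evaluate_bundle(
    bundle: ClassifierBundle,
    features: pd.DataFrame,
    references: list[str],
) -> EvaluationReport:
    """Predict and compute the full metric report, including one-vs-all AUC.

    Validation rows whose reference class is unknown to the model (e.g. a
    class whose training rows all lost required features) cannot be scored
    and are dropped with a logged count.
    """
    known = [ref in bundle.classes for ref in references]
    if not all(known):
        dropped = len(known) - sum(known)
        logger.info(
            "evaluation: dropped %d rows with reference classes unknown to the model",
            dropped,
        )
        features = features.loc[known].reset_index(drop=True)
        references = [r for r, keep in zip(references, known) if keep]
    if not references:
        raise ValidationError("no evaluable validation rows")
    preds = predict_label(bundle, features)
    report = confusion_and_metrics(preds, references, bundle.classes)
    probs = predict_proba(bundle, features)
    aucs, curves = roc_auc_one_vs_all(probs, references, bundle.classes)
    report.auc = aucs
    report.roc_curves = curves
    return report


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineConfig:
    """Single-config driver for the whole analysis."""

    out_dir: str = "pipeline_run"
    simulation: SimulationConfig = dc_field(default_factory=SimulationConfig)
    validation_sizes: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_VALIDATION_SIZES)
    )
    slide_mode: str = "bending_energy"
    slide: bool = True
    variance_target: float = 0.90
    designs: tuple[str, ...] = ("1", "2.1", "2.2")
    include_scores: dict[str, bool] | None = None  # per-design override
    random_intercept: bool = False
    n_folds: int = 5
    max_rounds: int = 500
    learning_rate: float = 0.3
    gamma: float = 0.0
    max_depth: int = 6
    run_umap: bool = False
    classifier_residual_mode: str = "marginal"  # identical feature definition for train + new data
    seed: int = 0

    def design_spec(self, design_id: str) -> DesignSpec:
        spec = DesignSpec.default(design_id)
        if self.include_scores and design_id in self.include_scores:
            spec = DesignSpec(id=design_id, include_scores=self.include_scores[design_id])
        return spec


@dataclass
class PipelineResult:
    training: Cohort
    validation: Cohort
    state: MorphometricState
    fits: list[PCMixedFit]
    residuals_training: ResidualSet
    residuals_training_conditional: ResidualSet
    residuals_validation: ResidualSet
    scores_training: dict[str, PatientScores]
    scores_validation: dict[str, PatientScores]
    fa_max: float
    bundles: dict[str, ClassifierBundle]
    reports: dict[str, EvaluationReport]
    umap_coords: dict[str, np.ndarray]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write intermediates to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # simulate ------------------------------------------------------------
    sim = config.simulation
    training = simulate_cohort(sim)
    val_sim = SimulationConfig(**{**sim.__dict__})
    val_sim.group_sizes = dict(config.validation_sizes)
    val_sim.size_scale = 1.0
    val_sim.role = "validation"
    val_sim.seed = sim.seed + 1_000_003
    validation = simulate_cohort(val_sim)
    logger.info(
        "simulate: %d training ears (%d patients), %d validation ears (%d patients)",
        len(training), len(training.patients), len(validation), len(validation.patients),
    )
    training.to_frame().to_csv(out / "cohort_training.csv", index=False)
    validation.to_frame().to_csv(out / "cohort_validation.csv", index=False)

    # landmarks-process ----------------------------------------------------
    state = process_landmarks(
        training, mode=config.slide_mode,
        variance_target=config.variance_target, slide=config.slide,
    )
    np.savez(
        out / "shapespace.npz",
        aligned=state.aligned,
        consensus=state.consensus,
        mean=state.shapespace.mean,
        loadings=state.shapespace.loadings,
        eigenvalues=state.shapespace.eigenvalues,
        k=state.shapespace.k,
    )

    # adjust ---------------------------------------------------------------
    fits = fit_component_models(state, random_intercept=config.random_intercept)
    res_train_cond = residuals_for(fits, state.shapespace.scores, state.records, "conditional")
    res_train = residuals_for(
        fits, state.shapespace.scores, state.records, config.classifier_residual_mode
    )
    val_records, val_scores_mat = project_validation(state, validation)
    res_val = residuals_for(fits, val_scores_mat, val_records, "marginal")
    fits_payload = [
        {
            "component": f.component,
            "alpha": f.alpha,
            "beta_age": f.beta_age,
            "beta_gender": f.beta_gender,
            "sigma_b": f.sigma_b,
            "sigma_eps": f.sigma_eps,
            "singular": f.singular,
        }
        for f in fits
    ]
    (out / "mixed_model_fits.json").write_text(json.dumps(fits_payload, indent=2, sort_keys=True, default=_json_default))

    # score ----------------------------------------------------------------
    scores_train, fa_max = compute_patient_scores(training)
    scores_val, _ = compute_patient_scores(validation, fa_max=fa_max)
    pd.DataFrame(
        [
            {"patient_id": s.patient_id, "severity": s.severity, "asymmetry": s.asymmetry}
            for s in list(scores_train.values()) + list(scores_val.values())
        ]
    ).to_csv(out / "patient_scores.csv", index=False)

    # train / evaluate -----------------------------------------------------
    selected = select_validation_ears(validation, rng)
    sel_ids = {r.photo_id for r in selected}
    sel_mask = [r.photo_id in sel_ids for r in val_records]
    sel_records = [r for r, m in zip(val_records, sel_mask) if m]
    sel_res = ResidualSet(
        residuals=res_val.residuals[np.array(sel_mask, dtype=bool)],
        mode=res_val.mode,
        photo_ids=[r.photo_id for r in sel_records],
    )

    bundles: dict[str, ClassifierBundle] = {}
    reports: dict[str, EvaluationReport] = {}
    umap_coords: dict[str, np.ndarray] = {}
    for design_id in config.designs:
        spec = config.design_spec(design_id)
        feats, labels = assemble_features(res_train, state.records, spec, scores_train)
        if len(set(labels)) < 2:
            logger.warning("design %s: fewer than 2 classes in training; skipped", design_id)
            continue
        bundle = train_classifier(
            feats, labels,
            n_folds=config.n_folds, seed=config.seed,
            learning_rate=config.learning_rate, gamma=config.gamma,
            max_depth=config.max_depth, max_rounds=config.max_rounds,
            design_id=design_id, include_scores=spec.include_scores,
        )
        bundles[design_id] = bundle
        vfeats, vrefs = assemble_features(sel_res, sel_records, spec, scores_val)
        if not len(vfeats):
            logger.warning("design %s: no evaluable validation rows; skipped", design_id)
            continue
        report = evaluate_bundle(bundle, vfeats, vrefs)
        reports[design_id] = report
        logger.info(
            "design %s: %d training rows, %d validation rows, accuracy %.3f",
            design_id, len(feats), len(vfeats), report.accuracy,
        )
        if config.run_umap:
            from .embed import umap_embed

            coords = umap_embed(feats.to_numpy(dtype=float), seed=config.seed)
            umap_coords[design_id] = coords
            pd.DataFrame(
                {"x": coords[:, 0], "y": coords[:, 1], "label": labels}
            ).to_csv(out / f"umap_design_{design_id.replace('.', '_')}.csv", index=False)

    payload = {
        design_id: report.to_dict() for design_id, report in reports.items()
    }
    (out / "evaluation_reports.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return PipelineResult(
        training=training,
        validation=validation,
        state=state,
        fits=fits,
        residuals_training=res_train,
        residuals_training_conditional=res_train_cond,
        residuals_validation=res_val,
        scores_training=scores_train,
        scores_validation=scores_val,
        fa_max=fa_max,
        bundles=bundles,
        reports=reports,
        umap_coords=umap_coords,
    )
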