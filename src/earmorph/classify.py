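"""Feature assembly and gradient-boosted classification designs.

Four designs are supported:

* ``1``   — MFDM vs. Control (binary), best without severity/asymmetry;
* ``2.1`` — MFDM / Control / CHARGE / TC / NAFD, with severity/asymmetry;
* ``2.2`` — MFDM / CHARGE / TC / NAFD (no controls), with severity/asymmetry;
* ``3``   — genotype classes within MFDM.

Features are, per ear, the k mixed-model residuals of the retained shape
components, plus (when ``include_scores``) the patient's severity and
asymmetry scores broadcast to the patient's ear rows. Rows missing a
required feature (e.g. a patient without scores) are dropped with a logged
count.

The classifier is gradient-boosted trees (XGBoost) with a logloss objective;
the iteration count is chosen as the argmin of the stratified 5-fold
cross-validated logloss curve, and the final model is refit on all data at
that count. Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .mixedmodel import ResidualSet
from .scores import PatientScores
from .types import EarRecord, ValidationError

logger = logging.getLogger(__name__)

DESIGN_GROUPS = {
    "1": ("MFDM", "control"),
    "2.1": ("MFDM", "control", "CHARGE", "TC", "NAFD"),
    "2.2": ("MFDM", "CHARGE", "TC", "NAFD"),
    "3": ("MFDM",),
}
# display labels: the control group is capitalized in reports
_LABEL = {"control": "Control"}


@dataclass(frozen=True)
class DesignSpec:
    """One classification design: id, class labels, and score usage."""

    id: str
    include_scores: bool

    def __post_init__(self) -> None:
        if self.id not in DESIGN_GROUPS:
            raise ValidationError(f"unknown design {self.id!r}")

    @staticmethod
    def default(design_id: str) -> "DesignSpec":
        # severity/asymmetry help the multiclass designs but not design 1
        return DesignSpec(id=design_id, include_scores=design_id in ("2.1", "2.2"))

    def label_of(self, record: EarRecord) -> str | None:
        if record.group not in DESIGN_GROUPS[self.id]:
            return None
        if self.id == "3":
            return record.genotype_class
        return _LABEL.get(record.group, record.group)


def assemble_features(
    residuals: ResidualSet,
    records: list[EarRecord],
    design: DesignSpec,
    patient_scores: dict[str, PatientScores] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the (feature table, label vector) for one design.

    ``records`` must align row-for-row with ``residuals``. Rows outside the
    design's groups are excluded; rows whose patient lacks scores are
    dropped (with a logged count) when the design includes scores.
    """
    if len(records) != residuals.residuals.shape[0]:
        raise ValidationError("records do not align with residual rows")
    if design.include_scores and patient_scores is None:
        raise ValidationError(f"design {design.id} requires patient scores")
    k = residuals.residuals.shape[1]
    columns = [f"pc{j + 1}_residual" for j in range(k)]
    rows, labels, dropped = [], [], 0
    for res_row, rec in zip(residuals.residuals, records):
        label = design.label_of(rec)
        if label is None:
            continue
        if design.id == "3" and label == "none":
            continue
        feats = dict(zip(columns, res_row))
        if design.include_scores:
            sc = (patient_scores or {}).get(rec.patient_id)
            if sc is None or not np.isfinite(sc.asymmetry):
                dropped += 1
                continue
            feats["severity"] = float(sc.severity)
            feats["asymmetry"] = float(sc.asymmetry)
        rows.append(feats)
        labels.append(label)
    if dropped:
        logger.info("design %s: dropped %d rows with missing scores", design.id, dropped)
    if design.id == "3" and not labels:
        raise ValidationError("design 3 has no genotype-labelled rows")
    features = pd.DataFrame(rows)
    return features, labels


@dataclass
class ClassifierBundle:
    """Trained boosted-tree model with its CV curve and provenance."""

    booster: xgb.Booster
    classes: list[str]  # sorted label order; argmax ties resolve to the first
    best_round: int  # 0-based argmin of the CV logloss curve
    cv_curve: np.ndarray
    feature_names: list[str]
    design_id: str
    include_scores: bool
    seed: int
    params: dict = field(default_factory=dict)


def train_classifier(
    features: pd.DataFrame,
    labels: list[str],
    n_folds: int = 5,
    seed: int = 0,
    learning_rate: float = 0.3,
    gamma: float = 0.0,
    max_depth: int = 6,
    max_rounds: int = 500,
    design_id: str = "1",
    include_scores: bool = False,
) -> ClassifierBundle:
    """Train boosted trees with CV-selected iteration count.

    Stratified ``n_folds``-fold cross-validation produces a per-round mean
    held-out logloss curve; the final model is refit on all rows at the
    argmin round. Folds are reduced (with a warning) if the rarest class has
    fewer members than ``n_folds``.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    y = np.array([classes.index(lab) for lab in labels])
    x = features.to_numpy(dtype=float)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        new_folds = max(2, int(counts.min()))
        warnings.warn(
            f"class with {counts.min()} members < {n_folds} folds; using {new_folds} folds",
            stacklevel=2,
        )
        n_folds = new_folds
    params = {
        "eta": learning_rate,
        "gamma": gamma,
        "max_depth": max_depth,
        "seed": seed,
        "nthread": 1,
    }
    if len(classes) == 2:
        params |= {"objective": "binary:logistic", "eval_metric": "logloss"}
        metric = "logloss"
    else:
        params |= {
            "objective": "multi:softprob",
            "num_class": len(classes),
            "eval_metric": "mlogloss",
        }
        metric = "mlogloss"

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    curves = []
    for train_idx, test_idx in skf.split(x, y):
        dtrain = xgb.DMatrix(x[train_idx], label=y[train_idx])
        dtest = xgb.DMatrix(x[test_idx], label=y[test_idx])
        history: dict = {}
        xgb.train(
            params,
            dtrain,
            num_boost_round=max_rounds,
            evals=[(dtest, "test")],
            evals_result=history,
            verbose_eval=False,
        )
        curves.append(history["test"][metric])
    cv_curve = np.mean(np.array(curves, dtype=float), axis=0)
    best_round = int(np.argmin(cv_curve))

    dall = xgb.DMatrix(x, label=y, feature_names=list(features.columns))
    booster = xgb.train(params, dall, num_boost_round=best_round + 1)
    return ClassifierBundle(
        booster=booster,
        classes=classes,
        best_round=best_round,
        cv_curve=cv_curve,
        feature_names=list(features.columns),
        design_id=design_id,
        include_scores=include_scores,
        seed=seed,
        params=params,
    )


def predict_proba(bundle: ClassifierBundle, features: pd.DataFrame) -> np.ndarray:
    """Per-class probability rows (columns follow ``bundle.classes``)."""
    if list(features.columns) != bundle.feature_names:
        raise ValidationError(
            f"feature mismatch: expected {bundle.feature_names}, got {list(features.columns)}"
        )
    dmat = xgb.DMatrix(features.to_numpy(dtype=float), feature_names=bundle.feature_names)
    raw = bundle.booster.predict(dmat)
    if raw.ndim == 1:  # binary: probability of class index 1
        return np.column_stack([1.0 - raw, raw])
    return raw


def predict_label(bundle: ClassifierBundle, features: pd.DataFrame) -> list[str]:
    """Argmax class per row; ties resolve to the first label in class order."""
    probs = predict_proba(bundle, features)
    return [bundle.classes[i] for i in np.argmax(probs, axis=1)]


def argmax_label(probabilities, classes) -> str:
    """First maximal class of one probability vector."""
    probs = np.asarray(probabilities, dtype=float)
    return list(classes)[int(np.argmax(probs))]
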