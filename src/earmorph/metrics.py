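"""Classification metrics: confusion matrices, exact CIs, NIR test, AUC, ICC.

Conventions
-----------
* Confusion matrices are oriented prediction rows x reference columns.
* Sensitivity/specificity/balanced accuracy are one-vs-all per reference
  class; for a binary problem the summary Se/Sp refer to the alphabetically
  first class label as the positive class (so with classes Control/MFDM,
  Se = 1.000 means every control was recognized). This is the reverse of
  clinical intuition — the syndrome is the *negative* class of the binary
  summary — and is stated here prominently for that reason.
* "Overall accuracy" is trace/total; multiclass reports sometimes label this
  quantity "balanced accuracy", and the report exposes it under both names.
* The accuracy CI is exact Clopper–Pearson; the accuracy test is a one-sided
  exact binomial test against the no-information rate (the largest reference
  class frequency).
* One-vs-all AUC uses the rank (Mann–Whitney) formulation with ties counted
  one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson interval via Beta quantiles."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts ({successes}, {trials})")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lower, upper


def nir_test(successes: int, trials: int, references) -> tuple[float, float]:
    """One-sided binomial test of accuracy against the no-information rate.

    Returns (NIR, p) with NIR the largest reference-class frequency and
    p = P(X >= successes | Binomial(trials, NIR)).
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts ({successes}, {trials})")
    refs = pd.Series(list(references))
    nir = float(refs.value_counts(normalize=True).max())
    p = float(stats.binom.sf(successes - 1, trials, nir))
    return nir, p


@dataclass
class EvaluationReport:
    """Confusion matrix plus every derived metric."""

    label_order: list[str]
    confusion: np.ndarray  # prediction rows x reference columns
    accuracy: float
    ci_lower: float
    ci_upper: float
    nir: float
    nir_p_value: float
    per_class: pd.DataFrame  # index class; sensitivity, specificity, ...
    sensitivity: float | None = None  # binary summary (positive = first label alphabetically)
    specificity: float | None = None
    balanced_accuracy: float | None = None
    auc: dict[str, float] = field(default_factory=dict)
    roc_curves: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def overall_accuracy(self) -> float:
        return self.accuracy

    def to_dict(self) -> dict:
        out = {
            "label_order": self.label_order,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "nir": self.nir,
            "nir_p_value": self.nir_p_value,
            "per_class": self.per_class.to_dict(orient="index"),
        }
        if self.sensitivity is not None:
            out["sensitivity"] = self.sensitivity
            out["specificity"] = self.specificity
            out["balanced_accuracy"] = self.balanced_accuracy
        if self.auc:
            out["auc"] = dict(self.auc)
        return out


def confusion_matrix_from_labels(predictions, references, label_order) -> np.ndarray:
    preds = list(predictions)
    refs = list(references)
    if len(preds) != len(refs) or not preds:
        raise ValidationError("predictions and references must be equal-length, non-empty")
    index = {lab: i for i, lab in enumerate(label_order)}
    unknown = (set(preds) | set(refs)) - set(label_order)
    if unknown:
        raise ValidationError(f"labels outside label_order: {sorted(unknown)}")
    mat = np.zeros((len(label_order), len(label_order)), dtype=int)
    for p, r in zip(preds, refs):
        mat[index[p], index[r]] += 1
    return mat


def metrics_from_confusion(confusion: np.ndarray, label_order) -> EvaluationReport:
    """Derive every confusion-based metric from a prediction x reference matrix."""
    mat = np.asarray(confusion)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] != len(label_order):
        raise ValidationError("confusion matrix must be square and match label_order")
    if np.any(mat < 0):
        raise ValidationError("confusion matrix entries must be >= 0")
    total = int(mat.sum())
    if total == 0:
        raise ValidationError("empty confusion matrix")
    correct = int(np.trace(mat))
    accuracy = correct / total
    ci_lower, ci_upper = exact_binomial_ci(correct, total)
    ref_counts = mat.sum(axis=0)
    nir = float(ref_counts.max() / total)
    nir_p = float(stats.binom.sf(correct - 1, total, nir))

    rows = {}
    for i, lab in enumerate(label_order):
        tp = mat[i, i]
        fn = ref_counts[i] - tp
        fp = mat[i, :].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        prec = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        f1 = (
            2 * prec * sens / (prec + sens)
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
            else np.nan
        )
        rows[lab] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2,
            "precision": prec,
            "recall": sens,
            "f1": f1,
        }
    per_class = pd.DataFrame(rows).T

    sens = spec = balacc = None
    if len(label_order) == 2:
        positive = sorted(label_order)[0]
        sens = float(per_class.loc[positive, "sensitivity"])
        spec = float(per_class.loc[positive, "specificity"])
        balacc = (sens + spec) / 2
    return EvaluationReport(
        label_order=list(label_order),
        confusion=mat.astype(int),
        accuracy=accuracy,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        nir=nir,
        nir_p_value=nir_p,
        per_class=per_class,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balacc,
    )


def confusion_and_metrics(predictions, references, label_order) -> EvaluationReport:
    """Confusion matrix and all derived metrics from label vectors."""
    mat = confusion_matrix_from_labels(predictions, references, label_order)
    return metrics_from_confusion(mat, label_order)


def roc_auc_one_vs_all(
    probabilities: np.ndarray, references, label_order
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Per-class one-vs-all AUC (rank formulation, ties counted half) + ROC points.

    Classes absent from the references get ``nan`` (AUC undefined). ROC
    curves are returned as (fpr, tpr) arrays over score thresholds.
    """
    probs = np.asarray(probabilities, dtype=float)
    refs = np.asarray(list(references))
    if probs.shape != (len(refs), len(label_order)):
        raise ValidationError("probability matrix shape must be (n, n_classes)")
    aucs: dict[str, float] = {}
    curves: dict[str, np.ndarray] = {}
    for j, lab in enumerate(label_order):
        positive = refs == lab
        n1 = int(positive.sum())
        n0 = len(refs) - n1
        scores = probs[:, j]
        if n1 == 0 or n0 == 0:
            aucs[lab] = float("nan")
            continue
        ranks = stats.rankdata(scores)  # average ranks: ties count one half
        auc = (ranks[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        aucs[lab] = float(auc)
        order = np.argsort(-scores, kind="stable")
        tps = np.cumsum(positive[order])
        fps = np.cumsum(~positive[order])
        # collapse ties on score thresholds
        thresholds = np.flatnonzero(np.diff(np.append(scores[order], -np.inf)) != 0)
        tpr = np.concatenate([[0.0], tps[thresholds] / n1])
        fpr = np.concatenate([[0.0], fps[thresholds] / n0])
        curves[lab] = np.column_stack([fpr, tpr])
    return aucs, curves


def icc_two_raters(measurements: np.ndarray) -> tuple[float, bool]:
    """Two-way random-effects, absolute-agreement, single-rater ICC(2,1).

    *measurements* is an (n items x 2 raters) array with no missing cells.
    Returns (icc, degenerate): ``degenerate`` is True when the table has
    zero total variance, in which case the ICC is reported as 1.0 by
    convention (perfect trivial agreement).
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValidationError("expected an (n >= 2) x 2 measurement table")
    if not np.all(np.isfinite(data)):
        raise ValidationError("missing or non-finite cells")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    if ss_total < 1e-30:
        return 1.0, True
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )
    return float(icc), False
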