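"""Feature assembly and the boosted-tree training/prediction contract."""

import numpy as np
import pandas as pd
import pytest

from earmorph import (
    DesignSpec,
    PatientScores,
    ResidualSet,
    ValidationError,
    argmax_label,
    assemble_features,
    predict_label,
    predict_proba,
    train_classifier,
)
from earmorph.types import EarRecord


def _records(groups, genotypes=None):
    recs = []
    for i, g in enumerate(groups):
        recs.append(
            EarRecord(
                patient_id=f"p{i}", photo_id=f"ph{i}", side="right", age=5.0,
                gender="female", group=g,
                genotype_class=(genotypes[i] if genotypes else "none"),
            )
        )
    return recs


def _residuals(n, k=8, seed=0):
    rng = np.random.default_rng(seed)
    return ResidualSet(residuals=rng.normal(size=(n, k)), mode="marginal")


def test_design1_has_k_feature_columns():
    groups = ["MFDM"] * 4 + ["control"] * 4 + ["TC"] * 2
    feats, labels = assemble_features(
        _residuals(10), _records(groups), DesignSpec("1", include_scores=False)
    )
    assert feats.shape == (8, 8)  # TC rows excluded, k=8 columns
    assert set(labels) == {"MFDM", "Control"}


def test_include_scores_adds_two_columns_and_drops_unscored_rows():
    groups = ["MFDM"] * 3 + ["control"] * 3
    scores = {
        f"p{i}": PatientScores(patient_id=f"p{i}", severity=0, asymmetry=0.2)
        for i in range(5)  # p5 has no scores
    }
    feats, labels = assemble_features(
        _residuals(6), _records(groups), DesignSpec("2.1", include_scores=True), scores
    )
    assert feats.shape == (5, 10)
    assert list(feats.columns[-2:]) == ["severity", "asymmetry"]


def test_design3_uses_genotype_labels():
    groups = ["MFDM"] * 6 + ["control"] * 2
    genos = ["splice", "splice", "frameshift", "nonsense", "deletion", "deletion",
             "none", "none"]
    feats, labels = assemble_features(
        _residuals(8), _records(groups, genos), DesignSpec("3", include_scores=False)
    )
    assert len(labels) == 6
    assert set(labels) <= {"splice", "frameshift", "nonsense", "deletion"}


def test_design3_without_genotypes_is_an_error():
    groups = ["control"] * 4
    with pytest.raises(ValidationError):
        assemble_features(
            _residuals(4), _records(groups), DesignSpec("3", include_scores=False)
        )


def _separable_data(rng, n_per_class=60, classes=("A", "B")):
    rows, labels = [], []
    for c, lab in enumerate(classes):
        centre = np.zeros(5)
        centre[c % 5] = 4.0
        rows.append(rng.normal(size=(n_per_class, 5)) + centre)
        labels += [lab] * n_per_class
    return pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(5)]), labels


def test_separable_classes_are_learned():
    rng = np.random.default_rng(0)
    feats, labels = _separable_data(rng)
    test_feats, test_labels = _separable_data(np.random.default_rng(99))
    bundle = train_classifier(feats, labels, max_rounds=60, seed=1)
    preds = predict_label(bundle, test_feats)
    accuracy = np.mean(np.array(preds) == np.array(test_labels))
    assert accuracy > 0.95
    # the CV curve must have improved from its starting value
    assert bundle.cv_curve[bundle.best_round] < bundle.cv_curve[0]


def test_pure_noise_gives_chance_level_accuracy():
    rng = np.random.default_rng(1)
    feats = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"f{i}" for i in range(5)])
    labels = ["A"] * 100 + ["B"] * 100
    bundle = train_classifier(feats, labels, max_rounds=40, seed=2)
    held = pd.DataFrame(rng.normal(size=(400, 5)), columns=feats.columns)
    held_labels = ["A"] * 200 + ["B"] * 200
    accuracy = np.mean(np.array(predict_label(bundle, held)) == held_labels)
    # binomial 99.9% band around 0.5 at n=400
    assert 0.41 < accuracy < 0.59


def test_same_seed_is_deterministic():
    rng = np.random.default_rng(3)
    feats, labels = _separable_data(rng, n_per_class=40)
    a = train_classifier(feats, labels, max_rounds=30, seed=7)
    b = train_classifier(feats, labels, max_rounds=30, seed=7)
    assert a.best_round == b.best_round
    np.testing.assert_array_equal(predict_proba(a, feats), predict_proba(b, feats))


def test_probabilities_sum_to_one_multiclass():
    rng = np.random.default_rng(4)
    feats, labels = _separable_data(rng, n_per_class=30, classes=("A", "B", "C"))
    bundle = train_classifier(feats, labels, max_rounds=20, seed=0)
    probs = predict_proba(bundle, feats)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_small_class_reduces_folds_with_warning():
    rng = np.random.default_rng(5)
    feats = pd.DataFrame(rng.normal(size=(23, 3)), columns=["a", "b", "c"])
    labels = ["A"] * 20 + ["B"] * 3
    with pytest.warns(UserWarning, match="folds"):
        bundle = train_classifier(feats, labels, max_rounds=10, seed=0)
    assert bundle.best_round >= 0


def test_single_class_is_an_error():
    feats = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
    with pytest.raises(ValidationError):
        train_classifier(feats, ["A"] * 10)


def test_feature_mismatch_is_an_error():
    rng = np.random.default_rng(6)
    feats, labels = _separable_data(rng, n_per_class=20)
    bundle = train_classifier(feats, labels, max_rounds=10, seed=0)
    wrong = feats.rename(columns={"f0": "zzz"})
    with pytest.raises(ValidationError):
        predict_proba(bundle, wrong)


def test_case_study_probability_vector_argmax():
    classes = ("CHARGE", "control", "MFDM", "NAFD", "TC")
    probs = (0.84, 0.11, 0.03, 0.02, 0.01)
    assert argmax_label(probs, classes) == "CHARGE"
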