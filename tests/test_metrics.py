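"""Metric engine: CIs, NIR test, confusion metrics, AUC, ICC."""

import numpy as np
import pytest
from scipy import stats

from earmorph import (
    ValidationError,
    confusion_and_metrics,
    exact_binomial_ci,
    icc_two_raters,
    metrics_from_confusion,
    nir_test,
    roc_auc_one_vs_all,
)


# --- exact binomial CI -----------------------------------------------------

def test_ci_boundaries():
    assert exact_binomial_ci(32, 32)[1] == 1.0
    assert exact_binomial_ci(0, 32)[0] == 0.0


def _ci_by_bisection(x, n, alpha=0.05):
    """Independent oracle: invert the exact binomial tail equalities."""
    def solve(func, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if func(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    # lower bound: P(X >= x | p) = alpha/2 ; sf is increasing in p
    lower = 0.0 if x == 0 else solve(
        lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 0.0, 1.0
    )
    # upper bound: P(X <= x | p) = alpha/2 ; cdf is decreasing in p
    upper = 1.0 if x == n else solve(
        lambda p: alpha / 2 - stats.binom.cdf(x, n, p), 0.0, 1.0
    )
    return lower, upper


@pytest.mark.parametrize("x, n", [(13, 16), (31, 32), (5, 50), (1, 3)])
def test_ci_matches_tail_probability_bisection(x, n):
    lo, hi = exact_binomial_ci(x, n)
    olo, ohi = _ci_by_bisection(x, n)
    assert lo == pytest.approx(olo, abs=1e-6)
    assert hi == pytest.approx(ohi, abs=1e-6)


def test_ci_coverage_in_simulation():
    """Clopper–Pearson is conservative: empirical coverage must be >= nominal."""
    rng = np.random.default_rng(0)
    p_true, n = 0.8, 30
    covered = 0
    for _ in range(500):
        x = rng.binomial(n, p_true)
        lo, hi = exact_binomial_ci(x, n)
        covered += lo <= p_true <= hi
    assert covered / 500 >= 0.95


def test_ci_invalid_counts():
    with pytest.raises(ValidationError):
        exact_binomial_ci(5, 3)


# --- NIR test ----------------------------------------------------------------

def test_nir_at_the_center_of_the_distribution():
    refs = ["A"] * 6 + ["B"] * 4
    successes = 6  # exactly NIR * trials
    _, p = nir_test(successes, 10, refs)
    assert p > 0.4


def test_nir_small_case_matches_hand_summation():
    refs = ["A"] * 3 + ["B"] * 2  # NIR = 0.6
    _, p = nir_test(4, 5, refs)
    expected = sum(
        stats.binom.pmf(k, 5, 0.6) for k in (4, 5)
    )
    assert p == pytest.approx(expected, abs=1e-12)


# --- confusion metrics -------------------------------------------------------

def test_all_correct_predictions():
    report = confusion_and_metrics(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
    assert report.accuracy == 1.0
    assert (report.per_class["balanced_accuracy"] == 1.0).all()


def test_matrix_orientation_is_prediction_rows():
    report = confusion_and_metrics(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
    np.testing.assert_array_equal(report.confusion, [[1, 1], [0, 1]])


def test_binary_positive_class_is_alphabetical():
    # predictions recognize every "Control" but miss one "MFDM"
    preds = ["MFDM"] * 10 + ["Control"] * 22
    refs = ["MFDM"] * 11 + ["Control"] * 21
    report = confusion_and_metrics(preds, refs, ["MFDM", "Control"])
    assert report.sensitivity == pytest.approx(1.0)  # Control is positive
    assert report.specificity == pytest.approx(10 / 11, abs=1e-9)


def test_empty_input_rejected():
    with pytest.raises(ValidationError):
        confusion_and_metrics([], [], ["A"])


def test_negative_confusion_entries_rejected():
    with pytest.raises(ValidationError):
        metrics_from_confusion(np.array([[1, -1], [0, 2]]), ["A", "B"])


# --- one-vs-all AUC ----------------------------------------------------------

def test_perfectly_ranked_scores_have_auc_one():
    probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
    refs = ["A", "A", "B", "B"]
    aucs, _ = roc_auc_one_vs_all(probs, refs, ["A", "B"])
    assert aucs["A"] == 1.0
    assert aucs["B"] == 1.0


def test_constant_scores_give_half_by_tie_convention():
    probs = np.full((10, 2), 0.5)
    refs = ["A"] * 5 + ["B"] * 5
    aucs, _ = roc_auc_one_vs_all(probs, refs, ["A", "B"])
    assert aucs["A"] == pytest.approx(0.5)


def test_random_scores_have_auc_near_half():
    rng = np.random.default_rng(1)
    n = 2000
    probs = rng.random((n, 2))
    probs = probs / probs.sum(axis=1, keepdims=True)
    refs = list(rng.choice(["A", "B"], size=n))
    aucs, _ = roc_auc_one_vs_all(probs, refs, ["A", "B"])
    assert abs(aucs["A"] - 0.5) < 0.03


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(2)
    scores = rng.random(300)
    y = rng.integers(0, 2, 300)
    probs = np.column_stack([1 - scores, scores])
    refs = ["B" if v else "A" for v in y]
    aucs, _ = roc_auc_one_vs_all(probs, refs, ["A", "B"])
    assert aucs["B"] == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.random(100)
    refs = ["B" if v else "A" for v in rng.integers(0, 2, 100)]
    a1, _ = roc_auc_one_vs_all(np.column_stack([1 - scores, scores]), refs, ["A", "B"])
    warped = np.exp(5 * scores)
    a2, _ = roc_auc_one_vs_all(np.column_stack([-warped, warped]), refs, ["A", "B"])
    assert a1["B"] == pytest.approx(a2["B"], abs=1e-12)


def test_absent_class_is_flagged_nan():
    probs = np.array([[0.5, 0.5]] * 4)
    refs = ["A"] * 4
    aucs, _ = roc_auc_one_vs_all(probs, refs, ["A", "B"])
    assert np.isnan(aucs["B"])


# --- ICC ---------------------------------------------------------------------

def test_identical_raters_have_icc_one():
    rng = np.random.default_rng(4)
    values = rng.normal(size=50)
    icc, degenerate = icc_two_raters(np.column_stack([values, values]))
    assert icc == pytest.approx(1.0, abs=1e-10)
    assert not degenerate


def test_independent_raters_have_icc_near_zero():
    rng = np.random.default_rng(5)
    data = rng.normal(size=(500, 2))
    icc, _ = icc_two_raters(data)
    assert abs(icc) < 0.1


def test_six_item_table_matches_hand_anova():
    data = np.array(
        [[9.0, 2.0], [10.0, 5.0], [8.0, 4.0], [7.0, 1.0], [8.0, 2.0], [9.0, 3.0]]
    )
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_err = (
        ((data - grand) ** 2).sum()
        - k * ((data.mean(axis=1) - grand) ** 2).sum()
        - n * ((data.mean(axis=0) - grand) ** 2).sum()
    )
    ms_err = ss_err / ((n - 1) * (k - 1))
    expected = (ms_rows - ms_err) / (ms_rows + ms_err + 2 * (ms_cols - ms_err) / n)
    icc, _ = icc_two_raters(data)
    assert icc == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(6)
    true = rng.normal(0.0, 2.0, 40)
    data = np.column_stack(
        [true + rng.normal(0, 0.5, 40), true + 0.3 + rng.normal(0, 0.5, 40)]
    )
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(40), 2),
            "raters": ["r1", "r2"] * 40,
            "scores": data.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="targets", raters="raters",
                               ratings="scores")
    expected = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    icc, _ = icc_two_raters(data)
    assert icc == pytest.approx(expected, abs=1e-8)


def test_zero_variance_is_degenerate():
    icc, degenerate = icc_two_raters(np.full((5, 2), 3.0))
    assert degenerate


def test_missing_cells_rejected():
    with pytest.raises(ValidationError):
        icc_two_raters(np.array([[1.0, np.nan], [2.0, 2.0]]))
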