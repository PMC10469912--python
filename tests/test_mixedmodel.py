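"""Random-age-slope mixed model: recovery, oracles, residual properties."""

import warnings

import numpy as np
import pandas as pd
import pytest

from earmorph import (
    PCMixedFit,
    ValidationError,
    fit_pc_mixed_model,
    residualize,
)


def simulate_longitudinal(
    rng, n_patients=60, photos=3, alpha=0.5, beta_age=0.2, beta_gender=-0.3,
    sigma_b=0.1, sigma_eps=0.4,
):
    rows = []
    for i in range(n_patients):
        male = rng.random() < 0.5
        b_i = rng.normal(0.0, sigma_b)
        base_age = rng.uniform(0.5, 15.0)
        for j in range(photos):
            age = base_age + j * rng.uniform(0.5, 2.0)
            y = (
                alpha + beta_age * age + beta_gender * male + b_i * age
                + rng.normal(0.0, sigma_eps)
            )
            rows.append((y, age, "male" if male else "female", f"p{i}"))
    frame = pd.DataFrame(rows, columns=["y", "age", "gender", "patient"])
    return frame


def _fit(frame, **kwargs):
    return fit_pc_mixed_model(
        frame["y"], frame["age"], frame["gender"], frame["patient"], **kwargs
    )


def test_null_data_recovers_zero_effects():
    rng = np.random.default_rng(0)
    frame = simulate_longitudinal(rng, beta_age=0.0, beta_gender=0.0, sigma_b=0.0)
    fit = _fit(frame)
    assert abs(fit.beta_age) < 3 * fit.se_beta_age
    assert abs(fit.beta_gender) < 3 * fit.se_beta_gender


def test_known_parameters_recovered():
    rng = np.random.default_rng(1)
    frame = simulate_longitudinal(rng, n_patients=200, photos=3)
    fit = _fit(frame)
    assert abs(fit.beta_age - 0.2) < 3 * fit.se_beta_age
    assert abs(fit.beta_gender + 0.3) < 3 * fit.se_beta_gender
    assert fit.sigma_b == pytest.approx(0.1, abs=0.05)
    assert fit.sigma_eps == pytest.approx(0.4, abs=0.05)
    assert not fit.singular


def test_agrees_with_statsmodels_mixedlm():
    """Cross-implementation oracle: REML fixed effects must match MixedLM."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(2)
    frame = simulate_longitudinal(rng, n_patients=50)
    frame["male"] = (frame["gender"] == "male").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = smf.mixedlm(
            "y ~ age + male", frame, groups=frame["patient"], re_formula="0 + age"
        ).fit(reml=True)
    fit = _fit(frame)
    assert fit.alpha == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
    assert fit.beta_age == pytest.approx(sm_fit.params["age"], abs=1e-4)
    assert fit.beta_gender == pytest.approx(sm_fit.params["male"], abs=1e-4)
    sm_sigma_b = float(np.sqrt(sm_fit.cov_re.iloc[0, 0]))
    assert fit.sigma_b == pytest.approx(sm_sigma_b, abs=1e-3)


def test_boundary_variance_returns_singular_flag_not_exception():
    rng = np.random.default_rng(3)
    frame = simulate_longitudinal(rng, sigma_b=0.0, sigma_eps=0.2)
    fit = _fit(frame)
    assert fit.sigma_b == pytest.approx(0.0, abs=0.02)
    # a flagged boundary fit is acceptable; no exception either way
    if fit.sigma_b == 0.0:
        assert fit.singular


def test_sigma_b_zero_makes_conditional_equal_marginal():
    rng = np.random.default_rng(4)
    frame = simulate_longitudinal(rng, sigma_b=0.0)
    fit = _fit(frame)
    fit.patient_slopes = {p: 0.0 for p in fit.patient_slopes}  # force exact boundary
    cond = residualize(fit, frame["y"], frame["age"], frame["gender"], frame["patient"],
                       mode="conditional")
    marg = residualize(fit, frame["y"], frame["age"], frame["gender"], frame["patient"],
                       mode="marginal")
    np.testing.assert_allclose(cond, marg, atol=1e-12)


def test_training_conditional_residuals_have_zero_mean():
    rng = np.random.default_rng(5)
    frame = simulate_longitudinal(rng, n_patients=80)
    fit = _fit(frame)
    cond = residualize(fit, frame["y"], frame["age"], frame["gender"], frame["patient"],
                       mode="conditional")
    assert abs(cond.mean()) < 1e-6


def test_residuals_match_hand_arithmetic():
    """4-observation example with fixed coefficients, checked by hand."""
    fit = PCMixedFit(
        component=0, alpha=1.0, beta_age=0.5, beta_gender=-2.0,
        sigma_b=0.1, sigma_eps=0.3,
        se_alpha=0.1, se_beta_age=0.1, se_beta_gender=0.1, se_sigma_b=None,
        patient_slopes={"a": 0.2, "b": -0.1}, patient_intercepts=None,
        singular=False, restricted_loglik=0.0,
    )
    y = [3.0, 4.0, 1.0, 0.0]
    age = [2.0, 4.0, 1.0, 3.0]
    gender = ["female", "female", "male", "male"]
    patient = ["a", "a", "b", "b"]
    # conditional: y - (alpha + 0.5*age - 2*male + slope*age)
    expected_cond = [
        3.0 - (1.0 + 1.0 + 0.4),          # 0.6
        4.0 - (1.0 + 2.0 + 0.8),          # 0.2
        1.0 - (1.0 + 0.5 - 2.0 - 0.1),    # 1.6
        0.0 - (1.0 + 1.5 - 2.0 - 0.3),    # -0.2
    ]
    cond = residualize(fit, y, age, gender, patient, mode="conditional")
    np.testing.assert_allclose(cond, expected_cond, atol=1e-12)
    expected_marg = [1.0, 1.0, 1.5, -0.5]
    marg = residualize(fit, y, age, gender, patient, mode="marginal")
    np.testing.assert_allclose(marg, expected_marg, atol=1e-12)


def test_unseen_patient_falls_back_to_marginal_with_warning():
    rng = np.random.default_rng(6)
    frame = simulate_longitudinal(rng, n_patients=10)
    fit = _fit(frame)
    with pytest.warns(UserWarning, match="unseen"):
        res = residualize(fit, [1.0], [2.0], ["female"], ["new_patient"],
                          mode="conditional")
    marg = residualize(fit, [1.0], [2.0], ["female"], ["new_patient"], mode="marginal")
    np.testing.assert_allclose(res, marg)


def test_conditional_residuals_uncorrelated_with_age():
    """Residualization removes a strong true age trend."""
    rng = np.random.default_rng(7)
    frame = simulate_longitudinal(rng, n_patients=150, beta_age=1.5)
    fit = _fit(frame)
    cond = residualize(fit, frame["y"], frame["age"], frame["gender"], frame["patient"],
                       mode="conditional")
    design = np.column_stack([np.ones(len(frame)), frame["age"]])
    coef, res_ss, *_ = np.linalg.lstsq(design, cond, rcond=None)
    dof = len(frame) - 2
    sigma2 = float(res_ss[0]) / dof if len(res_ss) else np.var(cond)
    se_slope = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[1, 1])
    assert abs(coef[1]) < 3 * se_slope


def test_non_finite_inputs_rejected():
    with pytest.raises(ValidationError):
        fit_pc_mixed_model([1.0, np.nan, 2.0], [1, 2, 3], ["female"] * 3,
                           ["a", "a", "b"])


def test_random_intercept_option_runs():
    rng = np.random.default_rng(8)
    frame = simulate_longitudinal(rng, n_patients=40)
    fit = _fit(frame, random_intercept=True)
    assert fit.random_intercept
    assert fit.patient_intercepts is not None
    assert np.isfinite(fit.beta_age)
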