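"""Per-component linear mixed models and covariate residualization.

Each retained shape principal component is modelled as

    PC_ij = alpha + beta1 * age_ij + beta2 * male_i + b_i * age_ij + eps_ij

with a random slope for age per individual, b_i ~ N(0, sigma_b^2), and
residual eps_ij ~ N(0, sigma_eps^2). Gender is coded 0 = female, 1 = male.
No age x gender interaction is included. The residuals eps are the
classifier's inputs: conditional residuals (subtracting the predicted
individual slope) for training individuals, marginal residuals (fixed
effects only) for individuals unseen in training, for whom random effects
are inestimable.

Fitting is restricted maximum likelihood, profiled over the variance ratio
theta = sigma_b^2 / sigma_eps^2: for fixed theta the marginal covariance per
individual is I + theta z z' (z the individual's age vector), beta is the
GLS solution and sigma_eps^2 = RSS / (n - p), leaving a one-dimensional
search over theta. The optional independent random intercept adds a second
ratio and a two-dimensional search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .types import ValidationError

_SINGULAR_THETA = 1e-8


def _encode_gender(gender) -> np.ndarray:
    arr = np.asarray(gender)
    if arr.dtype.kind in "UO":
        out = np.zeros(arr.shape, dtype=float)
        for i, g in enumerate(arr.ravel()):
            if g == "male":
                out.ravel()[i] = 1.0
            elif g != "female":
                raise ValidationError(f"invalid gender {g!r}")
        return out
    return arr.astype(float)


@dataclass
class PCMixedFit:
    """REML fit of one principal component's mixed model."""

    component: int
    alpha: float
    beta_age: float
    beta_gender: float
    sigma_b: float
    sigma_eps: float
    se_alpha: float
    se_beta_age: float
    se_beta_gender: float
    se_sigma_b: float | None
    patient_slopes: dict[str, float]
    patient_intercepts: dict[str, float] | None
    singular: bool
    restricted_loglik: float
    random_intercept: bool = False
    sigma_b0: float = 0.0

    @property
    def fixed_effects(self) -> np.ndarray:
        return np.array([self.alpha, self.beta_age, self.beta_gender])


@dataclass
class ResidualSet:
    """Per-ear residuals for each retained component."""

    residuals: np.ndarray  # (n_ears, k)
    mode: str  # conditional | marginal
    photo_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.residuals)):
            raise ValidationError("non-finite residuals")


def _group_blocks(patient_id) -> tuple[list[str], list[np.ndarray]]:
    ids = np.asarray(patient_id)
    patients = list(dict.fromkeys(ids.tolist()))
    return patients, [np.flatnonzero(ids == p) for p in patients]


def _reml_pieces(y, x, z_blocks, blocks, ratios):
    """GLS beta, RSS and the two log-determinant terms at given variance ratios."""
    p = x.shape[1]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    logdet_w = 0.0
    winv_blocks = []
    for idx, z in zip(blocks, z_blocks):
        ni = len(idx)
        w = np.eye(ni) + (z * ratios) @ z.T
        winv = np.linalg.inv(w)
        sign, ld = np.linalg.slogdet(w)
        logdet_w += ld
        xi = x[idx]
        xtwx += xi.T @ winv @ xi
        xtwy += xi.T @ winv @ y[idx]
        winv_blocks.append(winv)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = 0.0
    for idx, winv in zip(blocks, winv_blocks):
        r = y[idx] - x[idx] @ beta
        rss += float(r @ winv @ r)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    return beta, rss, logdet_w, logdet_xtwx, xtwx


def _criterion(y, x, z_blocks, blocks, ratios):
    n, p = x.shape
    _, rss, logdet_w, logdet_xtwx, _ = _reml_pieces(y, x, z_blocks, blocks, ratios)
    return logdet_w + logdet_xtwx + (n - p) * np.log(rss)


def _restricted_loglik(y, x, z_blocks, blocks, ratios):
    """-2 * restricted log-likelihood up to the additive constant removed."""
    n, p = x.shape
    _, rss, logdet_w, logdet_xtwx, _ = _reml_pieces(y, x, z_blocks, blocks, ratios)
    sigma2 = rss / (n - p)
    m2ll = (
        (n - p) * np.log(2 * np.pi * sigma2)
        + logdet_w
        + logdet_xtwx
        - p * np.log(sigma2)
        + (n - p)
    )
    return -0.5 * m2ll


def fit_pc_mixed_model(
    scores,
    age,
    gender,
    patient_id,
    component: int = 0,
    random_intercept: bool = False,
) -> PCMixedFit:
    """REML fit of the random-age-slope model for one component.

    A boundary fit (sigma_b -> 0) is returned with ``singular=True`` rather
    than raised. Requires at least 2 patients; the random-slope variance is
    only identifiable when some patients contribute repeated observations.
    """
    y = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    male = _encode_gender(gender)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(age)) and np.all(np.isfinite(male))):
        raise ValidationError("non-finite inputs to mixed-model fit")
    patients, blocks = _group_blocks(patient_id)
    if len(patients) < 2:
        raise ValidationError("mixed-model fit requires at least 2 patients")
    n = len(y)
    x = np.column_stack([np.ones(n), age, male])

    if random_intercept:
        z_blocks = [np.column_stack([np.ones(len(idx)), age[idx]]) for idx in blocks]
        q = 2
    else:
        z_blocks = [age[idx][:, None] for idx in blocks]
        q = 1

    def f(log_ratios):
        return _criterion(y, x, z_blocks, blocks, np.exp(log_ratios))

    if q == 1:
        res = minimize_scalar(lambda t: f(np.array([t])), bounds=(-25.0, 10.0), method="bounded")
        best = np.array([res.x])
        best_val = res.fun
    else:
        res = minimize(f, x0=np.array([-1.0, -1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
        best = res.x
        best_val = res.fun
    # compare against the no-random-effect boundary
    boundary_val = _criterion(y, x, z_blocks, blocks, np.zeros(q))
    if boundary_val <= best_val:
        ratios = np.zeros(q)
    else:
        ratios = np.exp(best)
        ratios[ratios < _SINGULAR_THETA] = 0.0

    beta, rss, _, _, xtwx = _reml_pieces(y, x, z_blocks, blocks, ratios)
    p = x.shape[1]
    sigma_eps2 = rss / (n - p)
    sigma_eps = float(np.sqrt(sigma_eps2))
    slope_ratio = ratios[-1]
    intercept_ratio = ratios[0] if q == 2 else 0.0
    sigma_b = float(np.sqrt(slope_ratio * sigma_eps2))
    sigma_b0 = float(np.sqrt(intercept_ratio * sigma_eps2))
    singular = bool(slope_ratio <= _SINGULAR_THETA)

    cov_beta = sigma_eps2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_beta))

    # BLUPs: b_hat_i = D Z_i' W_i^-1 (y_i - X_i beta), D in ratio units
    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {} if q == 2 else None
    for pat, idx, z in zip(patients, blocks, z_blocks):
        w = np.eye(len(idx)) + (z * ratios) @ z.T
        r = y[idx] - x[idx] @ beta
        b = ratios * (z.T @ np.linalg.solve(w, r))
        slopes[pat] = float(b[-1])
        if q == 2:
            intercepts[pat] = float(b[0])

    # SE of sigma_b via the observed information of -2 REML loglik in
    # (sigma_b, sigma_eps); undefined on the boundary.
    se_sigma_b: float | None = None
    if not singular and not random_intercept:
        # full -2ll as a function of (sigma_b, sigma_eps), beta profiled
        def m2ll_full(params):
            sb, se = params
            ratio = np.array([(sb / se) ** 2])
            _, rss_, ldw, ldx, _ = _reml_pieces(y, x, z_blocks, blocks, ratio)
            s2 = se**2
            return (
                (n - p) * np.log(2 * np.pi * s2)
                + ldw
                + ldx
                - p * np.log(s2)
                + rss_ / s2
            )

        theta0 = np.array([sigma_b, sigma_eps])
        h = np.zeros((2, 2))
        step = theta0 * 1e-4 + 1e-8
        for a in range(2):
            for b_ in range(2):
                ea = np.eye(2)[a] * step[a]
                eb = np.eye(2)[b_] * step[b_]
                h[a, b_] = (
                    m2ll_full(theta0 + ea + eb)
                    - m2ll_full(theta0 + ea - eb)
                    - m2ll_full(theta0 - ea + eb)
                    + m2ll_full(theta0 - ea - eb)
                ) / (4 * step[a] * step[b_])
        try:
            cov_var = 2.0 * np.linalg.inv(h)
            if cov_var[0, 0] > 0:
                se_sigma_b = float(np.sqrt(cov_var[0, 0]))
        except np.linalg.LinAlgError:  # pragma: no cover
            se_sigma_b = None

    return PCMixedFit(
        component=component,
        alpha=float(beta[0]),
        beta_age=float(beta[1]),
        beta_gender=float(beta[2]),
        sigma_b=sigma_b,
        sigma_eps=sigma_eps,
        se_alpha=float(ses[0]),
        se_beta_age=float(ses[1]),
        se_beta_gender=float(ses[2]),
        se_sigma_b=se_sigma_b,
        patient_slopes=slopes,
        patient_intercepts=intercepts,
        singular=singular,
        restricted_loglik=float(
            _restricted_loglik(y, x, z_blocks, blocks, ratios)
        ),
        random_intercept=random_intercept,
        sigma_b0=sigma_b0,
    )


def residualize(
    fit: PCMixedFit,
    scores,
    age,
    gender,
    patient_id,
    mode: str = "conditional",
) -> np.ndarray:
    """Residuals eps for one component under a fitted model.

    ``conditional`` subtracts each training individual's predicted random
    slope (and intercept, if fitted); a patient unseen in training falls
    back to the marginal prediction with a warning. ``marginal`` subtracts
    fixed effects only. With sigma_b = 0 the two modes coincide.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown residual mode {mode!r}")
    y = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    male = _encode_gender(gender)
    ids = np.asarray(patient_id)
    pred = fit.alpha + fit.beta_age * age + fit.beta_gender * male
    if mode == "conditional":
        unseen = sorted({p for p in ids.tolist() if p not in fit.patient_slopes})
        if unseen:
            warnings.warn(
                f"{len(unseen)} patients unseen in training; using marginal residuals for them",
                stacklevel=2,
            )
        slope = np.array([fit.patient_slopes.get(p, 0.0) for p in ids])
        pred = pred + slope * age
        if fit.patient_intercepts is not None:
            pred = pred + np.array([fit.patient_intercepts.get(p, 0.0) for p in ids])
    return y - pred


def fit_all_components(
    score_matrix,
    age,
    gender,
    patient_id,
    random_intercept: bool = False,
) -> list[PCMixedFit]:
    """Fit one mixed model per column of a (n_ears, k) score matrix."""
    mat = np.asarray(score_matrix, dtype=float)
    return [
        fit_pc_mixed_model(
            mat[:, j], age, gender, patient_id,
            component=j, random_intercept=random_intercept,
        )
        for j in range(mat.shape[1])
    ]


def residualize_all(
    fits: list[PCMixedFit],
    score_matrix,
    age,
    gender,
    patient_id,
    mode: str = "conditional",
    photo_ids: list[str] | None = None,
) -> ResidualSet:
    """Residual matrix across all fitted components."""
    mat = np.asarray(score_matrix, dtype=float)
    if mat.shape[1] != len(fits):
        raise ValidationError("score matrix width does not match number of fits")
    res = np.column_stack(
        [
            residualize(fit, mat[:, j], age, gender, patient_id, mode=mode)
            for j, fit in enumerate(fits)
        ]
    )
    return ResidualSet(residuals=res, mode=mode, photo_ids=photo_ids or [])
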