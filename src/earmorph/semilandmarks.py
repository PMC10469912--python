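"""Thin-plate-spline bending energy and semilandmark sliding.

Curve points carry no exact anatomical identity along their curve, so after
superimposition each semilandmark is allowed to slide along its local
tangent (the unit chord between its curve neighbours) to minimize either the
TPS bending energy of the configuration against the current consensus
(``bending_energy`` mode, the classical treatment) or its squared Procrustes
distance to the consensus (``procrustes_distance`` mode). Anchors — curve
endpoints and free anatomical points — never move.

The outer loop alternates sliding with re-superimposition (GPA); the mode's
objective is kept non-increasing by construction: an outer iteration that
would increase it is reverted and iteration stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .procrustes import AlignedSet, gpa
from .template import EarTemplate
from .types import GeometryError

RIDGE = 1e-10


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Upper-left p x p block of the inverse bordered TPS system.

    Kernel ``K_ij = r^2 log r^2`` (0 on the diagonal) with affine border
    ``Q = (1, x, y)``; the returned matrix is the bending-energy quadratic
    form: symmetric, positive semi-definite, and annihilating affine
    displacement fields.
    """
    ref = np.asarray(reference, dtype=float)
    p = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    off_diag = ~np.eye(p, dtype=bool)
    if np.any(r2[off_diag] < 1e-20):
        raise GeometryError("coincident reference points in TPS kernel")
    kernel = np.zeros_like(r2)
    kernel[off_diag] = r2[off_diag] * np.log(r2[off_diag])
    q = np.hstack([np.ones((p, 1)), ref])
    bordered = np.zeros((p + 3, p + 3))
    bordered[:p, :p] = kernel
    bordered[:p, p:] = q
    bordered[p:, :p] = q.T
    inv = np.linalg.inv(bordered)
    be = inv[:p, :p]
    return (be + be.T) / 2.0


def bending_energy(be_matrix: np.ndarray, displacement: np.ndarray) -> float:
    """Bending energy of a (p, 2) displacement field: sum over x and y."""
    d = np.asarray(displacement, dtype=float)
    return float(d[:, 0] @ be_matrix @ d[:, 0] + d[:, 1] @ be_matrix @ d[:, 1])


@dataclass
class SlideResult:
    aligned: AlignedSet
    objective_history: list[float]
    mode: str


def _tangents(config: np.ndarray, template: EarTemplate) -> dict[int, np.ndarray]:
    """Unit chord between each semilandmark's curve neighbours."""
    out: dict[int, np.ndarray] = {}
    for idx in template.semilandmark_indices():
        prev_i, next_i = template.neighbors(idx)
        chord = config[next_i] - config[prev_i]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            raise GeometryError(f"zero-length tangent chord at point {idx}")
        out[idx] = chord / norm
    return out


def _slide_one(
    config: np.ndarray,
    consensus: np.ndarray,
    template: EarTemplate,
    be_matrix: np.ndarray | None,
) -> np.ndarray:
    """Slide one configuration's semilandmarks along their tangents.

    Solves t = -(U' B U)^-1 U' B (x - xbar) over the tangent directions,
    with B the bending-energy form (``None`` means the identity, i.e. the
    procrustes_distance mode, in which the solve decouples per point).
    """
    tangents = _tangents(config, template)
    semis = list(tangents.keys())
    residual = (config - consensus).ravel()  # interleaved x0,y0,x1,y1,...
    p = config.shape[0]
    m = len(semis)
    basis = np.zeros((2 * p, m))
    for j, idx in enumerate(semis):
        basis[2 * idx : 2 * idx + 2, j] = tangents[idx]
    if be_matrix is None:
        # U'U = I (unit tangents on disjoint points): per-point projection
        t = -(basis.T @ residual)
    else:
        b2 = np.kron(be_matrix, np.eye(2))
        lhs = basis.T @ b2 @ basis
        rhs = basis.T @ (b2 @ residual)
        try:
            t = -np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular sliding system; applying 1e-10 ridge", stacklevel=2)
            t = -np.linalg.solve(lhs + RIDGE * np.eye(m), rhs)
    slid = config.copy()
    for j, idx in enumerate(semis):
        slid[idx] += t[j] * tangents[idx]
    return slid


def _objective(aligned: AlignedSet, mode: str) -> float:
    if mode == "bending_energy":
        be = bending_energy_matrix(aligned.consensus)
        return float(
            sum(bending_energy(be, cfg - aligned.consensus) for cfg in aligned.aligned)
        )
    return float(np.sum((aligned.aligned - aligned.consensus[None]) ** 2))


def slide_semilandmarks(
    configs: "list[np.ndarray] | np.ndarray",
    template: EarTemplate,
    mode: str = "bending_energy",
    max_outer_iters: int = 5,
    tol: float = 1e-6,
) -> SlideResult:
    """Alternate GPA and tangential sliding of the template's semilandmarks.

    Returns the slid, re-aligned configurations together with the objective
    value after the initial GPA and after each accepted outer iteration.
    """
    if mode not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding mode {mode!r}")
    aligned = gpa(configs)
    history = [_objective(aligned, mode)]
    for _ in range(max_outer_iters):
        be = bending_energy_matrix(aligned.consensus) if mode == "bending_energy" else None
        slid = np.stack(
            [_slide_one(cfg, aligned.consensus, template, be) for cfg in aligned.aligned]
        )
        candidate = gpa(slid)
        value = _objective(candidate, mode)
        if value > history[-1] + 1e-12:
            break  # re-superimposition undid the gain; keep the previous state
        aligned = candidate
        improvement = history[-1] - value
        history.append(value)
        if improvement < tol:
            break
    return SlideResult(aligned=aligned, objective_history=history, mode=mode)
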