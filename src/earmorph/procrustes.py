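"""Pairwise and generalized Procrustes superimposition.

All superimpositions are rotation-only (determinant +1): reflection is never
allowed to enter silently, because the fluctuating-asymmetry index depends on
the left/right difference that a reflection would erase. Left ears are mapped
to the right-ear frame by the explicit reflection in
:func:`reflect_to_reference_side` before any alignment.

Shapes are compared in the full-Procrustes sense: every configuration is
centred and scaled to unit centroid size, so only shape (not size) remains —
the photographs the pipeline models are uncalibrated and carry no size
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EarLandmarks, GeometryError


def _center(config: np.ndarray) -> np.ndarray:
    return config - config.mean(axis=0)


def center_and_scale(config: np.ndarray) -> np.ndarray:
    """Translate to centroid origin and scale to unit centroid size."""
    config = np.asarray(config, dtype=float)
    centered = _center(config)
    size = np.linalg.norm(centered)
    if size < 1e-12:
        raise GeometryError("degenerate configuration: zero centroid size")
    return centered / size

def optimal_rotation(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||target @ R - reference||.

    Both inputs are assumed centred. The reflection branch of the orthogonal
    Procrustes solution is excluded by flipping the smallest singular vector.
    """
    u, _, vt = np.linalg.svd(target.T @ reference)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, d])
    return u @ flip @ vt


def align_pair(reference: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Superimpose *target* on *reference* by similarity transform.

    The reference is centred and scaled to unit centroid size; the target is
    translated, scaled and rotated (no reflection) to minimize the summed
    squared distance to it. Returns the fitted target and the minimized
    root-sum-of-squares (full Procrustes) distance.
    """
    ref = center_and_scale(np.asarray(reference, dtype=float))
    tgt = _center(np.asarray(target, dtype=float))
    size = np.linalg.norm(tgt)
    if size < 1e-12:
        raise GeometryError("degenerate configuration: zero centroid size")
    tgt = tgt / size
    rot = optimal_rotation(ref, tgt)
    rotated = tgt @ rot
    # optimal scale for unit-norm configurations: beta = <ref, rotated>
    beta = float(np.sum(ref * rotated))
    fitted = beta * rotated
    distance = float(np.linalg.norm(ref - fitted))
    return fitted, distance


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    return align_pair(a, b)[1]


def reflect_to_reference_side(landmarks: EarLandmarks) -> EarLandmarks:
    """Mirror left ears about the vertical axis into the right-ear frame.

    Right ears pass through unchanged (the operation is idempotent on them);
    point order is preserved, so the template still applies. The returned
    landmarks are tagged ``side="right"``.
    """
    if landmarks.side == "right":
        return landmarks
    pts = landmarks.points.copy()
    pts[:, 0] = -pts[:, 0]
    return EarLandmarks(points=pts, side="right", template=landmarks.template)


@dataclass
class AlignedSet:
    """GPA output: aligned unit-size configurations and their consensus."""

    aligned: np.ndarray  # (n, p, 2)
    consensus: np.ndarray  # (p, 2), unit centroid size
    iterations: int
    final_change: float

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def flattened(self) -> np.ndarray:
        """(n, 2p) view with coordinates ordered x0,y0,x1,y1,..."""
        return self.aligned.reshape(self.n, -1)


def gpa(
    configs: "list[np.ndarray] | np.ndarray",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedSet:
    """Generalized Procrustes analysis of >= 2 configurations.

    Each configuration is centred and scaled to unit centroid size, rotated
    to the current consensus, and the consensus (rescaled to unit size) is
    recomputed; iteration stops when the consensus moves by less than *tol*
    or after *max_iter* rounds.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("gpa requires at least 2 configurations of equal point count")
    scaled = np.stack([center_and_scale(c) for c in arr])
    consensus = center_and_scale(scaled[0])
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(scaled.shape[0]):
            scaled[i] = scaled[i] @ optimal_rotation(consensus, scaled[i])
        new_consensus = center_and_scale(scaled.mean(axis=0))
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            break
    return AlignedSet(
        aligned=scaled, consensus=consensus, iterations=iterations, final_change=change
    )
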