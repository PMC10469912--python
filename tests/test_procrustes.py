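"""Pairwise and generalized Procrustes: invariances and independent oracles."""

import numpy as np
import pytest

from earmorph import (
    EarLandmarks,
    GeometryError,
    align_pair,
    gpa,
    procrustes_distance,
    reflect_to_reference_side,
)
from conftest import random_similarity


def complex_regression_distance(reference, target):
    """Closed-form full Procrustes distance via complex least squares.

    Representing 2D points as complex numbers, fitting target onto the
    centred unit-size reference by a complex coefficient (rotation + scale)
    plus a complex intercept (translation) is an ordinary linear least
    squares problem; its residual norm is the Procrustes distance. Complex
    multiplication cannot produce a reflection, matching the rotation-only
    convention.
    """
    ref = np.asarray(reference, dtype=float)
    refc = ref[:, 0] + 1j * ref[:, 1]
    refc = refc - refc.mean()
    refc = refc / np.linalg.norm(refc)
    tgt = np.asarray(target, dtype=float)
    tgtc = tgt[:, 0] + 1j * tgt[:, 1]
    design = np.column_stack([tgtc, np.ones_like(tgtc)])
    coef, *_ = np.linalg.lstsq(design, refc, rcond=None)
    return float(np.linalg.norm(refc - design @ coef))


def test_identical_configurations_have_zero_distance(base_shape):
    _, dist = align_pair(base_shape, base_shape)
    assert dist < 1e-12


def test_similarity_transform_invariance(base_shape):
    rng = np.random.default_rng(1)
    angle = np.deg2rad(37.0)
    c, s = np.cos(angle), np.sin(angle)
    transformed = 2.5 * base_shape @ np.array([[c, -s], [s, c]]).T + [40.0, -13.0]
    _, dist = align_pair(base_shape, transformed)
    assert dist < 1e-10


@pytest.mark.parametrize("n_points", [4, 10, 41])
def test_pairwise_distance_matches_complex_regression_oracle(n_points):
    rng = np.random.default_rng(7)
    for _ in range(30):
        ref = rng.normal(size=(n_points, 2))
        tgt = rng.normal(size=(n_points, 2))
        _, dist = align_pair(ref, tgt)
        assert dist == pytest.approx(complex_regression_distance(ref, tgt), abs=1e-10)


def test_reflection_is_never_applied(base_shape):
    mirrored = base_shape * [-1.0, 1.0]
    _, dist = align_pair(base_shape, mirrored)
    assert dist > 0.05  # a reflecting fit would give ~0


def test_degenerate_configuration_raises(base_shape):
    with pytest.raises(GeometryError):
        align_pair(base_shape, np.ones((41, 2)))


def test_reflect_right_is_identity_and_left_is_involution(base_shape, template):
    right = EarLandmarks(points=base_shape, side="right", template=template)
    assert reflect_to_reference_side(right) is right

    left = EarLandmarks(points=base_shape, side="left", template=template)
    once = reflect_to_reference_side(left)
    assert once.side == "right"
    twice_pts = once.points.copy()
    twice_pts[:, 0] = -twice_pts[:, 0]
    np.testing.assert_allclose(twice_pts, base_shape, atol=1e-12)


def test_left_ear_matches_its_true_mirror_after_reflection(base_shape, template):
    mirror = base_shape.copy()
    mirror[:, 0] = 300.0 - mirror[:, 0]
    left = EarLandmarks(points=mirror, side="left", template=template)
    reflected = reflect_to_reference_side(left)
    assert procrustes_distance(base_shape, reflected.points) < 1e-10


def test_gpa_aligns_copies_of_one_shape(base_shape):
    rng = np.random.default_rng(3)
    configs = np.stack([random_similarity(rng, base_shape) for _ in range(8)])
    result = gpa(configs)
    for cfg in result.aligned:
        np.testing.assert_allclose(cfg, result.aligned[0], atol=1e-8)
    # AlignedSet invariants
    for cfg in result.aligned:
        assert np.linalg.norm(cfg.mean(axis=0)) < 1e-8
        assert np.linalg.norm(cfg - cfg.mean(axis=0)) == pytest.approx(1.0, abs=1e-8)


def test_gpa_is_equivariant_under_input_order(base_shape):
    rng = np.random.default_rng(4)
    configs = np.stack(
        [random_similarity(rng, base_shape + rng.normal(0, 3, base_shape.shape))
         for _ in range(6)]
    )
    perm = np.array([3, 1, 5, 0, 4, 2])
    a = gpa(configs)
    b = gpa(configs[perm])
    # consensus agrees up to a global rotation
    assert procrustes_distance(a.consensus, b.consensus) < 1e-8
    dist_a = np.linalg.norm(a.aligned[:, None] - a.aligned[None], axis=(2, 3))
    dist_b = np.linalg.norm(b.aligned[perm][:, None] - b.aligned[perm][None], axis=(2, 3))
    np.testing.assert_allclose(dist_a, dist_b, atol=1e-8)


def test_two_shape_consensus_matches_grid_search_oracle():
    """For two triangles, GPA must match brute-force rotation minimization."""
    tri1 = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
    tri2 = np.array([[0.0, 0.5], [3.0, 1.0], [0.5, 4.0]])

    def unit(c):
        c = c - c.mean(axis=0)
        return c / np.linalg.norm(c)

    x1, x2 = unit(tri1), unit(tri2)
    best = (np.inf, None)
    for theta in np.arange(0.0, 2 * np.pi, 1e-4):
        c, s = np.cos(theta), np.sin(theta)
        rot = x2 @ np.array([[c, -s], [s, c]]).T
        mean = unit((x1 + rot) / 2.0)
        objective = np.sum((x1 - mean) ** 2) + np.sum((rot - mean) ** 2)
        if objective < best[0]:
            best = (objective, mean)
    result = gpa(np.stack([tri1, tri2]))
    assert procrustes_distance(result.consensus, best[1]) < 1e-3
    achieved = sum(np.sum((cfg - result.consensus) ** 2) for cfg in result.aligned)
    assert achieved <= best[0] + 1e-6


def test_gpa_requires_two_configurations(base_shape):
    with pytest.raises(ValueError):
        gpa(base_shape[None])
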