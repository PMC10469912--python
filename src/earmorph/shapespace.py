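"""Shape PCA over Procrustes coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import AlignedSet, align_pair


@dataclass
class ShapeSpace:
    """Principal-component decomposition of aligned shape coordinates.

    ``loadings`` are orthonormal axes over the flattened Procrustes
    coordinates (columns, one per component); ``variance_fractions`` sum to 1
    over all components and are non-increasing; ``k`` is the smallest number
    of leading components whose cumulative variance fraction reaches the
    target (default 90%); ``scores`` holds the per-ear coordinates on those
    retained components.
    """

    mean: np.ndarray  # (2p,)
    loadings: np.ndarray  # (2p, m), columns orthonormal
    eigenvalues: np.ndarray  # (m,)
    variance_fractions: np.ndarray  # (m,)
    k: int
    scores: np.ndarray  # (n, k)
    variance_target: float

    def transform(self, configs: np.ndarray) -> np.ndarray:
        """Scores of already-aligned (n, p, 2) configurations on the retained axes."""
        flat = np.asarray(configs, dtype=float).reshape(len(configs), -1)
        return (flat - self.mean) @ self.loadings[:, : self.k]

    def transform_full(self, configs: np.ndarray) -> np.ndarray:
        flat = np.asarray(configs, dtype=float).reshape(len(configs), -1)
        return (flat - self.mean) @ self.loadings


def shape_pca(aligned: AlignedSet, variance_target: float = 0.90) -> ShapeSpace:
    """Eigendecomposition of the covariance of flattened aligned coordinates.

    Requires at least 3 configurations. Components are ordered by
    non-increasing explained variance; the retained count is the smallest k
    with cumulative variance fraction >= *variance_target*.
    """
    if aligned.n < 3:
        raise ValueError("shape PCA requires at least 3 configurations")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    flat = aligned.flattened()
    mean = flat.mean(axis=0)
    centered = flat - mean
    # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (aligned.n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("zero total shape variance")
    fractions = eigenvalues / total
    cumulative = np.cumsum(fractions)
    k = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    k = min(k, len(eigenvalues))
    loadings = vt.T
    scores = centered @ loadings[:, :k]
    return ShapeSpace(
        mean=mean,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        k=k,
        scores=scores,
        variance_target=variance_target,
    )


def align_to_consensus(consensus: np.ndarray, configs: np.ndarray) -> np.ndarray:
    """Superimpose new configurations onto a frozen consensus.

    Used to carry validation ears into a training shape space: each
    configuration is fitted to the consensus by ordinary (pairwise)
    Procrustes superimposition and can then be projected with
    :meth:`ShapeSpace.transform`.
    """
    return np.stack([align_pair(consensus, cfg)[0] for cfg in configs])
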