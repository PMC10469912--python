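"""UMAP embedding of residual features for visualization."""

from __future__ import annotations

import warnings

import numpy as np


def umap_embed(
    features: np.ndarray,
    k: int = 15,
    metric: str = "cosine",
    min_dist: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """2D UMAP embedding (neighbourhood size k, cosine metric by default).

    ``min_dist`` is the effective minimal distance between embedded points.
    If fewer than k+1 rows are available, k is reduced with a warning.
    Deterministic for a given seed (single-threaded).
    """
    import umap  # deferred: numba compilation makes this import expensive

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need at least 3 rows to embed")
    if x.shape[0] < k + 1:
        k = max(2, x.shape[0] - 1)
        warnings.warn(f"fewer rows than k+1; reducing k to {k}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=k,
            n_components=2,
            metric=metric,
            min_dist=min_dist,
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(x)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return np.asarray(coords, dtype=float)
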