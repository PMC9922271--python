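"""Turn a consensus (meta-)distance matrix into a 2-D meta-visualization.

The meta-distance is generally asymmetric (each row was weighted by its own
sample's eigenscores), so it is first symmetrized as ``M + M^T`` and then fed
to an embedding method that accepts precomputed distances: UMAP (good for
cluster structure), kernel PCA (smooth manifolds; the distance matrix is
turned into a Gaussian kernel with the median-distance bandwidth) or t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MetaDistance

__all__ = ["MetaVisualization", "symmetrize", "render_meta", "scatter"]

SUPPORTED_METHODS = ("umap", "kpca", "tsne")


@dataclass
class MetaVisualization:
    """2-D coordinates rendered from a meta-distance."""

    coordinates: np.ndarray
    sample_ids: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def symmetrize(meta: MetaDistance | np.ndarray) -> np.ndarray:
    """M + M^T: symmetric, zero diagonal."""
    M = meta.values if isinstance(meta, MetaDistance) else np.asarray(meta, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got {M.shape}")
    return M + M.T


def _gaussian_kernel_from_distances(D: np.ndarray) -> np.ndarray:
    off = ~np.eye(D.shape[0], dtype=bool)
    h = np.median(D[off][D[off] > 0]) if np.any(D[off] > 0) else 1.0
    return np.exp(-(D**2) / (2.0 * h * h))


def render_meta(
    meta: MetaDistance,
    method: str = "umap",
    params: dict | None = None,
    seed: int = 0,
) -> MetaVisualization:
    """Render 2-D coordinates from a meta-distance.

    Deterministic given (method, params, seed).  Methods without a
    precomputed-distance mode raise with the supported list.
    """
    if method not in SUPPORTED_METHODS:
        raise ValueError(
            f"method {method!r} does not support precomputed distances here; "
            f"supported methods: {', '.join(SUPPORTED_METHODS)}"
        )
    params = dict(params or {})
    M = np.asarray(meta.values, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("meta-distance has non-finite entries")
    D = symmetrize(meta)
    n = D.shape[0]

    if method == "kpca":
        from sklearn.decomposition import KernelPCA

        K = _gaussian_kernel_from_distances(D)
        coords = KernelPCA(
            n_components=2, kernel="precomputed", random_state=seed, **params
        ).fit_transform(K)
    elif method == "umap":
        from umap import UMAP

        params.setdefault("n_neighbors", min(15, n - 2))
        coords = UMAP(
            n_components=2, metric="precomputed", random_state=seed, **params
        ).fit_transform(D)
    else:  # tsne
        from sklearn.manifold import TSNE

        params.setdefault("perplexity", min(30.0, (n - 1) / 3.0))
        coords = TSNE(
            n_components=2, metric="precomputed", init="random",
            random_state=seed, **params
        ).fit_transform(D)
    return MetaVisualization(
        np.asarray(coords, dtype=float), meta.sample_ids, method, params, seed
    )


def scatter(viz: MetaVisualization, labels=None, ax=None, **kwargs):
    """Minimal scatter-plot helper for a rendered meta-visualization."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = viz.coordinates
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=8, **kwargs)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(xy[m, 0], xy[m, 1], s=8, label=str(lab), **kwargs)
        ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"meta-visualization ({viz.method})")
    return ax
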