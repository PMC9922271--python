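"""Registry of candidate-visualization adapters.

Each candidate is a named 2-D embedding of the data produced by an external
dimension-reduction implementation (scikit-learn, umap-learn), except Sammon's
mapping, which no installed library provides and is implemented here with the
classic pseudo-Newton iteration.

The default registry holds 16 candidates from 12 base methods — PCA, metric
MDS, non-metric MDS, Sammon, LLE, Hessian LLE, LTSA, isomap, kernel PCA,
Laplacian eigenmaps, UMAP and t-SNE — with two parameter settings each for the
four most tuning-sensitive methods (kPCA, isomap, UMAP, t-SNE).  Parameter
choices are package defaults: each library's default plus one perturbed
setting.  Neighbour-count and perplexity parameters are clamped to valid
values for small n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import EmbeddingSet

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSpec",
    "CandidateError",
    "run_candidate",
    "run_registry",
    "default_registry",
    "BASE_METHODS",
    "sammon",
]

BASE_METHODS = (
    "pca",
    "mds",
    "imds",
    "sammon",
    "lle",
    "hlle",
    "ltsa",
    "isomap",
    "kpca",
    "leim",
    "umap",
    "tsne",
)


class CandidateError(RuntimeError):
    """An external embedding method failed; carries the candidate name."""


@dataclass
class CandidateSpec:
    """One candidate: a base method, its parameters, and a seed."""

    name: str
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in BASE_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {BASE_METHODS}"
            )


def sammon(
    data: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
    alpha: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Sammon's nonlinear mapping to 2-D.

    Minimizes the Sammon stress sum_{i<j} (d_ij - D_ij)^2 / D_ij (D = input
    distances, d = embedding distances) by the classic diagonal-Newton descent
    with step factor ``alpha``, initialized from the first two principal
    components.  Deterministic for a given input.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    D = squareform(pdist(X))
    # guard zero input distances so the 1/D weights stay finite
    off = ~np.eye(n, dtype=bool)
    eps = max(D[off].min(), 1e-12) if np.any(D[off] > 0) else 1e-12
    D = np.where(off & (D < eps), eps, D)
    c = D[off].sum() / 2.0

    Y = PCA(n_components=2, random_state=seed).fit_transform(X)
    scale = D[off].mean() / max(squareform(pdist(Y))[off].mean(), 1e-12)
    Y = Y * scale

    prev = np.inf
    for _ in range(max_iter):
        diff = Y[:, None, :] - Y[None, :, :]  # (n, n, 2)
        d = np.sqrt((diff**2).sum(-1))
        d[~off] = 1.0
        d = np.maximum(d, 1e-12)
        delta = D - d
        stress = (delta[off] ** 2 / D[off]).sum() / (2.0 * c)
        if prev - stress < tol * max(prev, 1.0):
            break
        prev = stress
        w = np.zeros_like(D)
        w[off] = 1.0 / (D[off] * d[off])
        grad = -2.0 / c * np.einsum("ij,ijq->iq", w * delta, diff)
        ratio = np.zeros_like(D)
        ratio[off] = 1.0 + delta[off] / d[off]
        hess = -2.0 / c * (
            (w * delta).sum(axis=1)[:, None]
            - np.einsum("ij,ijq->iq", w * ratio / d, diff**2)
        )
        Y = Y - alpha * grad / np.maximum(np.abs(hess), 1e-12)
    return Y


def _median_heuristic(data: np.ndarray) -> float:
    d = pdist(data)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(med)


def _clamp_neighbors(k: int, n: int) -> int:
    return int(min(k, n - 2)) if n > 3 else 2


def run_candidate(data: np.ndarray, spec: CandidateSpec) -> np.ndarray:
    """Produce the n x 2 embedding for one candidate spec.

    Deterministic given ``spec.seed`` for stochastic methods; failures are
    wrapped in :class:`CandidateError` carrying the candidate name.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected an n x p data matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix has non-finite entries")
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    p = dict(spec.params)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _dispatch(X, spec.method, p, spec.seed)
    except Exception as exc:  # noqa: BLE001 - wrapped with context
        raise CandidateError(f"candidate {spec.name!r} ({spec.method}) failed: {exc}") from exc


def _dispatch(X: np.ndarray, method: str, p: dict, seed: int) -> np.ndarray:
    n = X.shape[0]
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed, **p).fit_transform(X)
    if method == "mds":
        from sklearn.manifold import MDS

        p.setdefault("n_init", 2)
        p.setdefault("max_iter", 150)
        return MDS(
            n_components=2, random_state=seed, normalized_stress=False, **p
        ).fit_transform(X)
    if method == "imds":
        from sklearn.manifold import MDS

        p.setdefault("n_init", 1)
        p.setdefault("max_iter", 150)
        return MDS(
            n_components=2, metric=False, random_state=seed,
            normalized_stress=True, **p
        ).fit_transform(X)
    if method == "sammon":
        return sammon(X, seed=seed, **p)
    if method in ("lle", "hlle", "ltsa"):
        from sklearn.manifold import LocallyLinearEmbedding

        lle_method = {"lle": "standard", "hlle": "hessian", "ltsa": "ltsa"}[method]
        k = _clamp_neighbors(p.pop("n_neighbors", 15), n)
        if lle_method in ("hessian", "ltsa"):
            k = max(k, 6)  # hessian/ltsa need n_neighbors > 5 for 2 components
        return LocallyLinearEmbedding(
            n_components=2, n_neighbors=k, method=lle_method,
            eigen_solver="dense", random_state=seed, **p
        ).fit_transform(X)
    if method == "isomap":
        from sklearn.manifold import Isomap

        k = _clamp_neighbors(p.pop("n_neighbors", 10), n)
        return Isomap(n_components=2, n_neighbors=k, **p).fit_transform(X)
    if method == "kpca":
        from sklearn.decomposition import KernelPCA

        scale = p.pop("bandwidth_scale", 1.0)
        h = scale * _median_heuristic(X)
        return KernelPCA(
            n_components=2, kernel="rbf", gamma=1.0 / (2.0 * h * h),
            random_state=seed, **p
        ).fit_transform(X)
    if method == "leim":
        from sklearn.manifold import SpectralEmbedding

        k = _clamp_neighbors(p.pop("n_neighbors", 15), n)
        return SpectralEmbedding(
            n_components=2, n_neighbors=k, random_state=seed, **p
        ).fit_transform(X)
    if method == "umap":
        from umap import UMAP

        k = max(_clamp_neighbors(p.pop("n_neighbors", 15), n), 2)
        return UMAP(
            n_components=2, n_neighbors=k, random_state=seed, **p
        ).fit_transform(X)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perp = min(p.pop("perplexity", 30.0), (n - 1) / 3.0)
        return TSNE(
            n_components=2, perplexity=perp, init="pca", random_state=seed, **p
        ).fit_transform(X)
    raise ValueError(f"unknown method {method!r}")


def default_registry(seed: int = 0) -> list[CandidateSpec]:
    """The 16-candidate default registry (12 base methods; kPCA, isomap, UMAP
    and t-SNE each appear with two parameter settings)."""
    return [
        CandidateSpec("pca", "pca", {}, seed),
        CandidateSpec("mds", "mds", {}, seed),
        CandidateSpec("imds", "imds", {}, seed),
        CandidateSpec("sammon", "sammon", {}, seed),
        CandidateSpec("lle", "lle", {"n_neighbors": 15}, seed),
        CandidateSpec("hlle", "hlle", {"n_neighbors": 15}, seed),
        CandidateSpec("ltsa", "ltsa", {"n_neighbors": 15}, seed),
        CandidateSpec("isomap1", "isomap", {"n_neighbors": 10}, seed),
        CandidateSpec("isomap2", "isomap", {"n_neighbors": 30}, seed),
        CandidateSpec("kpca1", "kpca", {"bandwidth_scale": 1.0}, seed),
        CandidateSpec("kpca2", "kpca", {"bandwidth_scale": 3.0}, seed),
        CandidateSpec("leim", "leim", {"n_neighbors": 15}, seed),
        CandidateSpec("umap1", "umap", {"n_neighbors": 15}, seed),
        CandidateSpec("umap2", "umap", {"n_neighbors": 100}, seed),
        CandidateSpec("tsne1", "tsne", {"perplexity": 30.0}, seed),
        CandidateSpec("tsne2", "tsne", {"perplexity": 100.0}, seed),
    ]


def run_registry(
    data: np.ndarray,
    specs: list[CandidateSpec] | None = None,
    sample_ids=None,
    strict: bool = False,
    seed: int | None = None,
) -> EmbeddingSet:
    """Run every candidate spec on the data and collect an EmbeddingSet.

    In non-strict mode a failing candidate is skipped with a logged warning;
    in strict mode the wrapped error propagates.
    """
    if specs is None:
        specs = default_registry(seed=seed if seed is not None else 0)
    elif seed is not None:
        specs = [CandidateSpec(s.name, s.method, dict(s.params), seed) for s in specs]
    embeddings = {}
    for spec in specs:
        try:
            embeddings[spec.name] = run_candidate(data, spec)
        except CandidateError as exc:
            if strict:
                raise
            logger.warning("skipping failed candidate: %s", exc)
    if not embeddings:
        raise CandidateError("all candidates failed")
    return EmbeddingSet(embeddings, sample_ids=sample_ids)
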