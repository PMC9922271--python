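"""Ground-truth concordance and structure-preservation metrics.

With synthetic data the noiseless signals give a reference normalized
distance matrix P*; the *true local concordance* of candidate k at sample i
is the inner product of the candidate's i-th unit distance row with the
reference's.  Eigenscores estimate exactly these vectors (up to scale), so
their per-sample cosine against the truth measures how well the spectral
assessment works; the mean concordance of the meta-distance rows against the
reference measures how well the combination works.

For real-data-style structure checks the module provides Silhouette scores on
normalized distance matrices, circular/linear sample orderings from a 2-D
embedding, and Kendall's tau for cyclic and linear orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import kendalltau

from .core import (
    AlignmentError,
    EigenscoreTable,
    MetaDistance,
    NormalizedDistanceMatrix,
    _check_same_ids,
    normalize_distances,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceReport",
    "true_concordance",
    "concordance_table",
    "eigenscore_truth_cosine",
    "candidate_mean_concordance",
    "meta_truth_concordance",
    "concordance_report",
    "silhouette_normalized",
    "circular_order",
    "kendall_cyclic",
    "linear_order",
    "kendall_linear",
    "make_adversarial",
]


@dataclass
class ConcordanceReport:
    """Bundle of truth-referenced quality measures for one ensemble."""

    candidates: list[str]
    truth: np.ndarray  # s_i vectors, (n, K)
    eigenscore_truth_cosines: np.ndarray  # (n,)
    candidate_mean: np.ndarray  # (K,)
    meta_per_sample: np.ndarray  # (n,)
    meta_mean: float

    @property
    def mean_cosine(self) -> float:
        return float(np.nanmean(self.eigenscore_truth_cosines))


def _reference_matrix(reference) -> NormalizedDistanceMatrix:
    if isinstance(reference, NormalizedDistanceMatrix):
        return reference
    return normalize_distances(np.asarray(reference, dtype=float))


def concordance_table(
    reference: NormalizedDistanceMatrix,
    matrices: Sequence[NormalizedDistanceMatrix],
) -> np.ndarray:
    """(n, K) matrix of true local concordances: entry (i, k) is the inner
    product of candidate k's i-th unit distance row with the reference's."""
    ref = _reference_matrix(reference)
    _check_same_ids([ref, *matrices])
    R = np.stack([m.values for m in matrices])  # (K, n, n)
    return np.einsum("kij,ij->ik", R, ref.values)


def true_concordance(
    i: int,
    reference: NormalizedDistanceMatrix,
    matrices: Sequence[NormalizedDistanceMatrix],
) -> np.ndarray:
    """Length-K true local concordance vector s_i at sample i."""
    ref = _reference_matrix(reference)
    ids = _check_same_ids([ref, *matrices])
    if not 0 <= i < len(ids):
        raise IndexError(f"sample index {i} out of range")
    return np.array([m.values[i] @ ref.values[i] for m in matrices])


def eigenscore_truth_cosine(scores: EigenscoreTable, truth: np.ndarray) -> np.ndarray:
    """Per-sample cosine between eigenscores and true concordance vectors.

    Samples whose truth vector has zero norm are flagged missing (NaN).
    """
    S = scores.values
    T = np.asarray(truth, dtype=float)
    if S.shape != T.shape:
        raise ValueError(f"shape mismatch: eigenscores {S.shape}, truth {T.shape}")
    tn = np.linalg.norm(T, axis=1)
    sn = np.linalg.norm(S, axis=1)
    zero = (tn == 0) | (sn == 0)
    if np.any(zero):
        logger.warning("%d sample(s) have zero-norm vectors; cosine set to NaN",
                       int(zero.sum()))
    denom = np.where(zero, 1.0, sn * tn)
    cos = np.einsum("ik,ik->i", S, T) / denom
    return np.where(zero, np.nan, cos)


def candidate_mean_concordance(
    reference: NormalizedDistanceMatrix,
    matrices: Sequence[NormalizedDistanceMatrix],
) -> np.ndarray:
    """Mean over samples of each candidate's true local concordance."""
    return concordance_table(reference, matrices).mean(axis=0)


def meta_truth_concordance(
    meta: MetaDistance, reference
) -> tuple[np.ndarray, float]:
    """Per-sample cosine of meta-distance rows against the reference rows
    (meta rows are renormalized for the cosine only), and their mean."""
    ref = _reference_matrix(reference)
    _check_same_ids([ref, MetaDistance(meta.values, meta.sample_ids)])
    norms = np.linalg.norm(meta.values, axis=1)
    zero = norms == 0
    if np.any(zero):
        logger.warning("%d zero meta row(s) flagged", int(zero.sum()))
    denom = np.where(zero, 1.0, norms)
    cos = np.einsum("ij,ij->i", meta.values, ref.values) / denom
    cos = np.where(zero, np.nan, cos)
    return cos, float(np.nanmean(cos))


def concordance_report(
    reference,
    matrices: Sequence[NormalizedDistanceMatrix],
    scores: EigenscoreTable,
    meta: MetaDistance,
) -> ConcordanceReport:
    ref = _reference_matrix(reference)
    truth = concordance_table(ref, matrices)
    cosines = eigenscore_truth_cosine(scores, truth)
    per_sample, mean = meta_truth_concordance(meta, ref)
    return ConcordanceReport(
        candidates=list(scores.candidates),
        truth=truth,
        eigenscore_truth_cosines=cosines,
        candidate_mean=truth.mean(axis=0),
        meta_per_sample=per_sample,
        meta_mean=mean,
    )


def silhouette_normalized(
    matrix: NormalizedDistanceMatrix | MetaDistance | np.ndarray, labels
) -> np.ndarray:
    """Per-sample Silhouette values using a normalized (or meta) distance
    matrix, symmetrized by averaging, as the dissimilarity.

    Singleton classes score 0 (the usual convention); a single class raises.
    """
    from sklearn.metrics import silhouette_samples

    V = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two label classes")
    D = (V + V.T) / 2.0
    return silhouette_samples(D, labels, metric="precomputed")


def circular_order(embedding: np.ndarray) -> np.ndarray:
    """Rank of each sample by angular position on the unit circle after
    mean-centering the 2-D coordinates (radius is discarded).

    Points landing exactly on the center are jittered by 1e-9 (logged).
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected an n x 2 embedding, got {X.shape}")
    C = X - X.mean(axis=0)
    at_origin = np.all(C == 0, axis=1)
    if np.any(at_origin):
        logger.warning("%d point(s) at the center; jittering by 1e-9",
                       int(at_origin.sum()))
        rng = np.random.default_rng(0)
        C[at_origin] = 1e-9 * rng.standard_normal((int(at_origin.sum()), 2))
    ang = np.arctan2(C[:, 1], C[:, 0])
    return np.argsort(np.argsort(ang, kind="stable"), kind="stable")


def kendall_cyclic(inferred_order, true_order) -> float:
    """Kendall's tau between two cyclic orders, maximized over cyclic shifts
    of either order and both directions (a cycle has no origin or
    orientation), so the statistic is exactly invariant under cyclic shifts
    of both arguments."""
    a = np.asarray(inferred_order, dtype=float)
    b = np.asarray(true_order, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    best = -1.0
    for direction in (a, (n - 1) - a):
        for s_b in range(n):
            bb = (b + s_b) % n
            for s_a in range(n):
                tau = kendalltau((direction + s_a) % n, bb).statistic
                if tau > best:
                    best = float(tau)
    return best


def linear_order(embedding: np.ndarray) -> np.ndarray:
    """Rank of each sample by projection on the first principal axis of the
    2-D coordinates (the direction explaining the most variance)."""
    from sklearn.decomposition import PCA

    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected an n x 2 embedding, got {X.shape}")
    C = X - X.mean(axis=0)
    if np.allclose(C, 0):
        raise ValueError("zero-variance embedding has no principal axis")
    proj = PCA(n_components=1, svd_solver="full").fit_transform(C)[:, 0]
    return np.argsort(np.argsort(proj, kind="stable"), kind="stable")


def kendall_linear(inferred_order, true_order) -> float:
    """Kendall's tau between a projection order and the truth, maximized over
    the two axis orientations (a principal axis has no preferred sign)."""
    a = np.asarray(inferred_order, dtype=float)
    b = np.asarray(true_order, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    tau = kendalltau(a, b).statistic
    return float(max(tau, -tau))


def make_adversarial(
    n_or_matrix, seed: int = 0
) -> NormalizedDistanceMatrix:
    """Normalized distance matrix of a random (data-independent) 2-D Gaussian
    embedding — an uninformative 'adversarial' candidate whose rows carry no
    signal about any particular reference."""
    if isinstance(n_or_matrix, NormalizedDistanceMatrix):
        n = n_or_matrix.n_samples
        ids = n_or_matrix.sample_ids
    elif isinstance(n_or_matrix, (int, np.integer)):
        n = int(n_or_matrix)
        ids = None
    else:
        raise TypeError("expected a sample count or a NormalizedDistanceMatrix")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    return normalize_distances(X, sample_ids=ids)
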