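"""Spectral scoring and combination of candidate visualizations.

A *candidate visualization* is a 2-D embedding of the same ``n`` samples
produced by some dimension-reduction method.  Each candidate is summarized by
its normalized pairwise-distance matrix: the Euclidean distance matrix with
every row rescaled to unit length, which makes the summary invariant to
translation, rotation, reflection and positive rescaling of the embedding.

For each sample ``i`` the rows of the ``K`` candidates' normalized distance
matrices form ``K`` unit vectors in R^n; their Gram matrix ``G_i`` measures the
local pairwise concordance of the candidates around sample ``i``.  The
*eigenscores* of sample ``i`` are the entrywise absolute value of the leading
eigenvector of ``G_i`` — equivalently the first principal-component loadings of
the stacked n-by-K row matrix.  The *meta-distance* row for sample ``i`` is the
eigenscore-weighted sum of the candidates' rows, a consensus distance profile
that down-weights locally discordant candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateRowError",
    "AlignmentError",
    "EmbeddingSet",
    "NormalizedDistanceMatrix",
    "SimilarityMatrix",
    "EigenscoreTable",
    "MetaDistance",
    "normalize_distances",
    "similarity_matrix",
    "eigenscores_at",
    "eigenscores",
    "meta_distance",
    "naive_meta_distance",
]

#: relative tolerance accepted when validating user-supplied unit rows
#: (text round-trips lose a few digits)
UNIT_ROW_RTOL = 1e-6

#: near-tie threshold for the top two eigenvalues of a K x K Gram matrix,
#: scaled by K (the trace of G, hence the scale of its spectrum, grows with K)
EIGENVALUE_TIE_RTOL = 1e-9


class DegenerateRowError(ValueError):
    """All points of an embedding coincide with one sample, so its distance
    row has zero norm and cannot be normalized."""


class AlignmentError(ValueError):
    """Inputs do not share the same ordered sample index."""


def _as_ids(sample_ids: Sequence | None, n: int) -> np.ndarray:
    if sample_ids is None:
        return np.array([str(i) for i in range(n)], dtype=object)
    ids = np.asarray(sample_ids, dtype=object)
    if ids.shape != (n,):
        raise ValueError(f"expected {n} sample ids, got shape {ids.shape}")
    if len(set(ids.tolist())) != n:
        raise ValueError("sample ids must be unique")
    return ids


def _check_same_ids(matrices: Sequence["NormalizedDistanceMatrix"]) -> np.ndarray:
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if not np.array_equal(m.sample_ids, ids):
            raise AlignmentError("normalized distance matrices have mismatched sample ids")
    return ids


@dataclass
class EmbeddingSet:
    """K named 2-D embeddings over a shared ordered sample index."""

    sample_ids: np.ndarray
    embeddings: dict[str, np.ndarray]

    def __init__(self, embeddings: Mapping[str, np.ndarray], sample_ids: Sequence | None = None):
        if len(embeddings) < 1:
            raise ValueError("need at least one candidate embedding")
        emb = {}
        n = None
        for name, X in embeddings.items():
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError(f"candidate {name!r}: expected an n x 2 array, got {X.shape}")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"candidate {name!r} has non-finite coordinates")
            if n is None:
                n = X.shape[0]
            elif X.shape[0] != n:
                raise AlignmentError(
                    f"candidate {name!r} has {X.shape[0]} samples, expected {n}"
                )
            emb[str(name)] = X
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        self.embeddings = emb
        self.sample_ids = _as_ids(sample_ids, n)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_candidates(self) -> int:
        return len(self.embeddings)

    @property
    def names(self) -> list[str]:
        return list(self.embeddings)

    def normalized_distances(
        self, on_degenerate: str = "raise"
    ) -> dict[str, "NormalizedDistanceMatrix"]:
        """Normalized pairwise-distance matrix of every candidate."""
        return {
            name: normalize_distances(
                X, sample_ids=self.sample_ids, on_degenerate=on_degenerate, name=name
            )
            for name, X in self.embeddings.items()
        }


@dataclass
class NormalizedDistanceMatrix:
    """n x n nonnegative distance matrix with unit-norm rows and zero diagonal.

    Rows flagged in ``degenerate_rows`` are identically zero (all samples
    coincided with that sample in the source embedding) and contribute nothing
    downstream.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    degenerate_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @classmethod
    def from_values(cls, values: np.ndarray, sample_ids: Sequence | None = None):
        """Validate a user-supplied (e.g. file-loaded) matrix.

        Row norms must be 1 within ``UNIT_ROW_RTOL`` (or exactly 0 for a
        degenerate row); nothing is clipped.
        """
        V = np.asarray(values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"expected a square matrix, got {V.shape}")
        if not np.all(np.isfinite(V)):
            raise ValueError("matrix has non-finite entries")
        if np.any(V < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.abs(np.diag(V)) > 1e-12):
            raise ValueError("distance matrix has a nonzero diagonal")
        norms = np.linalg.norm(V, axis=1)
        degenerate = np.flatnonzero(norms == 0)
        live = norms > 0
        if np.any(np.abs(norms[live] - 1.0) > UNIT_ROW_RTOL):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"row {bad} has norm {norms[bad]:.8g}; rows must have unit Euclidean norm"
            )
        return cls(V, _as_ids(sample_ids, V.shape[0]), degenerate)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityMatrix:
    """K x K Gram matrix of the candidates' unit distance rows at one sample."""

    values: np.ndarray
    sample_index: int = -1

    def __post_init__(self):
        G = np.asarray(self.values, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError(f"expected a square matrix, got {G.shape}")
        self.values = G


@dataclass
class EigenscoreTable:
    """n x K per-sample, per-candidate eigenscores; rows are nonnegative unit
    vectors."""

    values: np.ndarray
    candidates: list[str]
    sample_ids: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.values.shape[1]


@dataclass
class MetaDistance:
    """Eigenscore-weighted consensus distance matrix (generally asymmetric)."""

    values: np.ndarray
    sample_ids: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def normalize_distances(
    embedding: np.ndarray,
    sample_ids: Sequence | None = None,
    on_degenerate: str = "raise",
    name: str | None = None,
) -> NormalizedDistanceMatrix:
    """Euclidean pairwise-distance matrix with rows rescaled to unit norm.

    Parameters
    ----------
    embedding : (n, d) array
        Coordinates; any finite dimension d >= 1 is accepted (the noiseless
        p-dimensional reference uses the same construction).
    on_degenerate : {"raise", "zero"}
        A row whose norm is zero (all points coincide with that sample) either
        raises :class:`DegenerateRowError` or is replaced by the zero vector
        and recorded in ``degenerate_rows``.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D coordinate array, got shape {X.shape}")
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding has non-finite coordinates")
    if on_degenerate not in ("raise", "zero"):
        raise ValueError(f"unknown degenerate-row policy {on_degenerate!r}")

    ids = _as_ids(sample_ids, n)
    # exact pairwise distances; no nearest-neighbour approximation
    diff = X[:, None, :] - X[None, :, :]
    P = np.sqrt(np.einsum("ijd,ijd->ij", diff, diff))
    np.fill_diagonal(P, 0.0)
    norms = np.linalg.norm(P, axis=1)
    degenerate = np.flatnonzero(norms == 0)
    if degenerate.size:
        if on_degenerate == "raise":
            i = int(degenerate[0])
            who = f" of candidate {name!r}" if name else ""
            raise DegenerateRowError(
                f"distance row{who} for sample {ids[i]!r} has zero norm: "
                "all points coincide with it"
            )
        logger.warning(
            "%s: %d degenerate distance row(s) replaced by zeros",
            name or "normalize_distances",
            degenerate.size,
        )
    safe = np.where(norms > 0, norms, 1.0)
    return NormalizedDistanceMatrix(P / safe[:, None], ids, degenerate)


def similarity_matrix(
    i: int, matrices: Sequence[NormalizedDistanceMatrix]
) -> SimilarityMatrix:
    """Gram matrix of the K candidates' i-th normalized distance rows."""
    ids = _check_same_ids(matrices)
    n = len(ids)
    if not 0 <= i < n:
        raise IndexError(f"sample index {i} out of range for n={n}")
    rows = np.stack([m.values[i] for m in matrices])  # (K, n)
    return SimilarityMatrix(rows @ rows.T, sample_index=i)


def _leading_abs_eigenvector(G: np.ndarray) -> np.ndarray:
    """|leading eigenvector| of a symmetric matrix, with a deterministic
    near-tie rule.

    If the top two eigenvalues are within ``EIGENVALUE_TIE_RTOL * K`` of each
    other, the tied eigenvectors are compared by the l1 norm of their absolute
    values (larger wins), then lexicographically — so degenerate inputs (e.g.
    two mutually orthogonal candidates) still give a reproducible answer.
    """
    K = G.shape[0]
    w, V = np.linalg.eigh(G)  # ascending eigenvalues
    tol = EIGENVALUE_TIE_RTOL * K
    tied = np.flatnonzero(w >= w[-1] - tol)
    if tied.size > 1:
        cand = [np.abs(V[:, j]) for j in tied]
        u = max(cand, key=lambda v: (np.sum(v), tuple(v)))
    else:
        u = np.abs(V[:, -1])
    norm = np.linalg.norm(u)
    if norm == 0:  # all-zero G (every candidate degenerate at this sample)
        return np.zeros(K)
    return u / norm


def eigenscores_at(G: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Eigenscores for one sample: entrywise absolute value of the unit
    eigenvector for the largest eigenvalue of ``G``.

    The theory behind the absolute-value convention assumes a leading
    eigenvector of a single sign (guaranteed by Perron-Frobenius when all
    entries of ``G`` are positive); genuinely mixed signs are kept —
    abs is still applied — but logged.
    """
    Gv = G.values if isinstance(G, SimilarityMatrix) else np.asarray(G, dtype=float)
    if Gv.ndim != 2 or Gv.shape[0] != Gv.shape[1]:
        raise ValueError(f"expected a square matrix, got {Gv.shape}")
    if Gv.shape[0] == 0:
        raise ValueError("similarity matrix is empty (K = 0)")
    if not np.all(np.isfinite(Gv)):
        raise ValueError("similarity matrix has non-finite entries")
    w, V = np.linalg.eigh(Gv)
    lead = V[:, -1]
    if np.any(lead > 1e-10) and np.any(lead < -1e-10):
        logger.info(
            "leading eigenvector has mixed signs (min %.3g, max %.3g); "
            "taking absolute values",
            lead.min(),
            lead.max(),
        )
    return _leading_abs_eigenvector(Gv)


def eigenscores(
    matrices: Sequence[NormalizedDistanceMatrix],
    candidates: Sequence[str] | None = None,
) -> EigenscoreTable:
    """Per-sample eigenscores for all n samples.

    Row ``i`` equals ``eigenscores_at(similarity_matrix(i, matrices))``; rows
    are computed independently, so the result does not depend on the order in
    which samples are visited.
    """
    ids = _check_same_ids(matrices)
    n = len(ids)
    K = len(matrices)
    names = list(candidates) if candidates is not None else [str(k) for k in range(K)]
    if len(names) != K:
        raise ValueError(f"got {len(names)} candidate names for K={K}")
    R = np.stack([m.values for m in matrices])  # (K, n, n)
    S = np.empty((n, K))
    for i in range(n):
        rows = R[:, i, :]
        S[i] = _leading_abs_eigenvector(rows @ rows.T)
    return EigenscoreTable(S, names, ids)


def meta_distance(
    matrices: Sequence[NormalizedDistanceMatrix], scores: EigenscoreTable
) -> MetaDistance:
    """Eigenscore-weighted consensus: row i = sum_k s_{i,k} * P^(k) row i.

    The unit-norm eigenscore vector is applied directly; rows are *not*
    renormalized afterwards.
    """
    ids = _check_same_ids(matrices)
    n = len(ids)
    K = len(matrices)
    if scores.values.shape != (n, K):
        raise ValueError(
            f"eigenscore table shape {scores.values.shape} does not match "
            f"(n, K) = {(n, K)}"
        )
    R = np.stack([m.values for m in matrices])  # (K, n, n)
    M = np.einsum("ik,kij->ij", scores.values, R)
    return MetaDistance(M, ids)


def naive_meta_distance(matrices: Sequence[NormalizedDistanceMatrix]) -> MetaDistance:
    """Uniform-weight consensus: the plain average of the K normalized
    distance matrices."""
    ids = _check_same_ids(matrices)
    R = np.stack([m.values for m in matrices])
    return MetaDistance(R.mean(axis=0), ids)
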