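"""Core spectral machinery: normalized distances, Gram matrices, eigenscores,
meta-distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaviz import core
from metaviz.core import (
    DegenerateRowError,
    EmbeddingSet,
    eigenscores,
    eigenscores_at,
    meta_distance,
    naive_meta_distance,
    normalize_distances,
    similarity_matrix,
)


def power_iteration_abs(G, iters=5000, tol=1e-14):
    """Independent oracle: |leading eigenvector| by plain power iteration."""
    rng = np.random.default_rng(0)
    v = rng.standard_normal(G.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(iters):
        w = G @ v + 1e-3 * v  # shift keeps convergence for PSD G with small gap
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    return np.abs(v)


def random_psd(rng, k):
    B = rng.standard_normal((k, k + 3))
    G = B @ B.T
    return G / np.max(np.abs(G))


class TestNormalizeDistances:
    def test_two_points_row_normalization_removes_separation(self):
        for d in (0.1, 1.0, 37.0):
            P = normalize_distances(np.array([[0.0, 0.0], [d, 0.0]]))
            np.testing.assert_array_equal(P.values, [[0.0, 1.0], [1.0, 0.0]])

    def test_hand_computed_row(self):
        P = normalize_distances(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]]))
        np.testing.assert_allclose(
            P.values[0], [0.0, 1 / np.sqrt(5), 2 / np.sqrt(5)], atol=1e-15
        )

    def test_rigid_motion_and_scale_invariance(self, rng):
        X = rng.standard_normal((12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        F = np.diag([1.0, -1.0])  # reflection
        Y = 3.7 * (X @ R.T @ F) + np.array([5.0, -2.0])
        np.testing.assert_allclose(
            normalize_distances(X).values, normalize_distances(Y).values, atol=1e-10
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(1e-3, 1e3),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_invariance_property(self, seed, scale, angle):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 2))
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        Y = scale * X @ R.T + rng.standard_normal(2)
        np.testing.assert_allclose(
            normalize_distances(X).values, normalize_distances(Y).values, atol=1e-9
        )

    def test_rows_unit_norm_zero_diag_nonneg(self, rng):
        P = normalize_distances(rng.standard_normal((20, 2)))
        assert np.all(P.values >= 0)
        np.testing.assert_allclose(np.linalg.norm(P.values, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(np.diag(P.values), 0.0)

    def test_degenerate_rows_raise_naming_sample(self):
        X = np.zeros((4, 2))  # every point identical
        with pytest.raises(DegenerateRowError, match="s0"):
            normalize_distances(X, sample_ids=["s0", "s1", "s2", "s3"])
        # partial coincidence is fine: only ALL-coincident embeddings degenerate
        X2 = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        normalize_distances(X2)

    def test_degenerate_zero_policy_zeroes_contribution(self, rng):
        good = normalize_distances(rng.standard_normal((6, 2)))
        flat = normalize_distances(np.zeros((6, 2)), on_degenerate="zero")
        assert flat.degenerate_rows.size == 6
        assert np.all(flat.values == 0)
        S = eigenscores([good, good, flat], ["a", "b", "flat"])
        np.testing.assert_allclose(S.values[:, 2], 0.0, atol=1e-12)
        np.testing.assert_allclose(S.values[:, 0], 1 / np.sqrt(2), atol=1e-12)

    def test_user_supplied_matrix_validation(self, rng):
        V = normalize_distances(rng.standard_normal((5, 2))).values
        core.NormalizedDistanceMatrix.from_values(V)  # round-trip ok
        with pytest.raises(ValueError, match="unit"):
            core.NormalizedDistanceMatrix.from_values(V * 1.5)


class TestSimilarityMatrix:
    def test_identical_candidates_all_ones(self, rng):
        P = normalize_distances(rng.standard_normal((7, 2)))
        G = similarity_matrix(2, [P, P, P])
        np.testing.assert_allclose(G.values, 1.0, atol=1e-12)

    def test_unit_diagonal(self, fast_matrices):
        _, mats = fast_matrices
        G = similarity_matrix(5, mats)
        np.testing.assert_allclose(np.diag(G.values), 1.0, atol=1e-12)

    def test_toy_off_diagonal(self, toy_matrices):
        A, B = toy_matrices
        G = similarity_matrix(0, [A, B])
        np.testing.assert_allclose(G.values[0, 1], 3 / np.sqrt(10), atol=1e-12)

    def test_psd_gram_property(self, fast_matrices, rng):
        _, mats = fast_matrices
        for i in rng.integers(0, mats[0].n_samples, 10):
            G = similarity_matrix(int(i), mats).values
            assert np.min(np.linalg.eigvalsh(G)) >= -1e-10
            assert np.all((G >= -1e-12) & (G <= 1 + 1e-12))

    def test_mismatched_ids_raise(self, rng):
        A = normalize_distances(rng.standard_normal((5, 2)), sample_ids=list("abcde"))
        B = normalize_distances(rng.standard_normal((5, 2)), sample_ids=list("abcdX"))
        with pytest.raises(core.AlignmentError):
            similarity_matrix(0, [A, B])


class TestEigenscoresAt:
    def test_all_ones_gives_uniform(self):
        for k in (2, 3, 7):
            np.testing.assert_allclose(
                eigenscores_at(np.ones((k, k))), 1 / np.sqrt(k), atol=1e-12
            )

    def test_single_candidate(self):
        np.testing.assert_allclose(eigenscores_at(np.array([[1.0]])), [1.0])

    def test_symmetric_2x2(self):
        s = eigenscores_at(np.array([[1.0, 0.5], [0.5, 1.0]]))
        np.testing.assert_allclose(s, [0.70711, 0.70711], atol=1e-5)

    def test_three_candidate_power_iteration(self):
        G = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        np.testing.assert_allclose(eigenscores_at(G), power_iteration_abs(G), atol=1e-8)

    def test_oracle_equivalence_random_psd(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 9))
            G = random_psd(rng, k)
            np.testing.assert_allclose(
                eigenscores_at(G), power_iteration_abs(G), atol=1e-8
            )

    def test_perron_single_sign_on_positive_matrices(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 8))
            B = rng.uniform(0.1, 1.0, (k, 30))
            B /= np.linalg.norm(B, axis=1, keepdims=True)
            G = B @ B.T  # strictly positive Gram matrix
            w, V = np.linalg.eigh(G)
            lead = V[:, -1]
            assert np.all(lead > 0) or np.all(lead < 0)
            np.testing.assert_allclose(eigenscores_at(G), np.abs(lead), atol=1e-12)

    def test_tie_break_deterministic(self):
        G = np.eye(2)  # two orthogonal candidates: fully degenerate spectrum
        s1, s2 = eigenscores_at(G), eigenscores_at(G)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(np.linalg.norm(s1), 1.0, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eigenscores_at(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            eigenscores_at(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestEigenscoreTable:
    def test_identical_candidates_uniform_rows(self, rng):
        P = normalize_distances(rng.standard_normal((8, 2)))
        S = eigenscores([P, P, P, P], list("abcd"))
        np.testing.assert_allclose(S.values, 0.5, atol=1e-12)

    def test_rows_nonnegative_unit_norm(self, fast_matrices):
        names, mats = fast_matrices
        S = eigenscores(mats, names)
        assert np.all(S.values >= 0)
        np.testing.assert_allclose(np.linalg.norm(S.values, axis=1), 1.0, atol=1e-10)

    def test_rows_match_per_sample_computation(self, fast_matrices):
        names, mats = fast_matrices
        S = eigenscores(mats, names)
        for i in (0, 13, 57):
            np.testing.assert_array_equal(
                S.values[i], eigenscores_at(similarity_matrix(i, mats))
            )

    def test_permutation_equivariance(self, rng):
        X1, X2 = rng.standard_normal((2, 9, 2))
        perm = rng.permutation(9)
        mats = [normalize_distances(X) for X in (X1, X2)]
        mats_p = [normalize_distances(X[perm]) for X in (X1, X2)]
        S, Sp = eigenscores(mats), eigenscores(mats_p)
        np.testing.assert_allclose(Sp.values, S.values[perm], atol=1e-12)

    def test_svd_oracle_on_stacked_rows(self, fast_matrices):
        # row i equals |first right singular vector| of the stacked n x K
        # matrix of the candidates' i-th normalized distance rows
        names, mats = fast_matrices
        S = eigenscores(mats, names)
        for i in (3, 40):
            stacked = np.column_stack([m.values[i] for m in mats])
            _, _, Vt = np.linalg.svd(stacked, full_matrices=False)
            np.testing.assert_allclose(S.values[i], np.abs(Vt[0]), atol=1e-8)


class TestMetaDistance:
    def test_single_candidate_pass_through(self, rng):
        P = normalize_distances(rng.standard_normal((6, 2)))
        S = eigenscores([P])
        M = meta_distance([P], S)
        np.testing.assert_allclose(M.values, P.values, atol=1e-12)

    def test_identical_candidates_scale_sqrt_k(self, rng):
        P = normalize_distances(rng.standard_normal((6, 2)))
        M = meta_distance([P] * 4, eigenscores([P] * 4))
        np.testing.assert_allclose(M.values, 2.0 * P.values, atol=1e-12)
        row, cand = M.values[2], P.values[2]
        cos = row @ cand / (np.linalg.norm(row) * np.linalg.norm(cand))
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_toy_weighted_sum(self, toy_matrices):
        A, B = toy_matrices
        S = eigenscores([A, B], ["a", "b"])
        M = meta_distance([A, B], S)
        expected = S.values[:, [0]] * A.values + S.values[:, [1]] * B.values
        np.testing.assert_allclose(M.values, expected, atol=1e-14)

    def test_linearity_invariant(self, fast_matrices):
        names, mats = fast_matrices
        S = eigenscores(mats, names)
        M = meta_distance(mats, S)
        i = 17
        np.testing.assert_allclose(
            M.values[i],
            sum(S.values[i, k] * mats[k].values[i] for k in range(len(mats))),
            atol=1e-12,
        )
        assert np.all(M.values >= 0)
        np.testing.assert_array_equal(np.diag(M.values), 0.0)

    def test_shape_mismatch_raises(self, toy_matrices):
        A, B = toy_matrices
        S = eigenscores([A, B])
        with pytest.raises(ValueError):
            meta_distance([A], S)


class TestNaiveMetaDistance:
    def test_identical_candidates_identity(self, rng):
        P = normalize_distances(rng.standard_normal((6, 2)))
        np.testing.assert_array_equal(naive_meta_distance([P, P]).values, P.values)
        np.testing.assert_allclose(naive_meta_distance([P] * 3).values, P.values,
                                   atol=1e-15)

    def test_single_candidate_pass_through(self, rng):
        P = normalize_distances(rng.standard_normal((6, 2)))
        np.testing.assert_array_equal(naive_meta_distance([P]).values, P.values)

    def test_two_candidate_midpoint(self, toy_matrices):
        A, B = toy_matrices
        np.testing.assert_allclose(
            naive_meta_distance([A, B]).values, (A.values + B.values) / 2, atol=1e-15
        )


class TestEmbeddingSet:
    def test_invariants(self, rng):
        with pytest.raises(ValueError):
            EmbeddingSet({})
        with pytest.raises(core.AlignmentError):
            EmbeddingSet({"a": rng.standard_normal((5, 2)),
                          "b": rng.standard_normal((6, 2))})
        with pytest.raises(ValueError):
            EmbeddingSet({"a": np.full((5, 2), np.nan)})
        with pytest.raises(ValueError):
            EmbeddingSet({"a": rng.standard_normal((2, 2))})
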