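"""Graph construction, Louvain/ECG clustering, and comparison statistics,
validated against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from neuroclass import clustering as gc


def modularity_bruteforce(A, labels, gamma=1.0):
    """O(n^2) double-loop evaluation of Q, independent of the implementation."""
    A = np.asarray(A.todense() if sp.issparse(A) else A, dtype=float)
    n = A.shape[0]
    w = A.sum()
    d = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * d[i] * d[j] / w
    return q / w


def two_cliques(k=5, eps=0.0):
    """Two k-cliques, optionally bridged by one weak edge."""
    n = 2 * k
    A = np.zeros((n, n))
    A[:k, :k] = 1.0
    A[k:, k:] = 1.0
    np.fill_diagonal(A, 0.0)
    if eps:
        A[0, k] = A[k, 0] = eps
    return sp.csr_matrix(A)


class TestPreprocess:
    def test_identical_rows_become_identical_unit_vectors(self):
        X = np.vstack([[1.0, 2.0, 3.0]] * 2 + [[4.0, 0.0, 1.0]])
        Z = gc.preprocess(X)
        assert np.allclose(Z[0], Z[1])
        assert np.allclose(np.linalg.norm(Z, axis=1), 1.0, atol=1e-12)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 4))
        X[:, 2] = 7.0
        Z, dropped = gc.preprocess(X, return_dropped=True)
        assert Z.shape == (10, 3)
        assert list(dropped) == [2]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_unit_norms_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, rng.uniform(0.1, 10), (rng.integers(2, 30), rng.integers(2, 8)))
        Z = gc.preprocess(X)
        assert np.allclose(np.linalg.norm(Z, axis=1), 1.0, atol=1e-9)


class TestModularity:
    def test_matches_bruteforce_on_random_labelings(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = rng.integers(5, 50)
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            if A.sum() == 0:
                continue
            labels = rng.integers(0, 4, n)
            gamma = rng.uniform(0.2, 3.0)
            assert gc.modularity(sp.csr_matrix(A), labels, gamma) == pytest.approx(
                modularity_bruteforce(A, labels, gamma), abs=1e-12)

    def test_single_community_value(self):
        A = two_cliques()
        q = gc.modularity(A, np.zeros(10, dtype=int), 1.0)
        assert q == pytest.approx(modularity_bruteforce(A, np.zeros(10)), abs=1e-12)

    def test_gamma_zero_single_community_optimal(self):
        A = two_cliques(eps=0.5)
        labels_one = np.zeros(10, dtype=int)
        labels_two = np.repeat([0, 1], 5)
        assert gc.modularity(A, labels_one, 0.0) >= gc.modularity(A, labels_two, 0.0)


class TestLouvain:
    def test_two_disconnected_cliques(self):
        res = gc.louvain(two_cliques(), resolution=1.0, seed=0)
        labels = res.labels
        assert np.unique(labels).size == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert res.modularity == pytest.approx(
            modularity_bruteforce(two_cliques(), labels), abs=1e-12)

    def test_reported_q_is_own_evaluation(self):
        # the stored Q must equal the direct evaluation for the returned labels
        rng = np.random.default_rng(2)
        A = rng.random((30, 30)) * (rng.random((30, 30)) < 0.2)
        A = sp.csr_matrix((A + A.T) / 2)
        A.setdiag(0)
        res = gc.louvain(A, resolution=1.0, seed=3)
        assert res.modularity == pytest.approx(
            modularity_bruteforce(A, res.labels), abs=1e-12)


class TestSelectResolution:
    def test_separated_clusters_recovered_with_zero_sd(self):
        rng = np.random.default_rng(4)
        centers = rng.normal(0, 6, (4, 8))
        X = np.vstack([c + rng.normal(0, 1, (60, 8)) for c in centers])
        graph = gc.build_graph(gc.preprocess(X), n_neighbors=15, seed=5)
        gamma, table = gc.select_resolution(graph, n_repeats=8, seed=6)
        row = table[table.resolution == gamma].iloc[0]
        assert row.k_sd == 0.0
        assert row.k_mean == 4.0

    def test_single_value_grid(self):
        graph = two_cliques(eps=0.2)
        gamma, table = gc.select_resolution(graph, resolutions=[1.5],
                                            n_repeats=3, seed=7)
        assert gamma == 1.5
        assert len(table) == 1

    def test_gamma_zero_excluded_from_argmax(self):
        graph = two_cliques(eps=0.2)
        gamma, table = gc.select_resolution(graph, resolutions=[0.0, 1.0],
                                            n_repeats=3, seed=8)
        assert gamma == 1.0  # gamma=0 always modularity 1 yet is degenerate


class TestECG:
    def test_two_clique_consensus_matches_louvain(self):
        A = two_cliques(eps=0.2)
        plain = gc.louvain(A, seed=9)
        cons = gc.ecg(A, k=8, w_star=0.05, seed=9)
        assert gc.compare_labelings(plain.labels, cons.labels)["ARI"] == 1.0

    def test_identical_partitions_weights_equal_one(self):
        # if all k level-1 partitions agree, 2-core co-cluster edges get
        # weight w* + (1 - w*) * 1 = 1
        A = two_cliques()  # disconnected cliques: every run finds the cliques
        res = gc.ecg(A, k=6, w_star=0.3, seed=10)
        parts = res.meta["level1_partitions"]
        assert all(
            gc.compare_labelings(parts[0], parts[i])["ARI"] == 1.0
            for i in range(len(parts))
        )
        assert np.unique(res.labels).size == 2

    def test_w_star_bounds(self):
        with pytest.raises(ValueError):
            gc.ecg(two_cliques(), w_star=1.5)


class TestComparisons:
    def test_cluster_likelihood_enumeration_oracle(self):
        # contingency by hand: a-cluster 1 = {0,1} -> b {1,2}; 2 = {2,3} -> {1,1}
        P = gc.cluster_likelihood([1, 1, 2, 2], [1, 2, 1, 1])
        assert np.allclose(P.to_numpy(), [[0.5, 0.5], [1.0, 0.0]])

    def test_identical_labelings_identity_pattern(self):
        P = gc.cluster_likelihood([0, 1, 2, 0], [0, 1, 2, 0])
        assert np.allclose(P.to_numpy(), np.eye(3))

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_likelihood_rows_sum_to_one(self, pairs):
        a, b = zip(*pairs)
        P = gc.cluster_likelihood(np.array(a), np.array(b))
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_ari_ami_trivials(self):
        same = gc.compare_labelings([0, 0, 1, 1], [5, 5, 9, 9])
        assert same == {"ARI": 1.0, "AMI": 1.0}
        rng = np.random.default_rng(11)
        a, b = rng.integers(0, 5, 1000), rng.integers(0, 5, 1000)
        null = gc.compare_labelings(a, b)
        assert abs(null["ARI"]) < 0.05

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 4, 200)
        perm = np.array([2, 3, 0, 1])
        orig = gc.compare_labelings(a, b)
        relabeled = gc.compare_labelings(perm[a], b)
        assert relabeled["ARI"] == pytest.approx(orig["ARI"], abs=1e-12)
        assert relabeled["AMI"] == pytest.approx(orig["AMI"], abs=1e-9)


class TestCosineSummary:
    def test_all_identical_vectors(self):
        X = np.tile([1.0, 0.0], (6, 1))
        out = gc.cosine_summary(X, [0, 0, 0, 1, 1, 1])
        assert np.allclose(out.to_numpy(), 1.0)

    def test_orthogonal_groups_cross_block_zero(self):
        X = np.vstack([[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3)
        out = gc.cosine_summary(X, [0] * 3 + [1] * 3)
        assert out.loc[0, 1] == pytest.approx(0.0)
        assert out.loc[0, 0] == pytest.approx(1.0)

    def test_hand_computed_four_vector_example(self):
        X = np.array([[1.0, 0.0], [0.6, 0.8], [0.0, 1.0], [0.8, 0.6]])
        labels = np.array([0, 0, 1, 1])
        S = X @ X.T
        # direct double-loop oracle
        within0 = S[0, 1]
        within1 = S[2, 3]
        cross = np.mean([S[0, 2], S[0, 3], S[1, 2], S[1, 3]])
        out = gc.cosine_summary(X, labels)
        assert out.loc[0, 0] == pytest.approx(within0, abs=1e-12)
        assert out.loc[1, 1] == pytest.approx(within1, abs=1e-12)
        assert out.loc[0, 1] == pytest.approx(cross, abs=1e-12)

    def test_singleton_within_block_flagged_nan(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.6, 0.8]])
        out = gc.cosine_summary(X, [0, 1, 1])
        assert np.isnan(out.loc[0, 0])

    def test_cross_dataset_blocks(self):
        Xa = np.array([[1.0, 0.0], [0.0, 1.0]])
        Xb = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gc.cosine_summary(Xa, [0, 1], Xb, [0, 1])
        assert out.loc[0, 0] == 1.0 and out.loc[0, 1] == 0.0


class TestSimilarityGroups:
    def test_set_sizes_from_combinatorics(self):
        # nE=3, nI=2 -> within sizes C(3,2)=3 and C(2,2)=1, cross 3*2=6
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (5, 4))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        groups = gc.similarity_groups(X, np.array(["E", "E", "E", "I", "I"]))
        assert groups["E-E"].size == 3
        assert groups["I-I"].size == 1
        assert groups["E-I"].size == 6

    def test_identical_vectors_all_ones(self):
        X = np.tile([0.6, 0.8], (5, 1))
        groups = gc.similarity_groups(X, np.array(["E"] * 3 + ["I"] * 2))
        for v in groups.values():
            assert np.allclose(v, 1.0)

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(14)
        X = rng.normal(0, 1, (7, 3))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        labels = np.array(["E", "I", "E", "I", "E", "E", "I"])
        groups = gc.similarity_groups(X, labels)
        e = np.flatnonzero(labels == "E")
        ee = sorted(float(X[i] @ X[j]) for a, i in enumerate(e) for j in e[a + 1:])
        assert sorted(groups["E-E"].tolist()) == pytest.approx(ee)


class TestBuildGraph:
    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            gc.build_graph(np.zeros((10, 3)), n_neighbors=20)

    def test_symmetry_zero_diagonal_determinism(self):
        rng = np.random.default_rng(15)
        X = gc.preprocess(rng.normal(0, 1, (40, 6)))
        g1 = gc.build_graph(X, n_neighbors=10, seed=16)
        g2 = gc.build_graph(X, n_neighbors=10, seed=16)
        assert (g1.adjacency != g2.adjacency).nnz == 0
        assert abs(g1.adjacency - g1.adjacency.T).max() < 1e-12
        assert g1.adjacency.diagonal().sum() == 0.0
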