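"""kNN-graph construction, Louvain clustering with stability-based resolution
selection, ECG consensus, and cluster-comparison statistics.

The clustering substrate is the fuzzy simplicial kNN graph built by UMAP's
first stage (the 2-D embedding is used only for plotting).  Louvain community
detection is delegated to networkx; the reported modularity is always
re-evaluated here directly from its definition

    Q = (1/w) sum_ij [A_ij - gamma d_i d_j / w] delta(c_i, c_j),

with w = sum_ij A_ij and d the (symmetrized) node strength, independent of the
optimizer's internal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix
from sklearn.utils import check_random_state

__all__ = [
    "NeighborGraph",
    "ClusterResult",
    "preprocess",
    "build_graph",
    "louvain",
    "modularity",
    "select_resolution",
    "ecg",
    "cluster_likelihood",
    "compare_labelings",
    "cosine_summary",
    "similarity_groups",
]


@dataclass
class NeighborGraph:
    adjacency: sp.csr_matrix  # symmetric, zero diagonal, non-negative
    n_neighbors: int
    min_dist: float
    seed: int
    embedding: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_scipy_sparse_array(self.adjacency)


@dataclass
class ClusterResult:
    labels: np.ndarray
    resolution: float
    modularity: float
    stability: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return np.unique(self.labels).size


def preprocess(X: np.ndarray, return_dropped: bool = False):
    """Standardize columns (population SD) then scale each row to unit L2 norm.

    Zero-variance columns are dropped (they carry no information and would
    z-score to NaN)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.isfinite(X).all():
        raise ValueError("missing values must be imputed before preprocessing")
    sd = X.std(axis=0)
    dropped = np.flatnonzero(sd == 0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out = Z / norms
    if return_dropped:
        return out, dropped
    return out


def build_graph(
    X: np.ndarray, n_neighbors: int = 20, min_dist: float = 0.1,
    seed: int = 0, embed: bool = False,
) -> NeighborGraph:
    """UMAP fuzzy simplicial kNN graph (symmetrized), optionally with the 2-D
    embedding for plotting.  Deterministic under a fixed seed."""
    from umap.umap_ import fuzzy_simplicial_set, simplicial_set_embedding, find_ab_params

    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {X.shape[0]}"
        )
    rs = check_random_state(seed)
    graph, _, _ = fuzzy_simplicial_set(X, n_neighbors, rs, "euclidean")
    A = sp.csr_matrix(graph)
    A = (A + A.T) / 2.0  # ensure exact symmetry
    A.setdiag(0.0)
    A.eliminate_zeros()
    embedding = None
    if embed:
        a, b = find_ab_params(1.0, min_dist)
        embedding, _ = simplicial_set_embedding(
            X, sp.coo_matrix(A), 2, 1.0, a, b, 1.0, 5, 200, "spectral",
            check_random_state(seed), "euclidean", {}, False, {}, False,
        )
    return NeighborGraph(adjacency=A, n_neighbors=n_neighbors,
                         min_dist=min_dist, seed=seed, embedding=embedding)


def modularity(adjacency: sp.spmatrix | np.ndarray, labels: np.ndarray,
               resolution: float = 1.0) -> float:
    """Direct evaluation of Q on a symmetric weighted graph.

    The degree-product null term uses the symmetrized strengths (in-degree =
    out-degree on an undirected graph)."""
    A = sp.csr_matrix(adjacency)
    labels = np.asarray(labels)
    w = A.sum()
    if w == 0:
        return 0.0
    strength = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        q += A[np.ix_(idx, idx)].sum() - resolution * strength[idx].sum() ** 2 / w
    return float(q / w)


def _louvain_once(G: nx.Graph, resolution: float, seed) -> np.ndarray:
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(G.number_of_nodes(), dtype=int)
    nodes = {u: i for i, u in enumerate(G.nodes())}
    for c, members in enumerate(comms):
        for u in members:
            labels[nodes[u]] = c
    return labels


def louvain(
    graph: NeighborGraph | sp.spmatrix, resolution: float = 1.0,
    seed: int = 0, n_repeats: int = 1,
) -> ClusterResult:
    """Louvain community detection at resolution gamma; with ``n_repeats`` > 1
    the max-Q run (Q evaluated by :func:`modularity`) is returned."""
    A = graph.adjacency if isinstance(graph, NeighborGraph) else sp.csr_matrix(graph)
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    G = nx.from_scipy_sparse_array(A)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_repeats, 1)):
        labels = _louvain_once(G, resolution, int(rng.integers(2**31)))
        q = modularity(A, labels, resolution=1.0)
        if best is None or q > best[1]:
            best = (labels, q)
    return ClusterResult(labels=best[0], resolution=resolution, modularity=best[1])


def select_resolution(
    graph: NeighborGraph | sp.spmatrix,
    resolutions: np.ndarray | None = None,
    n_repeats: int = 25,
    subsample_frac: float = 0.9,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Stability scan: for each resolution, cluster ``n_repeats`` random
    ``subsample_frac`` node subsamples and record modularity and cluster-count
    statistics; the selected resolution maximizes the mean modularity over
    gamma > 0 (gamma = 0 has a degenerate single-community optimum)."""
    if resolutions is None:
        resolutions = np.arange(0.0, 5.5, 0.5)
    resolutions = np.asarray(list(resolutions), dtype=float)
    if resolutions.size == 0:
        raise ValueError("empty resolution grid")
    A = graph.adjacency if isinstance(graph, NeighborGraph) else sp.csr_matrix(graph)
    n = A.shape[0]
    n_sub = max(int(round(subsample_frac * n)), 2)
    rng = np.random.default_rng(seed)
    rows = []
    for gamma in resolutions:
        qs, ks = [], []
        for _ in range(n_repeats):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            sub = A[np.ix_(idx, idx)]
            G = nx.from_scipy_sparse_array(sub)
            labels = _louvain_once(G, gamma, int(rng.integers(2**31)))
            qs.append(modularity(sub, labels, resolution=gamma))
            ks.append(np.unique(labels).size)
        rows.append({
            "resolution": gamma,
            "q_mean": float(np.mean(qs)), "q_sd": float(np.std(qs)),
            "k_mean": float(np.mean(ks)), "k_sd": float(np.std(ks)),
        })
    table = pd.DataFrame(rows)
    eligible = table[table["resolution"] > 0]
    if eligible.empty:
        eligible = table
    gamma_star = float(eligible.loc[eligible["q_mean"].idxmax(), "resolution"])
    return gamma_star, table


def ecg(
    graph: NeighborGraph | sp.spmatrix, k: int = 16, w_star: float = 0.05,
    seed: int = 0, final_resolution: float = 1.0,
) -> ClusterResult:
    """Ensemble clustering for graphs: k level-1 Louvain partitions reweight
    each edge by its co-clustering frequency (floored at the minimum weight
    w* off the graph's 2-core), then a final Louvain runs on the reweighted
    graph."""
    if not (0.0 < w_star < 1.0):
        raise ValueError("w_star must lie strictly between 0 and 1")
    A = graph.adjacency if isinstance(graph, NeighborGraph) else sp.csr_matrix(graph)
    G = nx.from_scipy_sparse_array(A)
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(k):
        gen = nx.community.louvain_partitions(
            G, weight="weight", resolution=1.0, seed=int(rng.integers(2**31))
        )
        level1 = next(gen)  # first pass of the Louvain algorithm
        lab = np.empty(G.number_of_nodes(), dtype=int)
        nodes = {u: i for i, u in enumerate(G.nodes())}
        for c, members in enumerate(level1):
            for u in members:
                lab[nodes[u]] = c
        partitions.append(lab)
    partitions = np.array(partitions)  # (k, n)

    core = set(nx.k_core(nx.Graph(G), k=2).nodes())
    W = A.tocoo(copy=True)
    new_data = np.empty_like(W.data)
    for e, (u, v) in enumerate(zip(W.row, W.col)):
        if u in core and v in core:
            co = np.mean(partitions[:, u] == partitions[:, v])
            new_data[e] = w_star + (1.0 - w_star) * co
        else:
            new_data[e] = w_star
    W2 = sp.coo_matrix((new_data, (W.row, W.col)), shape=W.shape).tocsr()
    result = louvain(W2, resolution=final_resolution, seed=int(rng.integers(2**31)))
    result.meta.update({"k": k, "w_star": w_star, "level1_partitions": partitions})
    # report modularity on the original graph
    result.modularity = modularity(A, result.labels, resolution=final_resolution)
    return result


def cluster_likelihood(labels_a: np.ndarray, labels_b: np.ndarray) -> pd.DataFrame:
    """Conditional probability matrix P(j | i) = C_ij / sum_j C_ij from the
    contingency table of two labelings of the same neurons."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same neurons")
    C = contingency_matrix(labels_a, labels_b)
    totals = C.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("empty cluster row in contingency matrix")
    return pd.DataFrame(
        C / totals, index=np.unique(labels_a), columns=np.unique(labels_b)
    )


def compare_labelings(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Chance-adjusted agreement between two labelings (ARI and AMI)."""
    return {
        "ARI": float(adjusted_rand_score(labels_a, labels_b)),
        "AMI": float(adjusted_mutual_info_score(labels_a, labels_b)),
    }


def cosine_summary(
    X_a: np.ndarray, labels_a: np.ndarray,
    X_b: np.ndarray | None = None, labels_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean pairwise cosine similarity for each (cluster_a, cluster_b) block.

    Rows must already have unit L2 norm.  With a single dataset/labeling, the
    diagonal (same-cluster) blocks average only the strict upper triangle;
    singleton same-cluster blocks yield NaN."""
    X_a = np.asarray(X_a, dtype=float)
    same = X_b is None
    if same:
        X_b, labels_b = X_a, labels_a
    X_b = np.asarray(X_b, dtype=float)
    S = X_a @ X_b.T
    cl_a = np.unique(labels_a)
    cl_b = np.unique(labels_b)
    out = np.full((cl_a.size, cl_b.size), np.nan)
    for i, ca in enumerate(cl_a):
        ia = np.flatnonzero(np.asarray(labels_a) == ca)
        for j, cb in enumerate(cl_b):
            ib = np.flatnonzero(np.asarray(labels_b) == cb)
            block = S[np.ix_(ia, ib)]
            if same and ca == cb:
                if ia.size < 2:
                    continue  # undefined within-mean for singleton block
                iu = np.triu_indices(ia.size, k=1)
                out[i, j] = block[iu].mean()
            else:
                out[i, j] = block.mean()
    return pd.DataFrame(out, index=cl_a, columns=cl_b)


def similarity_groups(X: np.ndarray, class_labels: np.ndarray) -> dict:
    """Cosine-similarity value sets for within-excitatory (E-E), within-
    inhibitory (I-I) and cross (E-I) comparisons.

    Within-class sets take the strict upper triangle of the class block; the
    cross set takes all E x I pairs.  Rows must have unit norm.  Downstream
    omnibus tests (Welch's ANOVA etc.) are left to standard libraries."""
    X = np.asarray(X, dtype=float)
    class_labels = np.asarray(class_labels)
    classes = np.unique(class_labels)
    if classes.size != 2:
        raise ValueError("expected exactly two classes")
    e_idx = np.flatnonzero(class_labels == classes[0])
    i_idx = np.flatnonzero(class_labels == classes[1])
    S = X @ X.T
    out = {}
    for name, idx in ((f"{classes[0]}-{classes[0]}", e_idx),
                      (f"{classes[1]}-{classes[1]}", i_idx)):
        if idx.size < 2:
            out[name] = np.empty(0)
        else:
            iu = np.triu_indices(idx.size, k=1)
            out[name] = S[np.ix_(idx, idx)][iu]
    out[f"{classes[0]}-{classes[1]}"] = S[np.ix_(e_idx, i_idx)].ravel()
    return out
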