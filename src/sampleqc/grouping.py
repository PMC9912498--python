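"""Sample grouping: pairwise MMD distances, kNN graph, Louvain groups, embeddings.

Large experiments rarely share one QC-metric distribution across all
samples.  Before any mixture model is fitted, samples are grouped so that
each group's samples follow approximately the same multivariate metric
distribution.  Distributional distance between two samples is measured by
the (unbiased) maximum mean discrepancy under a Gaussian RBF kernel, which
is sensitive to differences in means, covariances and higher moments.  The
pairwise distance matrix feeds a kNN graph clustered with Louvain, and 2-D
embeddings (classical MDS, UMAP) of the same matrix let users eyeball batch
effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .core import CellQCTable

logger = logging.getLogger(__name__)

__all__ = [
    "SampleGraph",
    "rbf_kernel",
    "mmd_squared",
    "pairwise_mmd_matrix",
    "cluster_samples",
    "embed_samples",
]

MAD_SCALE = 1.4826  # consistency factor for the Gaussian


@dataclass
class SampleGraph:
    """Pairwise sample distances plus derived grouping artifacts.

    ``mmd`` holds distances (square root of the clamped unbiased squared-MMD
    estimate): symmetric, nonnegative, zero diagonal.
    """

    sample_ids: list[str]
    mmd: np.ndarray
    knn_edges: list[tuple[int, int]] | None = None
    group_labels: np.ndarray | None = None
    embeddings: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        J = len(self.sample_ids)
        self.mmd = np.asarray(self.mmd, dtype=float)
        if self.mmd.shape != (J, J):
            raise ValueError("mmd matrix shape does not match sample_ids")
        if np.max(np.abs(self.mmd - self.mmd.T)) > 1e-12:
            raise ValueError("mmd matrix not symmetric")
        if np.any(np.diag(self.mmd) != 0):
            raise ValueError("mmd diagonal must be exactly zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> dict[int, list[str]]:
        if self.group_labels is None:
            raise ValueError("no group labels: run cluster_samples first")
        out: dict[int, list[str]] = {}
        for s, g in zip(self.sample_ids, self.group_labels):
            out.setdefault(int(g), []).append(s)
        return out


def rbf_kernel(x: np.ndarray, y: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian RBF kernel matrix k(x,y) = exp(-||x-y||^2 / (2 h^2))."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = cdist(x, y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * bandwidth**2))


def mmd_squared(A: np.ndarray, B: np.ndarray, bandwidth: float) -> float:
    """Unbiased U-statistic estimate of squared MMD, clamped at zero.

    MMD^2_u = mean_{i!=j} k(a_i,a_j) + mean_{i!=j} k(b_i,b_j)
              - 2 mean_{i,j} k(a_i,b_j)
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each sample needs >= 2 rows for the unbiased estimator")
    if A.shape[1] != B.shape[1]:
        raise ValueError("samples must share the metric dimension")
    m, n = A.shape[0], B.shape[0]
    Kaa = rbf_kernel(A, A, bandwidth)
    Kbb = rbf_kernel(B, B, bandwidth)
    Kab = rbf_kernel(A, B, bandwidth)
    term_a = (Kaa.sum() - np.trace(Kaa)) / (m * (m - 1))
    term_b = (Kbb.sum() - np.trace(Kbb)) / (n * (n - 1))
    # row sums of k(A,B) and of k(B,A), averaged: both reductions run over
    # contiguous rows in the same element order regardless of argument
    # order, so mmd_squared(A,B) == mmd_squared(B,A) bit-exactly
    rows = Kab.sum(axis=1)
    cols = np.ascontiguousarray(Kab.T).sum(axis=1)
    cross = 0.5 * (rows.sum() + cols.sum()) / (m * n)
    return max(term_a + term_b - 2.0 * cross, 0.0)


def _standardize(X: np.ndarray) -> np.ndarray:
    """Experiment-wide robust standardization: per metric (x - median) / scaled MAD."""
    med = np.median(X, axis=0)
    mad = MAD_SCALE * np.median(np.abs(X - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)  # constant metric: leave centered
    return (X - med) / mad


def pairwise_mmd_matrix(
    table: CellQCTable,
    subsample: int = 500,
    seed: int = 0,
    bandwidth: float | None = None,
) -> SampleGraph:
    """All-pairs MMD distances between samples of a QC table.

    Metrics are robustly standardized experiment-wide so no metric dominates
    the kernel; each sample is subsampled without replacement to at most
    ``subsample`` cells; the kernel bandwidth defaults to the median pairwise
    distance over a pooled seeded subsample (median heuristic).
    """
    X = _standardize(table.values())
    sidx = table.sample_index()
    all_ids = table.sample_ids

    counts = np.bincount(sidx, minlength=len(all_ids))
    excluded = [s for s, c in zip(all_ids, counts) if c < 2]
    if excluded:
        warnings.warn(f"excluding sample(s) with < 2 cells: {excluded}")
    sample_ids = [s for s in all_ids if s not in excluded]
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples with >= 2 cells")

    ss = np.random.SeedSequence([seed, len(sample_ids)])
    children = ss.spawn(len(sample_ids) + 1)
    subs = []
    for j, s in enumerate(sample_ids):
        idx = np.where(sidx == all_ids.index(s))[0]
        rng = np.random.default_rng(children[j])
        if len(idx) > subsample:
            idx = rng.choice(idx, size=subsample, replace=False)
        subs.append(X[np.sort(idx)])

    if bandwidth is None:
        pool = np.vstack(subs)
        rng = np.random.default_rng(children[-1])
        if len(pool) > 1000:
            pool = pool[rng.choice(len(pool), size=1000, replace=False)]
        bandwidth = float(np.median(pdist(pool)))
        if bandwidth <= 0:
            bandwidth = 1.0

    J = len(sample_ids)
    M = np.zeros((J, J))
    for a in range(J):
        for b in range(a + 1, J):
            d = np.sqrt(mmd_squared(subs[a], subs[b], bandwidth))
            M[a, b] = M[b, a] = d
    return SampleGraph(
        sample_ids=sample_ids,
        mmd=M,
        params={"bandwidth": bandwidth, "subsample": subsample, "seed": seed},
        excluded=excluded,
    )


def cluster_samples(
    graph: SampleGraph, k: int | None = None, resolution: float = 1.0, seed: int = 0
) -> SampleGraph:
    """Louvain sample groups on a union-symmetrized kNN graph of the MMD matrix.

    Labels are relabeled 0..G-1 in decreasing group size (ties broken by the
    smallest member index) so outputs are reproducible.
    """
    import networkx as nx

    J = graph.n_samples
    if k is None:
        k = min(5, J - 1)
    if k >= J:
        warnings.warn(f"k={k} >= number of samples {J}; clamping to {J - 1}")
        k = J - 1
    D = graph.mmd.copy()
    np.fill_diagonal(D, np.inf)
    edges = set()
    for a in range(J):
        # stable kNN: argsort is deterministic for ties
        for b in np.argsort(D[a], kind="stable")[:k]:
            edges.add((min(a, int(b)), max(a, int(b))))
    G = nx.Graph()
    G.add_nodes_from(range(J))
    G.add_edges_from(edges)
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(J, dtype=int)
    for g, comm in enumerate(comms):
        for a in comm:
            labels[a] = g
    graph.knn_edges = sorted(edges)
    graph.group_labels = labels
    graph.params.update({"k": k, "resolution": resolution, "louvain_seed": seed})
    logger.info("found %d sample group(s): sizes %s", len(comms), [len(c) for c in comms])
    return graph


def _classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances, top eigenpairs."""
    J = D.shape[0]
    J_c = np.eye(J) - np.ones((J, J)) / J
    B = -0.5 * J_c @ (D**2) @ J_c
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(w)
    if coords.shape[1] < n_components:
        coords = np.pad(coords, ((0, 0), (0, n_components - coords.shape[1])))
    return coords


def embed_samples(graph: SampleGraph, method: str = "mds", seed: int = 0) -> SampleGraph:
    """2-D sample embedding of the MMD matrix (classical MDS or UMAP)."""
    J = graph.n_samples
    if method == "mds":
        if J < 3:
            warnings.warn("fewer than 3 samples: MDS coordinates are degenerate")
        coords = _classical_mds(graph.mmd)
    elif method == "umap":
        import umap

        n_neighbors = max(2, min(15, J - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                metric="precomputed",
                n_neighbors=n_neighbors,
                random_state=seed,
            )
            coords = np.asarray(reducer.fit_transform(graph.mmd), dtype=float)
    else:
        raise ValueError(f"unknown embedding method '{method}'")
    graph.embeddings[method] = coords
    return graph
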