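"""Cell-type-identification backends behind a pluggable registry.

Three procedures are provided, mirroring the common benchmark trio:

* ``kmeans`` — Lloyd k-means on the PCA embedding with k set to the number
  of simulated cell types;
* ``snn_louvain`` — a Seurat-style pipeline: k-nearest-neighbor graph,
  shared-nearest-neighbor (Jaccard) weighting with pruning, Louvain
  modularity clustering, and a bounded resolution search toward a target
  cluster count (Louvain takes no k directly);
* ``mk_spectral`` — a SIMLR-style pipeline: a bank of Gaussian kernels over
  cell-cell distances at several bandwidths, averaged into one similarity,
  followed by normalized spectral clustering.

All backends consume the same preprocessed embedding so comparisons isolate
the clustering step, and all are deterministic given (input, settings, seed).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import igraph as ig
import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterAssignment",
    "BackendSpec",
    "BackendError",
    "preprocess",
    "cluster_kmeans",
    "cluster_snn_louvain",
    "cluster_multikernel_spectral",
    "register_backend",
    "get_backend",
    "list_backends",
    "run_backend",
]

SNN_PRUNE = 1.0 / 15.0  # Jaccard weights below this are dropped
KERNEL_BANDWIDTH_MULTIPLIERS = (0.5, 1.0, 2.0)
KERNEL_NEIGHBOR_FRACTIONS = (0.05, 0.10)
# similarity is restricted to a symmetric kNN mask of this fraction of cells
# (floor 10); keeping the graph sparse is what lets 2%-rare blocks surface
# in the leading eigenvectors instead of being absorbed by large types
KERNEL_MASK_FRACTION = 0.01
RESOLUTION_MAX_STEPS = 20
DEFAULT_N_HVG = 500
DEFAULT_N_PCS = 50


class BackendError(ValueError):
    """Raised for invalid backend inputs or unknown backend names."""


@dataclass
class ClusterAssignment:
    """Predicted cluster id per cell, plus the settings that produced it."""

    labels: np.ndarray
    backend_name: str
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise BackendError("assignment must cover at least one cell")

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass
class BackendSpec:
    """Name plus settings template resolving to a registered backend."""

    backend_name: str
    settings: dict = field(default_factory=dict)


def preprocess(counts, n_hvg: int = DEFAULT_N_HVG, n_pcs: int = DEFAULT_N_PCS,
               normalize: bool = True, target_sum: float = 1e4,
               cell_ids=None) -> np.ndarray:
    """Standard embedding: total-count normalization, log1p, HVG selection,
    per-gene standardization, PCA.

    Parameters
    ----------
    counts
        Genes x cells non-negative matrix (sparse or dense), or a
        LabeledCountMatrix-like object with ``counts`` / ``cell_ids``.
    n_hvg
        Number of highly variable genes retained (dispersion-based ranking
        on the log-normalized data). The default is deliberately tight:
        rare subpopulations are only visible in the embedding when the
        marker genes are not drowned out by noise-variable genes.
    n_pcs
        Target embedding dimensionality; capped at n_cells - 1 and at the
        number of retained genes.

    Returns
    -------
    (n_cells, d) array of principal-component coordinates.
    """
    if hasattr(counts, "counts"):
        if cell_ids is None:
            cell_ids = counts.cell_ids
        counts = counts.counts
    X = counts.T if sparse.issparse(counts) else np.asarray(counts, dtype=float).T
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise BackendError("need at least 2 cells to build an embedding")
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        name = cell_ids[j] if cell_ids is not None else f"column {j}"
        raise BackendError(f"all-zero cell: {name}")

    import scanpy as sc
    from anndata import AnnData

    adata = AnnData(sparse.csr_matrix(X, dtype=np.float32) if sparse.issparse(X)
                    else np.asarray(X, dtype=np.float32))
    if normalize:
        sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    n_hvg_eff = min(n_hvg, n_genes)
    if n_hvg_eff < n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg_eff, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    if sparse.issparse(adata.X):
        adata.X = np.asarray(adata.X.todense())  # scale densifies anyway
    sc.pp.scale(adata, max_value=10)
    d = min(n_pcs, n_cells - 1, adata.n_vars)
    sc.tl.pca(adata, n_comps=d, svd_solver="arpack", random_state=0)
    return np.asarray(adata.obsm["X_pca"], dtype=float)


def cluster_kmeans(embedding: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 10) -> ClusterAssignment:
    """Lloyd k-means with multiple restarts, best inertia kept."""
    embedding = np.asarray(embedding, dtype=float)
    if k < 1:
        raise BackendError("k must be >= 1")
    if k > embedding.shape[0]:
        raise BackendError("k cannot exceed the number of cells")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(embedding)
    return ClusterAssignment(labels=labels, backend_name="kmeans",
                             settings={"k": k, "seed": seed, "n_restarts": n_restarts,
                                       "inertia": float(km.inertia_)})


def _snn_graph(embedding: np.ndarray, k_param: int) -> ig.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets (self
    included), edges below the pruning threshold removed."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_param).fit(embedding)
    knn = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k_param - 1)
    cols = knn[:, : k_param - 1].ravel()
    data = np.ones(rows.size)
    member = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    member = member + sparse.eye(n, format="csr")  # neighbor sets include self
    inter = (member @ member.T).tocoo()
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jaccard = shared / (2 * k_param - shared)
    keep = jaccard >= SNN_PRUNE
    g = ig.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())))
    g.es["weight"] = jaccard[keep].tolist()
    return g


def _louvain(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    _pyrandom.seed(seed)  # igraph's python RNG drives tie-breaking
    part = graph.community_multilevel(weights="weight" if graph.ecount() else None,
                                      resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def cluster_snn_louvain(embedding: np.ndarray, k_param: int, m_target: int,
                        seed: int = 0) -> ClusterAssignment:
    """SNN-graph Louvain clustering with resolution search toward ``m_target``.

    Louvain has no direct cluster-count control, so after an initial run at
    resolution 1 the resolution is bisected (at most ``RESOLUTION_MAX_STEPS``
    evaluations) toward the target count; the best effort is returned and
    the realized count recorded in ``settings``.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k_param < 1 or m_target < 1:
        raise BackendError("k_param and m_target must be >= 1")
    if k_param >= n:
        raise BackendError("k_param must be smaller than the number of cells")
    graph = _snn_graph(embedding, k_param)

    evaluated: dict = {}

    def run(res: float):
        if res not in evaluated:
            labels = _louvain(graph, res, seed)
            evaluated[res] = (labels, int(np.unique(labels).size))
        return evaluated[res]

    labels, found = run(1.0)
    best = (abs(found - m_target), 1.0, labels)
    # widen a geometric bracket (higher resolution -> more clusters), then bisect
    lo = hi = 1.0
    if found < m_target:
        while found < m_target and len(evaluated) < RESOLUTION_MAX_STEPS and hi < 1e4:
            lo, hi = hi, hi * 2.0
            labels, found = run(hi)
            if abs(found - m_target) < best[0]:
                best = (abs(found - m_target), hi, labels)
    elif found > m_target:
        while found > m_target and len(evaluated) < RESOLUTION_MAX_STEPS and lo > 1e-4:
            hi, lo = lo, lo / 2.0
            labels, found = run(lo)
            if abs(found - m_target) < best[0]:
                best = (abs(found - m_target), lo, labels)
    while best[0] > 0 and len(evaluated) < RESOLUTION_MAX_STEPS and hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        labels, found = run(mid)
        if abs(found - m_target) < best[0]:
            best = (abs(found - m_target), mid, labels)
        if found < m_target:
            lo = mid
        elif found > m_target:
            hi = mid
        else:
            break
    _, resolution, labels = best
    return ClusterAssignment(
        labels=labels, backend_name="snn_louvain",
        settings={"k_param": k_param, "m_target": m_target, "seed": seed,
                  "resolution": float(resolution),
                  "realized_cluster_count": int(np.unique(labels).size)})


def _kernel_bank(distances: np.ndarray) -> np.ndarray:
    """Average Gaussian kernels at global and local (k-NN based) bandwidths."""
    n = distances.shape[0]
    offdiag = distances[~np.eye(n, dtype=bool)]
    med = float(np.median(offdiag))
    if med == 0:
        raise BackendError("zero distance matrix")
    d2 = distances ** 2
    kernels = [np.exp(-d2 / (2.0 * (mult * med) ** 2))
               for mult in KERNEL_BANDWIDTH_MULTIPLIERS]
    sorted_d = np.sort(distances, axis=1)
    for frac in KERNEL_NEIGHBOR_FRACTIONS:
        k = max(2, int(round(frac * n)))
        sigma = sorted_d[:, 1:k + 1].mean(axis=1)  # local scale, self excluded
        sigma = np.maximum(sigma, 1e-12)
        denom = np.outer(sigma, sigma)
        kernels.append(np.exp(-d2 / (2.0 * denom)))
    K = np.mean(kernels, axis=0)
    K = 0.5 * (K + K.T)
    # restrict similarity to a symmetric kNN neighborhood graph
    k_mask = max(10, int(round(KERNEL_MASK_FRACTION * n)))
    k_mask = min(k_mask, n - 1)
    nn_idx = np.argpartition(distances, k_mask, axis=1)[:, : k_mask + 1]
    mask = np.zeros_like(K)
    mask[np.repeat(np.arange(n), nn_idx.shape[1]), nn_idx.ravel()] = 1.0
    mask = np.maximum(mask, mask.T)
    return K * mask


def cluster_multikernel_spectral(embedding: np.ndarray, m_target: int,
                                 seed: int = 0) -> ClusterAssignment:
    """Multi-kernel similarity + normalized spectral clustering.

    Gaussian kernels at bandwidths {0.5, 1, 2} x median pairwise distance and
    at local k-NN scales are averaged into one similarity; its normalized
    affinity's top ``m_target`` eigenvectors (signs fixed so the
    largest-magnitude entry is positive) are row-normalized and k-means
    clustered.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if m_target < 2:
        raise BackendError("m_target must be >= 2")
    if m_target > n:
        raise BackendError("m_target cannot exceed the number of cells")
    D = pairwise_distances(embedding)
    K = _kernel_bank(D)
    deg = K.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    A = K * np.outer(inv_sqrt, inv_sqrt)
    v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector for determinism
    _, vecs = eigsh(A, k=m_target, which="LA", v0=v0)
    for j in range(vecs.shape[1]):
        i_max = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    Y = vecs / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=m_target, n_init=10, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(Y)
    return ClusterAssignment(labels=labels, backend_name="mk_spectral",
                             settings={"m_target": m_target, "seed": seed,
                                       "bandwidth_multipliers": list(KERNEL_BANDWIDTH_MULTIPLIERS),
                                       "neighbor_fractions": list(KERNEL_NEIGHBOR_FRACTIONS),
                                       "mask_fraction": KERNEL_MASK_FRACTION})


# ---------------------------------------------------------------------------
# Registry: (embedding, settings, seed) -> ClusterAssignment

_REGISTRY: Dict[str, Callable] = {}


def register_backend(name: str, fn: Callable) -> None:
    """Register a clustering backend under ``name``.

    ``fn`` must accept ``(embedding, settings: dict, seed: int)`` and
    return a :class:`ClusterAssignment`.
    """
    _REGISTRY[name] = fn


def get_backend(name: str) -> Callable:
    if name not in _REGISTRY:
        raise BackendError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def list_backends() -> list:
    return sorted(_REGISTRY)


def run_backend(spec: BackendSpec, embedding: np.ndarray, m_target: int,
                seed: int = 0) -> ClusterAssignment:
    """Resolve ``spec`` and run it; settings fall back to the target cluster
    count where the backend needs one."""
    fn = get_backend(spec.backend_name)
    settings = dict(spec.settings)
    settings.setdefault("m_target", m_target)
    return fn(embedding, settings, seed)


def _kmeans_entry(embedding, settings, seed):
    return cluster_kmeans(embedding, k=settings.get("k", settings["m_target"]),
                          seed=seed, n_restarts=settings.get("n_restarts", 10))


def _snn_entry(embedding, settings, seed):
    return cluster_snn_louvain(embedding,
                               k_param=settings.get("k_param", settings["m_target"]),
                               m_target=settings["m_target"], seed=seed)


def _spectral_entry(embedding, settings, seed):
    return cluster_multikernel_spectral(embedding, m_target=settings["m_target"],
                                        seed=seed)


register_backend("kmeans", _kmeans_entry)
register_backend("snn_louvain", _snn_entry)
register_backend("mk_spectral", _spectral_entry)
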