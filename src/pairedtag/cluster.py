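"""Embedding, neighbor graphs and clustering for the two modalities.

RNA follows the standard single-cell recipe: per-cell depth normalization to
a fixed total, log1p, variable-gene selection, centered/scaled PCA
(components 1-30). The histone modality follows the chromatin recipe:
binarized bin matrix, TF-IDF weighting, truncated SVD (LSI) with the
depth-correlated first component dropped (components 2-30). Each embedding
yields a shared-nearest-neighbor graph; the joint graph blends the two with
a fixed global modality weight (a deliberate simplification of per-cell
weighted-nearest-neighbor integration). Communities come from Louvain
modularity optimization (Leiden available as an alternative backend);
clusters below a minimum size (default 50 cells) are flagged excluded.
Cell types are labelled per cluster from marker-gene z-scores, and clusters
scoring high for several major types are flagged as doublets.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, InputError


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


def normalize_rna(matrix, target_sum: float = 10_000.0) -> sp.csr_matrix:
    """Depth-normalize to ``target_sum`` counts per cell, then log(1 + x)."""
    x = _as_csr(matrix).astype(float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise InputError(f"cell {bad} has zero total counts (QC should have removed it)")
    scale = sp.diags(target_sum / totals)
    out = scale @ x
    out.data = np.log1p(out.data)
    return out


def dispersion_scores(normalized: sp.csr_matrix) -> np.ndarray:
    """Variance-to-mean dispersion per gene on the log-normalized matrix.

    Genes with zero mean score 0. This is the documented selection statistic
    for variable genes: high between-cell variance relative to abundance.
    """
    x = _as_csr(normalized)
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def select_variable_genes(normalized: sp.csr_matrix, n: int = 2_000) -> np.ndarray:
    """Indices of the top-``n`` genes by dispersion, coordinate tie-break."""
    disp = dispersion_scores(normalized)
    n_genes = len(disp)
    if n > n_genes:
        warnings.warn(f"requested {n} variable genes but only {n_genes} present; using all")
        n = n_genes
    order = np.lexsort((np.arange(n_genes), -disp))
    return np.sort(order[:n])


def tfidf(binary: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """TF-IDF weighting of a binarized cell x bin matrix.

    entry(i, j) = log(1 + scale * tf(i, j) * idf(j)) with
    tf(i, j) = x(i, j) / row_sum(i) and idf(j) = n_cells / n_cells_with_bin_j.
    Empty rows or columns are an error (they make tf or idf undefined and
    should have been removed by the upstream filters).
    """
    x = _as_csr(binary).astype(float)
    row = np.asarray(x.sum(axis=1)).ravel()
    col = np.asarray(x.sum(axis=0)).ravel()
    if (row == 0).any():
        raise InputError(f"cell {int(np.flatnonzero(row == 0)[0])} has no nonzero bin")
    if (col == 0).any():
        raise InputError(f"bin {int(np.flatnonzero(col == 0)[0])} is empty in all cells")
    tf = sp.diags(1.0 / row) @ x
    out = (tf @ sp.diags(x.shape[0] / col)).tocsr()
    out.data = np.log1p(scale * out.data)
    return out


@dataclass
class Embedding:
    """cells x components coordinates plus the component range retained."""

    coords: np.ndarray
    method: str
    components: tuple[int, int]  # 1-based inclusive range of retained components


def _fix_signs(coords: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign convention: the largest-magnitude loading is positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            coords[:, k] *= -1
    return coords, loadings


def reduce(matrix, method: str = "pca", n: int = 30, seed: int = 0,
           scale: bool = True) -> Embedding:
    """Dimension reduction: ``pca`` (components 1-n) or ``lsi`` (2-n).

    PCA centers (and by default unit-scales) the input; LSI takes the
    truncated SVD of the TF-IDF matrix and drops the first, depth-correlated
    component. Both are deterministic given the seed and the sign convention
    (largest-magnitude loading positive). ``n`` is clipped to the matrix rank
    with a warning.
    """
    if method not in ("pca", "lsi"):
        raise ConfigurationError(f"unknown reduction {method!r}")
    x = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    max_comp = min(x.shape) - 1
    if n > max_comp:
        warnings.warn(f"n={n} exceeds usable rank {max_comp}; reducing")
        n = max_comp
    if method == "pca":
        x = x - x.mean(axis=0)
        if scale:
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = x / sd
        model = PCA(n_components=n, random_state=seed, svd_solver="full" if min(x.shape) < 1000 else "randomized")
        coords = model.fit_transform(x)
        coords, _ = _fix_signs(coords, model.components_.copy())
        return Embedding(coords, "pca", (1, n))
    model = TruncatedSVD(n_components=n, random_state=seed)
    coords = model.fit_transform(sp.csr_matrix(x))
    coords, _ = _fix_signs(coords, model.components_.copy())
    return Embedding(coords[:, 1:], "lsi", (2, n))


def knn_graph(embedding: Embedding | np.ndarray, k: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph from an embedding.

    Each cell's k nearest Euclidean neighbours (self included) define a
    neighbourhood; the undirected edge weight between two cells is the
    Jaccard overlap of their neighbourhoods, restricted to pairs that appear
    in each other's kNN lists, with weights below ``prune`` dropped.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    if k >= n:
        raise InputError(f"k={k} requires at least k+1={k + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    indices = nn.kneighbors(coords, return_distance=False)  # includes self
    rows = np.repeat(np.arange(n), k + 1)
    memb = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, indices.ravel())), shape=(n, n)
    )
    knn_pairs = memb + memb.T  # restrict SNN to kNN-adjacent pairs
    knn_pairs.setdiag(0)
    knn_pairs.eliminate_zeros()
    inter = (memb @ memb.T).multiply(knn_pairs > 0)
    inter = inter.tocoo()
    union = 2 * (k + 1) - inter.data
    weights = inter.data / union
    graph = sp.coo_matrix((weights, (inter.row, inter.col)), shape=(n, n)).tocsr()
    graph.data[graph.data < prune] = 0.0
    graph.eliminate_zeros()
    graph = graph.maximum(graph.T)  # numerical symmetry
    return graph


def joint_graph(graph_rna: sp.spmatrix, graph_dna: sp.spmatrix,
                weight_rna: float = 0.5) -> sp.csr_matrix:
    """Fixed-weight blend of the two modality graphs on the same cell set.

    weight_rna = 1 returns the RNA graph exactly; 0 the DNA graph. This is a
    documented simplification of per-cell WNN modality weighting.
    """
    if graph_rna.shape != graph_dna.shape:
        raise InputError("modality graphs have different cell sets")
    if not 0 <= weight_rna <= 1:
        raise ConfigurationError("weight_rna must lie in [0, 1]")
    if weight_rna == 1:
        return _as_csr(graph_rna).copy()
    if weight_rna == 0:
        return _as_csr(graph_dna).copy()
    return (weight_rna * _as_csr(graph_rna) + (1 - weight_rna) * _as_csr(graph_dna)).tocsr()


@dataclass
class ClusterAssignment:
    """Cell -> cluster map with sizes, exclusion flags and optional labels."""

    labels: np.ndarray            # cluster id per cell
    resolution: float
    min_size: int
    sizes: pd.Series = field(init=False)
    excluded: set[int] = field(init=False)
    type_labels: dict[int, str] = field(default_factory=dict)
    doublet_flags: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sizes = pd.Series(self.labels).value_counts().sort_index()
        self.excluded = {int(c) for c, n in self.sizes.items() if n < self.min_size}

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_retained_clusters(self) -> int:
        return len(self.sizes) - len(self.excluded)

    def retained_mask(self) -> np.ndarray:
        drop = self.excluded | self.doublet_flags
        return ~np.isin(self.labels, sorted(drop))


def _igraph_from_sparse(graph: sp.spmatrix) -> ig.Graph:
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    return g


def cluster_graph(graph: sp.spmatrix, resolution: float = 1.0, seed: int = 0,
                  min_size: int = 50, backend: str = "louvain") -> ClusterAssignment:
    """Louvain (or Leiden) modularity communities on a neighbor graph.

    Deterministic given ``seed``; isolated cells become singleton clusters
    (immediately flagged excluded by the size rule). Clusters with fewer than
    ``min_size`` cells (default 50) are flagged excluded downstream.
    """
    if graph.shape[0] == 0:
        raise InputError("empty graph")
    g = _igraph_from_sparse(graph)
    if backend == "louvain":
        ig.set_random_number_generator(_random.Random(seed))
        part = g.community_multilevel(weights="weight" if g.ecount() else None,
                                      resolution=resolution)
        labels = np.asarray(part.membership)
    elif backend == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight" if g.ecount() else None,
            resolution_parameter=resolution, seed=seed,
        )
        labels = np.asarray(part.membership)
    else:
        raise ConfigurationError(f"unknown backend {backend!r}")
    return ClusterAssignment(labels=labels, resolution=resolution, min_size=min_size)


def search_resolution(graph: sp.spmatrix, target_k: int, seed: int = 0,
                      min_size: int = 50, lo: float = 0.01, hi: float = 3.0,
                      max_iter: int = 14, backend: str = "louvain") -> ClusterAssignment:
    """Bisect the resolution until the number of retained clusters hits a target.

    Mirrors the practice of clustering into a preset number of clusters;
    returns the assignment whose retained-cluster count is closest to
    ``target_k`` (exact when the bisection finds it).
    """
    best = None
    best_k = None
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        assign = cluster_graph(graph, resolution=mid, seed=seed,
                               min_size=min_size, backend=backend)
        k = assign.n_clusters
        if best is None or abs(k - target_k) < abs(best_k - target_k):
            best, best_k = assign, k
        if k == target_k:
            return assign
        if k < target_k:
            lo = mid
        else:
            hi = mid
    return best


def marker_scores(normalized: sp.spmatrix, gene_names: list[str],
                  assignment: ClusterAssignment,
                  markers: dict[str, list[str]]) -> pd.DataFrame:
    """Mean marker-gene z-score per (cluster, cell type).

    Genes are z-scored across cells; each type's score in a cluster is the
    mean z over that type's markers and the cluster's cells. Markers absent
    from the matrix are warned about and skipped; gene order is irrelevant.
    """
    if not markers:
        raise ConfigurationError("empty marker configuration")
    x = _as_csr(normalized)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    dense = None
    scores = {}
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    sd = np.sqrt(np.maximum(sq - mean**2, 0))
    sd[sd == 0] = 1.0
    clusters = sorted(set(assignment.labels.tolist()))
    for ctype, genes in markers.items():
        idx = []
        for g in genes:
            if g in name_to_idx:
                idx.append(name_to_idx[g])
            else:
                warnings.warn(f"marker gene {g!r} missing from matrix; skipped")
        if not idx:
            scores[ctype] = {c: np.nan for c in clusters}
            continue
        sub = np.asarray(x[:, idx].todense())
        z = (sub - mean[idx]) / sd[idx]
        per_cell = z.mean(axis=1)
        scores[ctype] = {c: float(per_cell[assignment.labels == c].mean())
                         for c in clusters}
    return pd.DataFrame(scores)  # rows: cluster id, cols: cell type


def label_clusters(assignment: ClusterAssignment, normalized: sp.spmatrix,
                   gene_names: list[str], markers: dict[str, list[str]],
                   margin: float = 0.0) -> ClusterAssignment:
    """Assign each cluster the argmax marker-score type, or ``unresolved``."""
    table = marker_scores(normalized, gene_names, assignment, markers)
    labels = {}
    for cluster, row in table.iterrows():
        if row.isna().all() or row.max() <= margin:
            labels[int(cluster)] = "unresolved"
        else:
            labels[int(cluster)] = str(row.idxmax())
    assignment.type_labels = labels
    return assignment


def flag_doublet_clusters(assignment: ClusterAssignment, scores: pd.DataFrame,
                          threshold: float = 1.0) -> ClusterAssignment:
    """Flag clusters scoring above ``threshold`` for two or more major types."""
    flags = set()
    for cluster, row in scores.iterrows():
        if int((row > threshold).sum()) >= 2:
            flags.add(int(cluster))
    assignment.doublet_flags = flags
    return assignment
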