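"""Metacell aggregation: bootstrap co-clustering of cells on a mutual-kNN
graph followed by a hierarchical cut, producing homogeneous cell groups
whose expression and trait values are member averages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix


@dataclass
class MetacellConfig:
    scaled_var_threshold: float = 0.08
    knn_k: int = 100
    n_boot: int = 500
    boot_frac: float = 0.75
    min_size: int = 50
    mito_prefix: str = "MT-"
    resolution: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.boot_frac <= 1.0:
            raise ValueError("boot_frac must be in (0, 1]")


@dataclass
class MetacellAssignment:
    cell_to_metacell: np.ndarray          # per-cell id, contiguous from 1
    members: dict = field(default_factory=dict)  # id -> cell index array
    expression: np.ndarray | None = None  # metacells x genes (mean normalized)
    genes: np.ndarray | None = None
    trait: np.ndarray | None = None       # per-metacell mean trait

    @property
    def n_metacells(self) -> int:
        return len(self.members)


def select_variable_genes(
    matrix: ExpressionMatrix,
    threshold: float = 0.08,
    mito_prefix: str = "MT-",
) -> list[str]:
    """Genes whose variance/mean ratio of log-normalized expression exceeds
    ``threshold``; mitochondrial genes (by name prefix) are excluded first."""
    if matrix.n_obs < 2:
        raise ValueError("need at least 2 cells")
    expr = matrix.normalized(log=True)
    keep = ~np.char.startswith(matrix.genes.astype(str), mito_prefix)
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(mean > 0, var / mean, 0.0)
    sel = keep & (scaled > threshold) & (mean > 0)
    out = [str(g) for g in matrix.genes[sel]]
    if not out:
        raise ValueError(
            f"no gene passes scaled-variance threshold {threshold}; lower it"
        )
    return out


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of x."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    norms[norms == 0] = 1.0
    xc /= norms[:, None]
    return 1.0 - xc @ xc.T


def build_coclustering(matrix: ExpressionMatrix, config: MetacellConfig) -> np.ndarray:
    """Bootstrap co-clustering frequencies.

    Each bootstrap subsamples ``boot_frac`` of cells, builds a mutual-kNN
    graph on correlation distance over the selected variable genes, and
    partitions it into Leiden communities (connected components degenerate
    to one blob when variation is continuous). Entry (i, j) is the fraction
    of bootstraps containing both cells in which they co-partition; the
    diagonal is 1.
    """
    n = matrix.n_obs
    if n <= config.knn_k:
        raise ValueError(f"need more than knn_k={config.knn_k} cells, got {n}")
    m = int(round(config.boot_frac * n))
    if config.knn_k >= m:
        raise ValueError("knn_k must be smaller than the bootstrap subsample size")
    rng = np.random.default_rng(config.seed)

    var_genes = select_variable_genes(
        matrix, config.scaled_var_threshold, config.mito_prefix
    )
    expr = matrix.subset_genes(var_genes).normalized(log=True).T  # cells x genes

    co = np.zeros((n, n))
    both = np.zeros((n, n))
    for b in range(config.n_boot):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = expr[idx]
        dist = _correlation_distance(sub)
        np.fill_diagonal(dist, np.inf)
        k = min(config.knn_k, m - 1)
        nbr = np.argpartition(dist, k - 1, axis=1)[:, :k]
        adj = np.zeros((m, m), dtype=bool)
        rows = np.repeat(np.arange(m), k)
        adj[rows, nbr.ravel()] = True
        mutual = adj & adj.T
        ii, jj = np.nonzero(np.triu(mutual, 1))
        g = igraph.Graph(n=m, edges=list(zip(ii.tolist(), jj.tolist())))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=config.resolution,
            seed=config.seed * 100003 + b,
            n_iterations=3,
        )
        labels = np.asarray(part.membership)
        same = labels[:, None] == labels[None, :]
        co[np.ix_(idx, idx)] += same
        both[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(both > 0, co / both, 0.0)
    np.fill_diagonal(freq, 1.0)
    return freq


def partition_metacells(
    coclustering: np.ndarray,
    min_size: int = 50,
    matrix: ExpressionMatrix | None = None,
    trait: np.ndarray | None = None,
) -> MetacellAssignment:
    """Average-linkage cut of the co-clustering matrix into metacells.

    The dendrogram on (1 - co-clustering) is cut just below its top merge
    level (pairs never co-clustered sit in a tie block at height 1);
    undersized clusters are merged into the cluster they co-cluster with
    most, and clusters large enough to hold several metacells are split
    again by within-cluster linkage, so every metacell has at least
    ``min_size`` members and their number is (greedily) maximized. When
    expression/trait are supplied, metacell values are arithmetic means
    over members (log-normalized expression)."""
    co = np.asarray(coclustering, dtype=float)
    if co.ndim != 2 or co.shape[0] != co.shape[1]:
        raise ValueError("co-clustering must be square")
    if not np.allclose(co, co.T, atol=1e-8):
        raise ValueError("co-clustering must be symmetric")
    n = co.shape[0]
    expr_cells = matrix.normalized(log=True).T if matrix is not None else None
    if n < min_size:
        warnings.warn("fewer cells than min_size; returning a single metacell")
        labels = np.ones(n, dtype=int)
    else:
        labels = _cut_merge_split(co, min_size, expr_cells)

    # relabel contiguous from 1, ordered by first occurrence
    uniq = list(dict.fromkeys(labels.tolist()))
    remap = {old: i + 1 for i, old in enumerate(uniq)}
    labels = np.asarray([remap[v] for v in labels], dtype=int)
    members = {mc: np.where(labels == mc)[0] for mc in sorted(set(labels))}

    expression = genes = trait_out = None
    if matrix is not None:
        expr = matrix.normalized(log=True)  # genes x cells
        expression = np.vstack(
            [expr[:, idx].mean(axis=1) for mc, idx in sorted(members.items())]
        )
        genes = matrix.genes.copy()
    if trait is not None:
        trait_out = np.asarray(
            [np.mean(np.asarray(trait)[idx]) for mc, idx in sorted(members.items())]
        )
    return MetacellAssignment(
        cell_to_metacell=labels,
        members=members,
        expression=expression,
        genes=genes,
        trait=trait_out,
    )


def _linkage_on(co: np.ndarray):
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def _cut_merge_split(
    co: np.ndarray, min_size: int, expr_cells: np.ndarray | None = None
) -> np.ndarray:
    n = co.shape[0]
    z = _linkage_on(co)
    heights = np.unique(z[:, 2])
    # cut where the number of >= min_size clusters peaks (ties: higher cut)
    best_labels, best_big, best_h = np.ones(n, dtype=int), 1, -np.inf
    for h in heights:
        cand = fcluster(z, t=float(h), criterion="distance")
        _, sizes = np.unique(cand, return_counts=True)
        n_big = int((sizes >= min_size).sum())
        if n_big > best_big or (n_big == best_big and h > best_h):
            best_labels, best_big, best_h = cand, n_big, h
    labels = _merge_undersized(best_labels, co, min_size)
    # split clusters that can hold >= 2 metacells
    out = np.zeros(n, dtype=int)
    next_id = 1
    for cid in np.unique(labels):
        idx = np.where(labels == cid)[0]
        block_expr = expr_cells[idx] if expr_cells is not None else None
        parts = _split_block(co[np.ix_(idx, idx)], min_size, block_expr)
        for p in np.unique(parts):
            out[idx[parts == p]] = next_id
            next_id += 1
    return out


def _split_block(
    co_block: np.ndarray, min_size: int, expr_block: np.ndarray | None = None
) -> np.ndarray:
    """Split one cluster into as many >= min_size parts as possible: first
    by its internal co-clustering structure; when that is uniform (ties),
    by balanced chunks along the first principal component of expression."""
    m = co_block.shape[0]
    k_max = m // min_size
    if k_max < 2:
        return np.ones(m, dtype=int)
    z = _linkage_on(co_block)
    for k in range(k_max, 1, -1):
        cand = fcluster(z, t=k, criterion="maxclust")
        cand = _merge_undersized(cand, co_block, min_size)
        if len(np.unique(cand)) >= 2:
            return cand
    if expr_block is not None:
        centered = expr_block - expr_block.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        order = np.argsort(u[:, 0], kind="stable")
        parts = np.empty(m, dtype=int)
        bounds = np.linspace(0, m, k_max + 1).astype(int)
        for k in range(k_max):
            parts[order[bounds[k]:bounds[k + 1]]] = k + 1
        return parts
    return np.ones(m, dtype=int)


def _merge_undersized(labels: np.ndarray, co: np.ndarray, min_size: int) -> np.ndarray:
    """Merge each undersized cluster into the cluster it co-clusters with
    most; adequately sized clusters are never merged into each other."""
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        if len(ids) <= 1 or sizes.min() >= min_size:
            return labels
        small = ids[int(np.argmin(sizes))]
        mask = labels == small
        best, best_sim = None, -np.inf
        for other in ids:
            if other == small:
                continue
            sim = co[np.ix_(mask, labels == other)].mean()
            if sim > best_sim:
                best, best_sim = other, sim
        labels[mask] = best
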