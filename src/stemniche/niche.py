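"""Tumor-boundary geometry and niche statistics on the spot lattice:
boundary extraction, core-vs-boundary testing, two-gene co-localization,
NNLS deconvolution against reference profiles, and CAF-subtype scoring."""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .matrix import SpotGrid


@dataclass
class NicheLabels:
    region: np.ndarray                 # core / boundary / non_tumor
    distance_to_margin: np.ndarray     # BFS distance of tumor spots to non-tumor


def lattice_adjacency(grid: SpotGrid) -> nx.Graph:
    """Undirected neighbor graph: 6 neighbors on the hex (odd-r offset)
    lattice, 4 on the square lattice. Nodes are spot indices."""
    rows, cols = grid.array_row, grid.array_col
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    g = nx.Graph()
    g.add_nodes_from(range(grid.n_spots))
    for i, (r, c) in enumerate(zip(rows, cols)):
        r, c = int(r), int(c)
        if grid.lattice == "square":
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:  # odd-r offset hex
            odd = r & 1
            steps = [(0, -1), (0, 1), (-1, 0), (1, 0),
                     (-1, 1 if odd else -1), (1, 1 if odd else -1)]
        for dr, dc in steps:
            j = index.get((r + dr, c + dc))
            if j is not None:
                g.add_edge(i, j)
    return g


def extract_boundary(tumor_labels, graph: nx.Graph, width: int = 2) -> NicheLabels:
    """Split tumor spots into boundary (graph distance to the nearest
    non-tumor spot <= ``width``) and core. Spots on the section edge are
    measured against observed spots only: missing tissue beyond the capture
    area is not treated as non-tumor."""
    tumor = np.asarray(tumor_labels)
    if tumor.dtype != bool:
        tumor = np.isin(tumor, ["tumor", "1", 1, True])
    n = len(tumor)
    if tumor.sum() == 0:
        raise ValueError("no tumor spots")
    dist = np.full(n, np.inf)
    if (~tumor).sum() == 0:
        warnings.warn("no non-tumor spots; boundary is undefined, all tumor kept as boundary")
        region = np.where(tumor, "boundary", "non_tumor").astype(object)
        return NicheLabels(region=region, distance_to_margin=dist)

    # multi-source BFS from all non-tumor spots
    queue = deque()
    for i in np.where(~tumor)[0]:
        dist[i] = 0
        queue.append(i)
    while queue:
        i = queue.popleft()
        for j in graph.neighbors(i):
            if dist[j] == np.inf:
                dist[j] = dist[i] + 1
                queue.append(j)

    region = np.full(n, "non_tumor", dtype=object)
    region[tumor & (dist <= width)] = "boundary"
    region[tumor & (dist > width)] = "core"
    return NicheLabels(region=region, distance_to_margin=dist)


def compare_regions(values, labels: NicheLabels) -> dict:
    """Two-sided Mann-Whitney of boundary vs core spot values."""
    values = np.asarray(values, dtype=float)
    b = values[labels.region == "boundary"]
    c = values[labels.region == "core"]
    if len(b) < 3 or len(c) < 3:
        raise ValueError("both regions need at least 3 spots")
    res = stats.mannwhitneyu(b, c, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "median_diff": float(np.median(b) - np.median(c)),
        "n_boundary": len(b),
        "n_core": len(c),
    }


def colocalization(expr_a, expr_b, threshold: float = 0.0) -> tuple[np.ndarray, float]:
    """Per-spot co-localization class and double-positive percentage.

    A spot is A+ when ``expr_a > threshold`` (likewise B+). The percentage
    is 100 * |A+ and B+| / |A+ or B+| - double positives as a share of
    spots expressing either gene."""
    a = np.asarray(expr_a, dtype=float) > threshold
    b = np.asarray(expr_b, dtype=float) > threshold
    if len(a) != len(b):
        raise ValueError("expression vectors must have equal length")
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("no spot expresses either gene; percentage undefined")
    classes = np.where(
        a & b, "A+B+", np.where(a, "A+only", np.where(b, "B+only", "negative"))
    ).astype(object)
    percent = 100.0 * int((a & b).sum()) / union
    return classes, percent


def spot_correlation(expr_a, score_b, method: str = "spearman") -> tuple[float, float]:
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if len(a) < 10:
        raise ValueError("need at least 10 spots")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def deconvolve_spots(grid: SpotGrid, reference_profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-spot non-negative least squares against cell-type reference
    profiles (both sides CPM-normalized, no log), proportions renormalized
    to sum to 1. ``reference_profiles``: type x gene mean counts."""
    if reference_profiles.shape[0] < 2:
        raise ValueError("need at least 2 reference cell types")
    shared = [g for g in grid.matrix.genes if g in set(reference_profiles.columns)]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes; need at least 50")
    ref = reference_profiles[shared].to_numpy(dtype=float)
    ref_cpm = ref / ref.sum(axis=1, keepdims=True) * 1e6
    if np.linalg.matrix_rank(ref_cpm) < ref_cpm.shape[0]:
        raise ValueError("reference profile matrix is rank-deficient")

    sub = grid.matrix.subset_genes(shared)
    spots = sub.normalized(log=False, target_sum=1e6)  # genes x spots, CPM
    a = ref_cpm.T  # genes x types
    props = np.zeros((grid.n_spots, ref_cpm.shape[0]))
    for i in range(grid.n_spots):
        coef, _ = nnls(a, spots[:, i])
        total = coef.sum()
        props[i] = coef / total if total > 0 else 1.0 / len(coef)
    return pd.DataFrame(
        props, index=grid.matrix.obs_names, columns=reference_profiles.index
    )


def caf_subtype_scores(grid: SpotGrid, caf_signatures: dict[str, list[str]]) -> pd.DataFrame:
    """Mean log-normalized expression per CAF-subtype signature per spot."""
    expr = grid.matrix.normalized(log=True)
    cols = {}
    for name, genes in caf_signatures.items():
        idx = grid.matrix.gene_index(genes)
        if len(idx) == 0:
            raise ValueError(f"signature {name!r} has no gene present in the matrix")
        cols[name] = expr[idx].mean(axis=0)
    return pd.DataFrame(cols, index=grid.matrix.obs_names)
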