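"""Malignant-spot identification in spatial sections: clustering, immune
reference selection, windowed CNV inference, CNV scores, and malignant
cluster calling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix, SpotGrid


@dataclass
class MarkerPanel:
    pan_immune: tuple = ("PTPRC",)
    t_cell: tuple = ("CD2", "CD3D", "CD3E", "CD3G")
    b_cell: tuple = ("CD79A", "MS4A1", "CD79B")
    myeloid: tuple = ("CD68", "CD14")
    epithelial: tuple = ("EPCAM", "KRT8", "KRT19")

    def immune_union(self) -> list[str]:
        return list(
            dict.fromkeys(
                list(self.pan_immune) + list(self.t_cell)
                + list(self.b_cell) + list(self.myeloid)
            )
        )


@dataclass
class CnvProfile:
    values: np.ndarray                 # observations x genes, genome-ordered
    genes: np.ndarray
    obs_names: np.ndarray
    cnv_score: np.ndarray              # per-observation mean of squares
    reference_mask: np.ndarray
    chrom: np.ndarray = field(default=None)


def cluster_spots(
    grid: SpotGrid,
    n_pcs: int = 30,
    resolution: float = 1.0,
    n_top_genes: int = 2000,
    knn_k: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph over PCA of log-normalized
    top-variable genes. Deterministic under ``seed``."""
    matrix = grid.matrix
    if matrix.n_obs < 50:
        raise ValueError("need at least 50 spots")
    expr = matrix.normalized(log=True)  # genes x spots
    var = expr.var(axis=1)
    top = np.argsort(-var, kind="stable")[: min(n_top_genes, matrix.n_genes)]
    x = expr[top].T  # spots x genes
    n_pcs_eff = min(n_pcs, x.shape[0] - 1, x.shape[1])
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs to {n_pcs_eff}")
    pcs = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(
        x - x.mean(axis=0)
    )
    k = min(knn_k, matrix.n_obs - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i in range(matrix.n_obs) for j in nbr[i, 1:]}
    g = igraph.Graph(n=matrix.n_obs, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=5,
    )
    return np.asarray(part.membership, dtype=int)


def immune_score(grid: SpotGrid, panel: MarkerPanel | None = None) -> np.ndarray:
    """Mean log-normalized expression over the union of immune marker sets."""
    panel = panel or MarkerPanel()
    idx = grid.matrix.gene_index(panel.immune_union())
    if len(idx) == 0:
        raise ValueError("no immune panel gene present in the matrix")
    return grid.matrix.normalized(log=True)[idx].mean(axis=0)


def epithelial_score(grid: SpotGrid, panel: MarkerPanel | None = None) -> np.ndarray:
    panel = panel or MarkerPanel()
    idx = grid.matrix.gene_index(list(panel.epithelial))
    if len(idx) == 0:
        raise ValueError("no epithelial panel gene present in the matrix")
    return grid.matrix.normalized(log=True)[idx].mean(axis=0)


def select_reference(scores: np.ndarray, clusters: np.ndarray) -> int:
    """Cluster with the highest mean immune score; ties break to the lowest
    cluster id."""
    ids = np.unique(clusters)
    means = np.asarray([scores[clusters == c].mean() for c in ids])
    return int(ids[int(np.argmax(means))])  # argmax returns first max: lowest id


def _chrom_sort_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def infer_cnv(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    reference_mask,
    window: int = 101,
    clamp: float = 0.5,
    cutoff: float = 0.1,
) -> CnvProfile:
    """Windowed relative-expression CNV profile.

    Steps: drop genes with mean expression below ``cutoff``; log2(norm+1);
    center each gene by the reference mean; order genes along the genome;
    moving average of ``window`` genes within each chromosome (edges use
    the available genes); subtract the per-observation median (denoise);
    clamp to [-clamp, clamp]. ``cnv_score`` is the per-observation mean of
    squared values."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() < 20:
        raise ValueError("need at least 20 reference observations")
    ann = annotation.set_index("gene")
    have = np.isin(matrix.genes, ann.index)
    if have.mean() < 0.5:
        raise ValueError("annotation missing for more than half of the genes")

    norm = matrix.normalized(log=False)
    keep = have & (norm.mean(axis=1) >= cutoff)
    genes = matrix.genes[keep]
    if len(genes) < 100:
        raise ValueError("fewer than 100 annotated genes above the cutoff")
    x = np.log2(norm[keep] + 1.0)  # genes x obs
    x = x - x[:, reference_mask].mean(axis=1, keepdims=True)

    chrom = ann.loc[genes, "chrom"].to_numpy()
    start = ann.loc[genes, "start"].to_numpy()
    order = sorted(
        range(len(genes)), key=lambda i: (_chrom_sort_key(chrom[i]), start[i], i)
    )
    order = np.asarray(order)
    x, genes, chrom = x[order], genes[order], chrom[order]

    smoothed = np.empty_like(x)
    for c in pd.unique(chrom):
        sel = np.where(chrom == c)[0]
        smoothed[sel] = _moving_average(x[sel], window)

    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)
    if np.isfinite(clamp):
        smoothed = np.clip(smoothed, -clamp, clamp)
    values = smoothed.T  # obs x genes
    return CnvProfile(
        values=values,
        genes=genes,
        obs_names=matrix.obs_names.copy(),
        cnv_score=(values**2).mean(axis=1),
        reference_mask=reference_mask,
        chrom=chrom,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with shrinking edge windows."""
    n = x.shape[0]
    half = (min(window, n) - 1) // 2
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    out = np.empty_like(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def call_malignant(
    profile: CnvProfile,
    n_clusters: int = 8,
    mad_factor: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ward clustering of non-reference CNV profiles into ``n_clusters``;
    a cluster is malignant when the mean-square of its average CNV profile
    exceeds the reference spot-score median plus ``mad_factor`` reference
    MADs (averaging member profiles cancels per-spot sampling noise while
    coherent chromosome-level deviation survives). Returns per-observation
    "tumor" / "non_tumor" labels (reference observations are non_tumor) and
    a per-cluster summary table."""
    ref = profile.reference_mask
    query = ~ref
    ref_scores = profile.cnv_score[ref]
    med = float(np.median(ref_scores))
    mad = float(np.median(np.abs(ref_scores - med)))
    if mad == 0:
        warnings.warn("reference MAD is zero; using the 95th percentile threshold")
        threshold = float(np.percentile(ref_scores, 95))
    else:
        threshold = med + mad_factor * mad

    x = profile.values[query]
    k = min(n_clusters, x.shape[0])
    z = linkage(x, method="ward")
    clusters = fcluster(z, t=k, criterion="maxclust")

    labels = np.full(len(profile.obs_names), "non_tumor", dtype=object)
    rows = []
    qidx = np.where(query)[0]
    for c in np.unique(clusters):
        sel = qidx[clusters == c]
        cluster_score = float((profile.values[sel].mean(axis=0) ** 2).mean())
        malignant = cluster_score > threshold
        if malignant:
            labels[sel] = "tumor"
        rows.append(
            {
                "cluster": int(c),
                "n_spots": int(len(sel)),
                "cluster_cnv_score": cluster_score,
                "median_spot_score": float(np.median(profile.cnv_score[sel])),
                "malignant": bool(malignant),
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["threshold"] = threshold
    return labels, summary
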