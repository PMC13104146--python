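"""Weighted co-expression network on metacells: soft-threshold selection,
topological overlap, module detection, eigengenes, trait correlation, and
signature derivation by intersecting a module with malignant markers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .matrix import ExpressionMatrix

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


@dataclass
class NetworkConfig:
    n_top_genes: int = 5000
    power_grid: tuple = tuple(range(1, 21))
    r2_target: float = 0.8
    network_type: str = "unsigned"
    min_module_size: int = 30
    cut_height: float | None = None  # default: 0.98 * max merge height
    n_bins: int = 10


@dataclass
class ModuleSet:
    gene_module: pd.Series            # gene -> module label ("grey" = unassigned)
    eigengenes: pd.DataFrame          # metacells x modules, unit-norm columns
    trait_correlation: pd.DataFrame | None = None

    def genes_in(self, module: str) -> list[str]:
        return list(self.gene_module.index[self.gene_module == module])


@dataclass
class Signature:
    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(dict.fromkeys(self.genes))
        if not self.genes:
            raise ValueError("signature must be non-empty")


def _correlation(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; constant rows must be removed first."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    xc /= norms[:, None]
    c = xc @ xc.T
    return np.clip(c, -1.0, 1.0)


def adjacency_from_correlation(cor: np.ndarray, power: float, network_type: str) -> np.ndarray:
    if network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 frequency vs log10 mean connectivity over bins;
    negative when the slope is positive (not scale-free)."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    logs_k, logs_p = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        logs_k.append(np.log10(k[sel].mean()))
        logs_p.append(np.log10(sel.mean()))
    if len(logs_k) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(logs_k, logs_p)
    r2 = r**2
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    matrix: np.ndarray | pd.DataFrame,
    config: NetworkConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power approximating scale-free topology.

    ``matrix``: metacells x genes expression. Returns the smallest grid
    power whose signed fit R^2 reaches ``r2_target``, else the argmax, plus
    the per-power fit table (power, r2, mean_k, median_k, max_k).
    """
    config = config or NetworkConfig()
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if x.shape[0] < 30:
        raise ValueError("need at least 30 metacells")
    genes_x = x.T  # genes x metacells
    const = genes_x.std(axis=1) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant gene(s)")
        genes_x = genes_x[~const]
    cor = _correlation(genes_x)
    rows = []
    for beta in config.power_grid:
        a = adjacency_from_correlation(cor, beta, config.network_type)
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "r2": scale_free_fit(k, config.n_bins),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= config.r2_target]
    power = int(ok["power"].iloc[0]) if len(ok) else int(table.loc[table["r2"].idxmax(), "power"])
    return power, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), with unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must be in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    genes,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of (1 - TOM) with a static cut.

    Clusters smaller than ``min_module_size`` become "grey"; remaining
    modules are named by size rank using the conventional color sequence
    (largest = "turquoise")."""
    genes = np.asarray(genes, dtype=object)
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    max_h = z[:, 2].max() if len(z) else 0.0
    h = cut_height if cut_height is not None else 0.98 * max_h
    raw = fcluster(z, t=h, criterion="distance")

    ids, sizes = np.unique(raw, return_counts=True)
    keep = ids[sizes >= min_module_size]
    order = keep[np.argsort(-sizes[np.isin(ids, keep)], kind="stable")]
    labels = np.full(len(genes), "grey", dtype=object)
    for rank, mid in enumerate(order):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[raw == mid] = color
    if (labels == "grey").all():
        warnings.warn("all genes unassigned (grey); consider a higher cut height")
    return pd.Series(labels, index=genes, name="module")


def module_eigengene(expression: np.ndarray | pd.DataFrame, module_genes, genes=None) -> np.ndarray:
    """First principal component of the standardized module expression
    across metacells (unit norm), oriented to correlate positively with the
    module mean. ``expression``: metacells x genes."""
    if isinstance(expression, pd.DataFrame):
        sub = expression.loc[:, list(module_genes)].to_numpy(dtype=float)
    else:
        genes = np.asarray(genes, dtype=object)
        idx = [int(np.where(genes == g)[0][0]) for g in module_genes]
        sub = np.asarray(expression, dtype=float)[:, idx]
    if sub.shape[1] < 2:
        raise ValueError("module needs at least 2 genes")
    sd = sub.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate module: constant gene across metacells")
    zmat = (sub - sub.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(zmat, full_matrices=False)
    eig = u[:, 0]
    mean_profile = zmat.mean(axis=1)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig


def module_trait_correlation(eigengenes: pd.DataFrame, trait) -> pd.DataFrame:
    """Pearson r (two-sided t-test p) of each module eigengene against the
    per-metacell trait, sorted by r descending."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) != len(eigengenes):
        raise ValueError("trait length must match number of metacells")
    if np.std(trait) == 0:
        raise ValueError("trait has zero variance")
    rows = []
    for module in eigengenes.columns:
        r, p = stats.pearsonr(eigengenes[module].to_numpy(), trait)
        rows.append({"module": module, "r": r, "p": p})
    return (
        pd.DataFrame(rows)
        .sort_values("r", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def module_eigengenes(expression: pd.DataFrame, gene_module: pd.Series) -> pd.DataFrame:
    """Eigengene matrix for all non-grey modules (columns unit-norm)."""
    cols = {}
    for module in gene_module.unique():
        if module == "grey":
            continue
        cols[module] = module_eigengene(expression, gene_module.index[gene_module == module])
    if not cols:
        raise ValueError("no non-grey modules")
    return pd.DataFrame(cols, index=expression.index)


def malignant_markers(
    matrix: ExpressionMatrix,
    malignant_mask,
    lfc_min: float = 0.5,
    p_max: float = 0.05,
    adjust: bool = False,
) -> list[str]:
    """Genes up in malignant cells: log fold change of mean normalized
    expression (pseudocount 1) > ``lfc_min`` and Wilcoxon rank-sum p <
    ``p_max``. ``adjust=True`` applies Benjamini-Hochberg instead of raw p."""
    mask = np.asarray(malignant_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    expr = matrix.normalized(log=False)
    mal, rest = expr[:, mask], expr[:, ~mask]
    lfc = np.log((mal.mean(axis=1) + 1.0) / (rest.mean(axis=1) + 1.0))

    if mask.sum() < 3 or (~mask).sum() < 3:
        warnings.warn("a group has fewer than 3 cells; p-values set to 1")
        pvals = np.ones(matrix.n_genes)
    else:
        candidates = np.where(lfc > lfc_min)[0]
        pvals = np.ones(matrix.n_genes)
        for gi in candidates:
            pvals[gi] = stats.mannwhitneyu(
                mal[gi], rest[gi], alternative="two-sided"
            ).pvalue
    if adjust:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        pvals = pvals.copy()
        pvals[order] = np.minimum(adj, 1.0)
    sel = (lfc > lfc_min) & (pvals < p_max)
    return [str(g) for g in matrix.genes[sel]]


def derive_signature(module_genes, marker_genes, name: str = "CSC") -> Signature:
    """Sorted intersection of a module's genes with the marker set."""
    a, b = set(module_genes), set(marker_genes)
    if not a or not b:
        raise ValueError("both gene sets must be non-empty")
    inter = sorted(a & b)
    if not inter:
        raise ValueError("module and marker sets are disjoint")
    return Signature(name=name, genes=inter)
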