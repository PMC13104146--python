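"""Per-cell stemness scoring.

Two complementary scores:

* :func:`diversity_score` — transcriptional-diversity score in [0, 1];
  higher values indicate a less differentiated, more stem-like state.
* :func:`signature_auc` — ranking-based recovery-curve AUC of a gene
  signature, in [0, 1]; higher values indicate stronger signature activity.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix


def diversity_score(
    matrix: ExpressionMatrix,
    n_corr_genes: int = 200,
    knn_k: int = 30,
    smooth_alpha: float = 0.7,
    smooth_iters: int = 50,
) -> np.ndarray:
    """Transcriptional-diversity stemness score per cell.

    Pipeline: (1) per-cell detected-gene count; (2) Pearson correlation of
    each gene's log-normalized expression with the detected-gene count;
    (3) initial score = mean expression of the ``n_corr_genes`` most
    correlated genes; (4) diffusion over a kNN graph,
    ``score <- alpha * neighbor_mean + (1 - alpha) * initial`` iterated;
    (5) rank transform to [0, 1].
    """
    if matrix.n_obs < 2:
        raise ValueError("need at least 2 cells")
    counts = matrix.dense_counts()
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        bad = matrix.obs_names[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total counts")

    gene_counts = (counts > 0).sum(axis=0).astype(float)
    expr = matrix.normalized(log=True)  # genes x cells

    if np.ptp(gene_counts) == 0:
        # degenerate: no detected-gene variation to correlate against
        initial = expr.mean(axis=0)
    else:
        gc_c = gene_counts - gene_counts.mean()
        gc_norm = np.sqrt((gc_c**2).sum())
        x_c = expr - expr.mean(axis=1, keepdims=True)
        x_norm = np.sqrt((x_c**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            cors = (x_c @ gc_c) / (x_norm * gc_norm)
        cors = np.nan_to_num(cors, nan=-np.inf)  # constant genes never selected
        n_top = min(n_corr_genes, int(np.isfinite(cors).sum()))
        top = np.argsort(-cors, kind="stable")[:n_top]
        initial = expr[top, :].mean(axis=0)

    k = min(knn_k, matrix.n_obs - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(expr.T)
    _, nbr = nn.kneighbors(expr.T)
    nbr = nbr[:, :]  # includes self in column 0 for exact duplicates too

    score = initial.copy()
    for _ in range(smooth_iters):
        score = smooth_alpha * score[nbr].mean(axis=1) + (1.0 - smooth_alpha) * initial

    ranks = rankdata(score, method="average")
    lo, hi = ranks.min(), ranks.max()
    if hi == lo:
        return np.full(matrix.n_obs, 0.5)
    return (ranks - lo) / (hi - lo)


def signature_auc(
    matrix: ExpressionMatrix,
    signature_genes,
    top_frac: float = 0.05,
) -> np.ndarray:
    """Recovery-curve AUC of a gene signature per cell.

    Genes are ranked per cell by expression, descending, ties broken by
    gene order. The recovery curve counts signature genes found within the
    top ``ceil(top_frac * n_genes)`` ranks; its trapezoidal area is
    normalized by the area of a perfectly top-ranked signature, so scores
    lie in [0, 1]. Depends only on within-cell ranks, hence invariant to
    monotone per-cell transformations.
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    sig = list(dict.fromkeys(signature_genes))
    present = set(matrix.genes) & set(sig)
    if not present:
        raise ValueError(f"no signature gene present in matrix; missing: {sorted(sig)}")

    counts = matrix.dense_counts()
    n_genes, n_obs = counts.shape
    threshold = int(np.ceil(top_frac * n_genes))
    is_sig = np.isin(matrix.genes, sig)
    n_sig = int(is_sig.sum())

    # rank genes per cell: descending expression, stable tie-break by index
    order = np.argsort(-counts, axis=0, kind="stable")  # genes x cells
    top_hits = is_sig[order[:threshold, :]]  # threshold x cells, bool

    # trapezoidal area under cumulative recovery, x = 0..threshold
    cum = np.cumsum(top_hits, axis=0).astype(float)
    auc = cum.sum(axis=0) - 0.5 * cum[-1, :]

    perfect = np.minimum(np.arange(1, threshold + 1), n_sig).astype(float)
    max_auc = perfect.sum() - 0.5 * perfect[-1]
    return auc / max_auc
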