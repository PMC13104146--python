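"""End-to-end orchestration: cohort -> stemness -> metacells -> network ->
CSC signature, and section -> CNV -> tumor labels -> boundary niche."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import network, niche, stemness
from .matrix import ExpressionMatrix, SpotGrid
from .metacell import MetacellAssignment, MetacellConfig, build_coclustering, partition_metacells


@dataclass
class SignatureResult:
    signature: network.Signature
    modules: network.ModuleSet
    metacells: MetacellAssignment
    diversity: np.ndarray           # per malignant cell
    power: int
    top_module: str


def derive_csc_signature(
    matrix: ExpressionMatrix,
    malignant_mask,
    metacell_config: MetacellConfig | None = None,
    network_config: network.NetworkConfig | None = None,
    signature_name: str = "CSC",
) -> SignatureResult:
    """Full discovery path on a labeled cohort.

    Malignant cells are scored for transcriptional diversity, aggregated
    into metacells, a weighted co-expression network is built on the
    metacell matrix, and the module most correlated with the diversity
    trait is intersected with malignant markers to form the signature.
    """
    metacell_config = metacell_config or MetacellConfig()
    network_config = network_config or network.NetworkConfig()
    mask = np.asarray(malignant_mask, dtype=bool)

    mal = matrix.subset_obs(mask)
    diversity = stemness.diversity_score(mal)

    co = build_coclustering(mal, metacell_config)
    assignment = partition_metacells(
        co, metacell_config.min_size, matrix=mal, trait=diversity
    )

    expr = pd.DataFrame(assignment.expression, columns=assignment.genes)
    gene_var = expr.var(axis=0)
    keep = gene_var[gene_var > 0].sort_values(ascending=False, kind="stable")
    top_genes = keep.index[: network_config.n_top_genes]
    expr = expr[top_genes]

    power, _ = network.pick_soft_threshold(expr, network_config)
    cor = network._correlation(expr.to_numpy().T)
    adj = network.adjacency_from_correlation(cor, power, network_config.network_type)
    tom = network.tom_similarity(adj)
    gene_module = network.detect_modules(
        tom, top_genes, network_config.min_module_size, network_config.cut_height
    )
    eigengenes = network.module_eigengenes(expr, gene_module)
    trait_cor = network.module_trait_correlation(eigengenes, assignment.trait)
    top_module = str(trait_cor.iloc[0]["module"])

    markers = network.malignant_markers(matrix, mask)
    signature = network.derive_signature(
        gene_module.index[gene_module == top_module], markers, name=signature_name
    )
    modules = network.ModuleSet(
        gene_module=gene_module, eigengenes=eigengenes, trait_correlation=trait_cor
    )
    return SignatureResult(
        signature=signature,
        modules=modules,
        metacells=assignment,
        diversity=diversity,
        power=power,
        top_module=top_module,
    )


@dataclass
class SpatialResult:
    clusters: np.ndarray
    reference_cluster: int
    profile: cnv_mod.CnvProfile
    tumor_labels: np.ndarray        # "tumor" / "non_tumor" per spot
    niche_labels: niche.NicheLabels
    cluster_summary: pd.DataFrame


def map_tumor_boundary(
    grid: SpotGrid,
    annotation: pd.DataFrame,
    boundary_width: int = 2,
    n_cnv_clusters: int = 8,
    resolution: float = 1.0,
    seed: int = 0,
    window: int = 101,
) -> SpatialResult:
    """Spatial path: cluster spots, pick the immune reference cluster, infer
    CNV, call malignant spots, and split tumor into core and boundary."""
    clusters = cnv_mod.cluster_spots(grid, resolution=resolution, seed=seed)
    scores = cnv_mod.immune_score(grid)
    ref_cluster = cnv_mod.select_reference(scores, clusters)
    ref_mask = clusters == ref_cluster
    profile = cnv_mod.infer_cnv(grid.matrix, annotation, ref_mask, window=window)
    tumor_labels, summary = cnv_mod.call_malignant(profile, n_clusters=n_cnv_clusters)
    graph = niche.lattice_adjacency(grid)
    labels = niche.extract_boundary(tumor_labels == "tumor", graph, width=boundary_width)
    return SpatialResult(
        clusters=clusters,
        reference_cluster=ref_cluster,
        profile=profile,
        tumor_labels=tumor_labels,
        niche_labels=labels,
        cluster_summary=summary,
    )
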