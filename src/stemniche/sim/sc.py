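"""Synthetic single-cell cohort with a planted continuous stemness trait.

Counts are negative-binomial (gamma-Poisson) with gene-level base means
drawn log-normal. Non-malignant cells fall into six types with canonical
marker blocks; malignant cells carry a latent stemness trait that scales a
planted co-expressed gene module and the per-cell detection rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..matrix import ExpressionMatrix
from .config import GroundTruth, ScSimConfig

# Canonical marker blocks for non-malignant annotation.
TYPE_MARKERS: dict[str, list[str]] = {
    "epithelial": ["EPCAM", "KRT8", "KRT19"],
    "fibroblast": ["COL1A1", "COL1A2", "DCN"],
    "endothelial": ["PLVAP", "VWF", "PECAM1"],
    "t_cell": ["CD3D", "CD3E", "TRAC", "CD2", "CD3G"],
    "b_cell": ["MS4A1", "CD79A", "CD79B"],
    "myeloid": ["CD14", "CD163", "CD68", "FCGR3A"],
}
IMMUNE_TYPES = ("t_cell", "b_cell", "myeloid")
PAN_IMMUNE = ["PTPRC"]

# Genes present at moderate levels in specific compartments; used by the
# spatial simulator and the communication tests.
EXTRA_GENES: dict[str, list[str]] = {
    "malignant": ["DSG2", "MDK", "SPP1", "NCL", "CD44", "SDC1", "SDC2",
                  "PTPRZ1", "ITGA6", "ITGB1", "ITGAV", "EGFR"],
    "fibroblast": ["FAP", "ACTA2", "TAGLN", "POSTN", "MYL9", "IL6",
                   "CXCL12", "PDGFRA", "HLA-DRA", "CD74", "NOTCH3",
                   "RGS5", "MSLN", "UPK3B", "APOD", "CFD"],
}

MARKER_STRENGTH = 20.0
EXTRA_STRENGTH = 5.0
MODULE_PREFIX = "STM"


def gene_names(n_genes: int, module_size: int) -> np.ndarray:
    """Deterministic gene list: named markers first, then the planted module
    genes, then numbered filler. Needs n_genes large enough to hold them."""
    named: list[str] = []
    for markers in TYPE_MARKERS.values():
        named.extend(markers)
    named.extend(PAN_IMMUNE)
    for extra in EXTRA_GENES.values():
        named.extend(extra)
    named = list(dict.fromkeys(named))
    module = [f"{MODULE_PREFIX}{i + 1:04d}" for i in range(module_size)]
    n_fill = n_genes - len(named) - len(module)
    if n_fill < 0:
        raise ValueError(
            f"n_genes={n_genes} too small for {len(named)} named + "
            f"{len(module)} module genes"
        )
    fill = [f"G{i + 1:05d}" for i in range(n_fill)]
    return np.asarray(named + module + fill, dtype=object)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_sc_cohort(config: ScSimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = gene_names(config.n_genes, config.module_size)
    module_genes = [g for g in genes if g.startswith(MODULE_PREFIX)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_idx = np.asarray([gene_pos[g] for g in module_genes])

    n_mal = int(round(config.n_cells * config.frac_malignant))
    n_other = config.n_cells - n_mal
    other_types = list(TYPE_MARKERS)
    type_of = np.asarray(
        ["malignant"] * n_mal
        + [other_types[i % len(other_types)] for i in range(n_other)],
        dtype=object,
    )
    rng.shuffle(type_of)
    malignant_mask = type_of == "malignant"

    samples = rng.integers(0, config.n_samples, size=config.n_cells)
    sample_ids = np.asarray([f"P{j + 1:02d}" for j in samples], dtype=object)

    # gene-level base means, log-normal, rescaled to overall mean 1;
    # planted module genes floored so they stay detectable in all cells
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base *= 1.0 / base.mean()
    base[module_idx] = np.maximum(base[module_idx], 1.0)

    stemness = rng.uniform(0.0, 1.0, size=n_mal)
    s_full = np.zeros(config.n_cells)
    s_full[malignant_mask] = stemness

    # per-cell x per-gene mean built row-block-wise to bound memory
    mean = np.tile(base, (config.n_cells, 1))

    for ctype, markers in TYPE_MARKERS.items():
        idx = [gene_pos[g] for g in markers]
        mean[np.ix_(type_of == ctype, idx)] *= MARKER_STRENGTH
    imm = np.isin(type_of, IMMUNE_TYPES)
    mean[np.ix_(imm, [gene_pos[g] for g in PAN_IMMUNE])] *= MARKER_STRENGTH
    for ctype, extras in EXTRA_GENES.items():
        cmask = malignant_mask if ctype == "malignant" else type_of == ctype
        mean[np.ix_(cmask, [gene_pos[g] for g in extras])] *= EXTRA_STRENGTH
    # malignant cells also express the epithelial program
    mean[np.ix_(malignant_mask, [gene_pos[g] for g in TYPE_MARKERS["epithelial"]])] *= (
        MARKER_STRENGTH / 2.0
    )

    # planted stemness module: malignant-enriched and scaling with exp(effect*s)
    mod_scale = config.malignant_boost * np.exp(
        config.stemness_effect * (stemness - 0.5)
    )
    mean[np.ix_(malignant_mask, module_idx)] *= mod_scale[:, None]

    # patient-specific shifts, malignant cells only
    shifts = np.exp(
        rng.normal(0.0, config.sample_shift_sd, size=(config.n_samples, config.n_genes))
    )
    mean[malignant_mask, :] *= shifts[samples[malignant_mask], :]

    # detection decreases with (1 - s) in malignant cells
    detect = np.ones(config.n_cells)
    detect[malignant_mask] = 1.0 - config.diversity_effect * (1.0 - stemness)
    mean *= detect[:, None]

    counts = _nb_sample(rng, mean, config.nb_dispersion).T  # genes x cells

    barcodes = np.asarray(
        [f"CELL{i + 1:06d}" for i in range(config.n_cells)], dtype=object
    )
    matrix = ExpressionMatrix(
        counts=counts.astype(np.int64),
        genes=genes,
        obs_names=barcodes,
        labels=type_of,
        samples=sample_ids,
    )
    truth = GroundTruth(
        stemness=stemness,
        malignant_mask=malignant_mask,
        module_genes=module_genes,
        cell_types=type_of,
    )
    return matrix, truth


def reference_profiles_from_cohort(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Cell-type x gene mean raw counts, for spot mixing and deconvolution."""
    if matrix.labels is None:
        raise ValueError("cohort matrix has no cell-type labels")
    counts = matrix.dense_counts()
    rows = {}
    for ctype in np.unique(matrix.labels):
        rows[str(ctype)] = counts[:, matrix.labels == ctype].mean(axis=1)
    return pd.DataFrame(rows, index=matrix.genes).T
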