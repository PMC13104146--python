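"""Synthetic Visium-like section: a contiguous tumor disc with chromosome
gains, a CSC marker enriched in the boundary ring, a fibroblast marker in
the peritumoral stroma, and an immune-rich region, mixed from single-cell
reference profiles at 1-10 cells per spot."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..matrix import ExpressionMatrix, SpotGrid
from .config import GroundTruth, SpatialSimConfig

# region composition: cell-type mixing weights
REGION_MIX = {
    "tumor": {"malignant": 0.7, "fibroblast": 0.2, "myeloid": 0.1},
    "stroma_ring": {"fibroblast": 0.7, "endothelial": 0.2, "myeloid": 0.1},
    "immune": {"t_cell": 0.4, "b_cell": 0.3, "myeloid": 0.3},
    "other": {"fibroblast": 0.4, "endothelial": 0.3, "epithelial": 0.2, "myeloid": 0.1},
}

BACKGROUND_RATE = 0.02
CSC_CORE_RATE = 0.5
FAP_NICHE_RATE = 2.0
MYCAF_BACKGROUND_RATE = 0.5


def hex_distance(r1, c1, r2, c2) -> np.ndarray:
    """Lattice graph distance between odd-r offset hex coordinates."""
    q1 = np.asarray(c1) - (np.asarray(r1) - (np.asarray(r1) & 1)) // 2
    q2 = np.asarray(c2) - (np.asarray(r2) - (np.asarray(r2) & 1)) // 2
    dq = q1 - q2
    dr = np.asarray(r1) - np.asarray(r2)
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2


def lattice_distance(r1, c1, r2, c2, lattice: str) -> np.ndarray:
    if lattice == "hex":
        return hex_distance(r1, c1, r2, c2)
    return np.abs(np.asarray(r1) - np.asarray(r2)) + np.abs(
        np.asarray(c1) - np.asarray(c2)
    )


def gene_positions(genes, n_chrom: int = 10) -> pd.DataFrame:
    """Deterministic round-robin gene -> (chromosome, start) assignment."""
    genes = np.asarray(genes, dtype=object)
    chrom = np.asarray([f"chr{(i % n_chrom) + 1}" for i in range(len(genes))])
    start = np.asarray([(i // n_chrom + 1) * 100_000 for i in range(len(genes))])
    return pd.DataFrame({"gene": genes, "chrom": chrom, "start": start})


def _min_dist_to(rows, cols, mask, lattice: str) -> np.ndarray:
    """Per-spot minimum lattice distance to any spot in ``mask``."""
    out = np.full(len(rows), np.iinfo(np.int64).max)
    tr, tc = rows[mask], cols[mask]
    if len(tr) == 0:
        return out
    for i in range(len(rows)):
        out[i] = int(lattice_distance(rows[i], cols[i], tr, tc, lattice).min())
    return out


def simulate_visium_section(
    config: SpatialSimConfig,
    reference_profiles: pd.DataFrame,
    positions: pd.DataFrame | None = None,
) -> tuple[SpotGrid, GroundTruth]:
    """Mix reference cell-type profiles into spot counts on a lattice.

    ``reference_profiles`` is a cell-type x gene table of mean counts per
    cell (see ``reference_profiles_from_cohort``). The CSC and fibroblast
    marker genes are removed from the profiles and replanted with
    region-driven Poisson rates so their spatial pattern is controlled;
    the planted co-localization percentage recorded in the ground truth is
    the closed-form expectation under those rates."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = reference_profiles.columns.to_numpy(dtype=object)
    if positions is None:
        positions = gene_positions(genes)

    rows_grid, cols_grid = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    rows = rows_grid.ravel()
    cols = cols_grid.ravel()
    n_spots = len(rows)

    cr, cc = config.n_rows // 2, config.n_cols // 2
    d_center = lattice_distance(rows, cols, cr, cc, config.lattice)
    if config.tumor_radius == 0:
        tumor = np.zeros(n_spots, dtype=bool)
    else:
        tumor = d_center <= config.tumor_radius
        if tumor.sum() < _disc_size(config):
            warnings.warn("tumor disc exceeds lattice; clipped at section edge")

    d_to_nontumor = _min_dist_to(rows, cols, ~tumor, config.lattice)
    boundary = tumor & (d_to_nontumor <= config.boundary_width)
    core = tumor & ~boundary
    d_to_tumor = _min_dist_to(rows, cols, tumor, config.lattice)
    stroma_ring = ~tumor & (d_to_tumor <= 2) & (tumor.sum() > 0)

    # immune region: disc around the spot farthest from the tumor center
    far = np.argmax(np.where(~tumor & ~stroma_ring, d_center, -1))
    d_imm = lattice_distance(rows, cols, rows[far], cols[far], config.lattice)
    immune = ~tumor & ~stroma_ring & (d_imm <= max(3, config.n_rows // 8))

    region_of = np.where(
        tumor, "tumor", np.where(stroma_ring, "stroma_ring",
                                 np.where(immune, "immune", "other"))
    )

    types = reference_profiles.index.to_list()
    profiles = reference_profiles.to_numpy(dtype=float)  # types x genes
    gidx = {g: i for i, g in enumerate(genes)}
    planted = [config.csc_gene, config.fap_gene, *config.mycaf_genes]
    prof_plain = profiles.copy()
    for g in planted:
        if g in gidx:
            prof_plain[:, gidx[g]] = 0.0

    gain_vec = np.ones(len(genes))
    chrom_of = dict(zip(positions["gene"], positions["chrom"]))
    for chrom, mult in config.gain_blocks:
        sel = np.asarray([chrom_of.get(g) == chrom for g in genes])
        gain_vec[sel] *= mult

    lo, hi = config.cells_per_spot
    n_cells_spot = rng.integers(lo, hi + 1, size=n_spots)
    type_counts = np.zeros((n_spots, len(types)), dtype=float)
    tpos = {t: i for i, t in enumerate(types)}
    for i in range(n_spots):
        mix = REGION_MIX[region_of[i]]
        names = [t for t in mix if t in tpos]
        probs = np.asarray([mix[t] for t in names])
        probs = probs / probs.sum()
        draw = rng.multinomial(n_cells_spot[i], probs)
        for t, d in zip(names, draw):
            type_counts[i, tpos[t]] += d

    lam = type_counts @ prof_plain
    # chromosome gains apply to the malignant contribution in tumor spots
    if "malignant" in tpos:
        mcol = tpos["malignant"]
        extra = np.outer(
            type_counts[:, mcol] * tumor, prof_plain[mcol] * (gain_vec - 1.0)
        )
        lam += extra
    lam *= config.depth_factor  # per-cell sequencing depth scaling

    # planted niche genes: region-driven Poisson rates
    csc_rate = np.full(n_spots, BACKGROUND_RATE)
    csc_rate[core] = CSC_CORE_RATE
    csc_rate[boundary] = CSC_CORE_RATE * config.boundary_enrichment
    fap_rate = np.full(n_spots, BACKGROUND_RATE)
    fap_rate[boundary | stroma_ring] = FAP_NICHE_RATE
    if config.csc_gene in gidx:
        lam[:, gidx[config.csc_gene]] = csc_rate
    if config.fap_gene in gidx:
        lam[:, gidx[config.fap_gene]] = fap_rate

    # myCAF program planted in the peritumoral ring and boundary
    niche_mask = boundary | stroma_ring
    mycaf_rate = np.full(n_spots, MYCAF_BACKGROUND_RATE)
    mycaf_rate[niche_mask] = MYCAF_BACKGROUND_RATE * config.mycaf_enrichment
    for g in config.mycaf_genes:
        if g in gidx:
            lam[:, gidx[g]] = mycaf_rate

    counts = rng.poisson(lam).T.astype(np.int64)  # genes x spots

    barcodes = np.asarray(
        [f"SPOT_{r:03d}x{c:03d}" for r, c in zip(rows, cols)], dtype=object
    )
    grid = SpotGrid(
        matrix=ExpressionMatrix(counts=counts, genes=genes, obs_names=barcodes),
        array_row=rows,
        array_col=cols,
        lattice=config.lattice,
    )

    region = np.where(core, "core", np.where(boundary, "boundary", "non_tumor"))
    p_a = 1.0 - np.exp(-csc_rate)
    p_b = 1.0 - np.exp(-fap_rate)
    exp_both = float((p_a * p_b).sum())
    exp_union = float((p_a + p_b - p_a * p_b).sum())
    coloc_class = np.where(
        (csc_rate >= 0.5) & (fap_rate >= 0.5), "A+B+",
        np.where(csc_rate >= 0.5, "A+only",
                 np.where(fap_rate >= 0.5, "B+only", "negative")),
    )
    props = type_counts / n_cells_spot[:, None]
    truth = GroundTruth(
        region=region,
        tumor_mask=tumor,
        coloc_class=coloc_class,
        expected_coloc_percent=100.0 * exp_both / exp_union,
        proportions=pd.DataFrame(props, index=barcodes, columns=types),
    )
    truth.validate_proportions()
    return grid, truth


def _disc_size(config: SpatialSimConfig) -> int:
    """Spot count of an unclipped disc of tumor_radius on the lattice."""
    r = config.tumor_radius
    if config.lattice == "hex":
        return 1 + 3 * r * (r + 1)
    return 2 * r * (r + 1) + 1
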