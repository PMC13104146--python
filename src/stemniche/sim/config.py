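"""Configuration and ground-truth containers for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidConfigError(ValueError):
    pass


@dataclass
class ScSimConfig:
    """Single-cell cohort generator settings.

    A fraction ``frac_malignant`` of cells are malignant and carry a latent
    stemness trait s ~ Uniform(0,1). A planted module of ``module_size``
    genes has its mean scaled by exp(stemness_effect * s) in malignant
    cells; per-cell detection decreases with (1 - s) by ``diversity_effect``
    so stem-like cells express more genes. Malignant cells additionally get
    patient-specific log-normal expression shifts (non-malignant cells mix
    across patients).
    """

    n_cells: int = 2000
    n_genes: int = 1500
    n_samples: int = 4
    frac_malignant: float = 0.75
    module_size: int = 50
    stemness_effect: float = 2.0
    diversity_effect: float = 0.3
    sample_shift_sd: float = 0.3
    nb_dispersion: float = 0.4
    malignant_boost: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_samples) <= 0:
            raise InvalidConfigError("counts must be positive")
        if not (0.0 <= self.frac_malignant < 1.0 or self.frac_malignant == 0.0):
            if not 0.0 <= self.frac_malignant <= 1.0:
                raise InvalidConfigError("frac_malignant must be in [0, 1]")
        if self.module_size > self.n_genes:
            raise InvalidConfigError("module_size exceeds n_genes")
        if self.module_size <= 0:
            raise InvalidConfigError("module_size must be positive")
        if not 0.0 <= self.diversity_effect < 1.0:
            raise InvalidConfigError("diversity_effect must be in [0, 1)")
        if self.stemness_effect < 0 or self.nb_dispersion <= 0:
            raise InvalidConfigError("effects must be non-negative, dispersion positive")


@dataclass
class SpatialSimConfig:
    """Spatial section generator settings.

    A centered disc of ``tumor_radius`` (lattice graph distance) is tumor;
    genes on ``gain_blocks`` chromosomes are multiplied there. The CSC
    marker is enriched in the 2-spot-wide boundary ring, the fibroblast
    marker in the ring plus adjacent stroma, and immune genes concentrate in
    one non-tumor region.
    """

    n_rows: int = 40
    n_cols: int = 40
    lattice: str = "hex"
    tumor_radius: int = 12
    boundary_width: int = 2
    gain_blocks: list = field(default_factory=lambda: [("chr1", 2.0)])
    csc_gene: str = "DSG2"
    fap_gene: str = "FAP"
    immune_genes: tuple = ("PTPRC", "CD2", "CD3D", "CD3E", "CD3G",
                           "CD79A", "MS4A1", "CD79B", "CD68", "CD14")
    epithelial_genes: tuple = ("EPCAM", "KRT8", "KRT19")
    boundary_enrichment: float = 6.0
    mycaf_genes: tuple = ("ACTA2", "TAGLN", "POSTN", "MYL9")
    mycaf_enrichment: float = 8.0
    cells_per_spot: tuple = (1, 10)
    depth_factor: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.tumor_radius < 0:
            raise InvalidConfigError("tumor_radius must be >= 0")
        if self.lattice not in ("hex", "square"):
            raise InvalidConfigError("lattice must be hex or square")
        for _, mult in self.gain_blocks:
            if mult <= 0:
                raise InvalidConfigError("gain multiplier must be > 0")
        if self.boundary_enrichment <= 0:
            raise InvalidConfigError("boundary_enrichment must be > 0")
        lo, hi = self.cells_per_spot
        if lo < 1 or hi < lo:
            raise InvalidConfigError("cells_per_spot range invalid")
        if self.depth_factor <= 0:
            raise InvalidConfigError("depth_factor must be > 0")
        if self.mycaf_enrichment <= 0:
            raise InvalidConfigError("mycaf_enrichment must be > 0")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each simulated dataset."""

    # single-cell fields
    stemness: np.ndarray | None = None           # per-malignant-cell, [0,1]
    malignant_mask: np.ndarray | None = None     # per-cell bool
    module_genes: list | None = None
    cell_types: np.ndarray | None = None
    # spatial fields
    region: np.ndarray | None = None             # core / boundary / non_tumor
    tumor_mask: np.ndarray | None = None
    coloc_class: np.ndarray | None = None        # A+B+ / A+only / B+only / negative
    expected_coloc_percent: float | None = None
    proportions: pd.DataFrame | None = None      # spot x cell-type, rows sum to 1

    def validate_proportions(self, tol: float = 1e-9) -> None:
        if self.proportions is not None:
            sums = self.proportions.sum(axis=1).to_numpy()
            if np.any(np.abs(sums - 1.0) > tol):
                raise AssertionError("ground-truth proportions do not sum to 1")
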