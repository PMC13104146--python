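"""Core containers: expression matrices and spatial spot grids.

Matrices are stored genes x observations (cells or spots), matching the
orientation of the MTX exchange format used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


def _as_dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class ExpressionMatrix:
    """Gene x observation count matrix with observation metadata.

    Parameters
    ----------
    counts
        Non-negative count matrix, shape ``(n_genes, n_obs)``. Dense or
        scipy sparse; densified on access where needed.
    genes
        Gene identifiers, length ``n_genes``, unique.
    obs_names
        Observation (cell/spot) barcodes, length ``n_obs``, unique.
    labels
        Optional per-observation categorical labels (cell type, group).
    samples
        Optional per-observation sample/patient identifiers.
    """

    counts: np.ndarray
    genes: np.ndarray
    obs_names: np.ndarray
    labels: np.ndarray | None = None
    samples: np.ndarray | None = None
    _norm_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.obs_names = np.asarray(self.obs_names, dtype=object)
        if self.counts.shape != (len(self.genes), len(self.obs_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.obs_names)} observations"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=object)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_obs(self) -> int:
        return len(self.obs_names)

    def dense_counts(self) -> np.ndarray:
        return _as_dense(self.counts)

    def obs_totals(self) -> np.ndarray:
        c = self.counts
        if sparse.issparse(c):
            return np.asarray(c.sum(axis=0)).ravel()
        return np.asarray(c).sum(axis=0)

    def normalized(self, log: bool = True, target_sum: float | None = None) -> np.ndarray:
        """Depth-normalize each observation to ``target_sum`` (default: the
        median library size), optionally log1p-transformed. Result is dense,
        genes x obs. Cached per (log, target_sum)."""
        key = (log, target_sum)
        if key in self._norm_cache:
            return self._norm_cache[key]
        totals = self.obs_totals().astype(float)
        if np.any(totals <= 0):
            bad = self.obs_names[np.where(totals <= 0)[0][0]]
            raise ValueError(f"observation {bad!r} has zero total counts")
        tsum = float(np.median(totals)) if target_sum is None else float(target_sum)
        x = _as_dense(self.counts) * (tsum / totals)[None, :]
        if log:
            x = np.log1p(x)
        self._norm_cache[key] = x
        return x

    def gene_index(self, names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        idx = [lookup[n] for n in names if n in lookup]
        return np.asarray(idx, dtype=int)

    def subset_obs(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        c = self.counts
        c = c.tocsc()[:, idx] if sparse.issparse(c) else c[:, idx]
        return ExpressionMatrix(
            counts=c,
            genes=self.genes.copy(),
            obs_names=self.obs_names[idx],
            labels=None if self.labels is None else self.labels[idx],
            samples=None if self.samples is None else self.samples[idx],
        )

    def subset_genes(self, names) -> "ExpressionMatrix":
        idx = self.gene_index(names)
        c = self.counts
        c = c.tocsr()[idx, :] if sparse.issparse(c) else c[idx, :]
        return ExpressionMatrix(
            counts=c,
            genes=self.genes[idx],
            obs_names=self.obs_names.copy(),
            labels=self.labels,
            samples=self.samples,
        )


@dataclass
class SpotGrid:
    """Spatial section: an :class:`ExpressionMatrix` over spots plus integer
    array coordinates on a hex (Visium-like, 6-neighbor) or square
    (4-neighbor) lattice."""

    matrix: ExpressionMatrix
    array_row: np.ndarray
    array_col: np.ndarray
    lattice: str = "hex"

    def __post_init__(self) -> None:
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        n = self.matrix.n_obs
        if len(self.array_row) != n or len(self.array_col) != n:
            raise ValueError("coordinate arrays must match number of spots")
        if self.lattice not in ("hex", "square"):
            raise ValueError(f"unknown lattice type {self.lattice!r}")
        coords = list(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate spot coordinates")

    @property
    def n_spots(self) -> int:
        return self.matrix.n_obs

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.matrix.obs_names,
                "array_row": self.array_row,
                "array_col": self.array_col,
            }
        )
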