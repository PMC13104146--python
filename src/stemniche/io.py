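"""Readers and writers for the plain-text exchange formats used by the
pipeline: MTX + genes/barcodes TSV matrix directories, spot-coordinate TSV,
gene-position TSV, GMT gene sets, and ligand-receptor pair tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix, SpotGrid


def write_matrix_dir(matrix: ExpressionMatrix, outdir: str) -> None:
    """Write matrix.mtx, genes.tsv, barcodes.tsv (and labels/samples columns
    in barcodes.tsv when present) to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    counts = matrix.counts
    if not sparse.issparse(counts):
        counts = sparse.csr_matrix(counts)
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), counts)
    pd.Series(matrix.genes).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    bc = pd.DataFrame({"barcode": matrix.obs_names})
    if matrix.labels is not None:
        bc["label"] = matrix.labels
    if matrix.samples is not None:
        bc["sample"] = matrix.samples
    bc.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)


def read_matrix_dir(indir: str) -> ExpressionMatrix:
    counts = spio.mmread(os.path.join(indir, "matrix.mtx")).tocsr()
    genes = pd.read_csv(
        os.path.join(indir, "genes.tsv"), sep="\t", header=None
    )[0].to_numpy(dtype=object)
    bc = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")
    if "barcode" not in bc.columns:  # headerless fallback
        bc = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)
        bc.columns = ["barcode"] + [f"c{i}" for i in range(1, bc.shape[1])]
    return ExpressionMatrix(
        counts=counts,
        genes=genes,
        obs_names=bc["barcode"].to_numpy(dtype=object),
        labels=bc["label"].to_numpy(dtype=object) if "label" in bc.columns else None,
        samples=bc["sample"].to_numpy(dtype=object) if "sample" in bc.columns else None,
    )


def write_spot_grid(grid: SpotGrid, outdir: str) -> None:
    write_matrix_dir(grid.matrix, outdir)
    df = grid.coords_frame()
    df["lattice"] = grid.lattice
    df.to_csv(os.path.join(outdir, "spots.tsv"), sep="\t", index=False)


def read_spot_grid(indir: str) -> SpotGrid:
    matrix = read_matrix_dir(indir)
    df = pd.read_csv(os.path.join(indir, "spots.tsv"), sep="\t")
    order = {b: i for i, b in enumerate(df["barcode"])}
    idx = np.asarray([order[b] for b in matrix.obs_names])
    lattice = str(df["lattice"].iloc[0]) if "lattice" in df.columns else "hex"
    return SpotGrid(
        matrix=matrix,
        array_row=df["array_row"].to_numpy()[idx],
        array_col=df["array_col"].to_numpy()[idx],
        lattice=lattice,
    )


def write_gene_positions(positions: pd.DataFrame, path: str) -> None:
    """``positions``: columns gene, chrom, start."""
    positions[["gene", "chrom", "start"]].to_csv(path, sep="\t", index=False)


def read_gene_positions(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "chrom", "start"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "chrom", "start"])
    if df["gene"].duplicated().any():
        raise ValueError("duplicate genes in position table")
    if (df["start"] < 0).any():
        raise ValueError("gene start positions must be >= 0")
    return df


def write_gmt(gene_sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_lr_table(path: str) -> pd.DataFrame:
    """Ligand-receptor table: pathway, ligand, receptor; multi-subunit
    complexes comma-joined."""
    df = pd.read_csv(path, sep="\t")
    required = {"pathway", "ligand", "receptor"}
    if not required <= set(df.columns):
        raise ValueError(f"LR table needs columns {sorted(required)}")
    return df


def package_data_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "data", name)
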