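# stemniche

Cancer-stem-cell (CSC) signature discovery from single-cell RNA-seq and
tumor-boundary niche analysis in spatial transcriptomics, packaged as a
tested, reusable pipeline with a synthetic-data generator standing in for
the original cohorts.

## What it does

**Single-cell arm** — from a labeled gene x cell count matrix:

1. `stemness.diversity_score` — transcriptional-diversity stemness score
   per cell (detected-gene correlation + kNN smoothing, rank-scaled to
   [0, 1]); `stemness.signature_auc` — ranking recovery-curve AUC of a gene
   signature per cell.
2. `metacell` — bootstrap co-clustering of malignant cells on a mutual-kNN
   graph and a hierarchical cut into metacells (minimum size enforced),
   aggregated by member averaging.
3. `network` — weighted co-expression network on the metacell matrix:
   soft-threshold selection by scale-free fit, topological-overlap matrix,
   average-linkage module detection, module eigengenes, eigengene-trait
   correlation, malignant-marker testing (log fold change + Wilcoxon), and
   the CSC signature as the intersection of the top stemness-correlated
   module with the malignant markers.

**Spatial arm** — from a spot x gene count matrix on a Visium-like lattice:

4. `cnv` — spot clustering (Leiden), immune-score reference-cluster
   selection, windowed CNV inference against the reference, per-spot CNV
   scores, and malignant-cluster calling (Ward clusters whose mean CNV
   profile deviates from the reference).
5. `niche` — tumor boundary as the 2-spot-wide ring by lattice BFS
   distance, boundary-vs-core testing (Mann-Whitney), two-gene
   co-localization percentages, NNLS deconvolution against reference
   profiles (a simplification of CARD — no spatial prior), and CAF-subtype
   scoring from shipped GMT signatures.
6. `communication` — ligand-receptor scoring between groups with a
   saturating probability P = LR/(kh + LR) (geometric-mean subunit
   combination), permutation p-values, and pathway/sender/receiver
   aggregation. This is a deliberate simplification of CellChat's model.
7. `stats` — Mann-Whitney (exact for small samples), ROC-AUC, log-rank,
   Pike hazard ratio, and maximally-selected-rank cutpoints (reported
   p-values are not selection-adjusted; flagged in output).

**Synthetic data** (`sim`) — first-class generators with ground truth:
negative-binomial single-cell cohorts with a continuous planted stemness
trait driving a co-expressed module and detection rates, patient-specific
malignant shifts, Visium-like sections with a tumor disc carrying
chromosome gains, a boundary-enriched CSC marker, a peritumoral
fibroblast/myCAF program, an immune-rich region, and survival tables with
a biomarker-dependent hazard.

## CLI

```bash
stemniche simulate sc --out data/sc --seed 1
stemniche simulate spatial --sc data/sc --out data/sp --seed 2
stemniche simulate survival --n 500 --log-hr 0.7 --censor-rate 0.2 --out surv.csv --seed 3

stemniche stemness --matrix data/sc --signature data/sc/truth_module.gmt --out scores.tsv
stemniche signature --matrix data/sc --min-size 40 --n-boot 30 --out sigout
stemniche spatial cnv --grid data/sp --genes data/sp/gene_positions.tsv --out cnvout
stemniche niche --grid data/sp --tumor-labels data/sp/truth_spots.tsv --out nicheout
stemniche communicate --matrix data/sc --n-perm 100 --out commout
stemniche biomarker --survival surv.csv --mode maxstat --out bioout
```

All matrices travel as MTX + `genes.tsv`/`barcodes.tsv` directories; spot
coordinates as `spots.tsv` (barcode, array_row, array_col, lattice); gene
positions as TSV (gene, chrom, start); signatures as GMT.

## Scale notes

Printed full-scale parameters (bootstrap count 500, kNN 100, minimum
metacell size 50) are sized for cohorts of tens of thousands of cells and
are the config defaults; the test suite and acceptance script run
desk-scale equivalents (documented in `tests/conftest.py` and
`scripts/acceptance.py`) so that the whole pipeline finishes in minutes.
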