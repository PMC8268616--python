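"""Readers, writers, QC and normalization for single-cell and bulk expression data.

The single-cell container is a thin wrapper around a sparse genes x cells UMI
count matrix plus a per-cell annotation table (patient, sample, tissue, site,
major cell type, subcluster).  Bulk cohorts are samples x genes expression
frames with a clinical table (overall survival, age, FIGO stage, debulking).
Copy-number profiles are BED-like segment tables (0-based half-open
coordinates internally).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import EmptyResultError, FormatError, ValidationError

log = logging.getLogger(__name__)

CELL_META_COLUMNS = ["patient_id", "sample_id", "tissue_type", "site",
                     "major_cell_type", "subcluster"]
CLINICAL_COLUMNS = ["os_days", "os_event", "age", "stage", "debulking"]


@dataclass
class SingleCellMatrix:
    """Genes x cells raw UMI counts with per-cell annotations.

    ``counts`` is sparse CSR; ``cell_meta`` is indexed by barcode and carries
    :data:`CELL_META_COLUMNS`.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells")
        if (self.counts.data < 0).any():
            raise ValidationError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene symbols")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell barcodes")
        missing = [b for b in self.cell_ids if b not in self.cell_meta.index]
        if missing:
            raise ValidationError(f"cells absent from metadata: {missing[:5]}")
        self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def subclusters(self) -> pd.Series:
        return self.cell_meta["subcluster"]


@dataclass
class BulkCohort:
    """One bulk expression study: samples x genes plus clinical covariates."""

    cohort_id: str
    expr: pd.DataFrame                      # samples x genes
    clinical: pd.DataFrame | None = None    # indexed by sample

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValidationError(f"{self.cohort_id}: duplicate sample ids")
        if self.clinical is not None:
            if not self.expr.index.equals(self.clinical.index):
                raise ValidationError(
                    f"{self.cohort_id}: expression and clinical sample ids differ")
            if (self.clinical["os_days"] <= 0).any():
                raise ValidationError(f"{self.cohort_id}: os_days must be > 0")
            if not self.clinical["os_event"].isin([0, 1]).all():
                raise ValidationError(f"{self.cohort_id}: os_event must be 0/1")

    @property
    def samples(self) -> pd.Index:
        return self.expr.index

    @property
    def genes(self) -> pd.Index:
        return self.expr.columns


@dataclass
class CNProfile:
    """Genome-wide copy-number segments, 0-based half-open coordinates."""

    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        seg = pd.DataFrame(self.segments,
                           columns=["chrom", "start", "end", "copy_number"])
        if (seg["start"] >= seg["end"]).any():
            raise ValidationError("segment with start >= end")
        if (seg["copy_number"] < 0).any():
            raise ValidationError("negative copy number")
        for chrom, grp in seg.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValidationError(f"overlapping segments on {chrom}")
        self.segments = seg.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# 10x-style MTX triplet I/O

def read_10x_matrix(mtx_path, genes_path, barcodes_path, meta_path) -> SingleCellMatrix:
    """Read an MTX triplet plus a barcode-keyed annotation TSV.

    Genes files with two columns (id, symbol) use the symbol column.
    Every barcode must have a metadata record.
    """
    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # malformed header/entries
        raise FormatError(f"cannot parse MTX file {mtx_path}: {exc}") from exc
    genes_tab = pd.read_csv(genes_path, sep="\t", header=None)
    genes = genes_tab.iloc[:, -1].astype(str).values
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).values
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX declares {counts.shape} but gene/barcode lists have "
            f"{len(genes)} x {len(barcodes)} entries")
    meta = pd.read_csv(meta_path, sep="\t")
    meta = meta.rename(columns={"barcode": "barcode", "patient": "patient_id",
                                "sample": "sample_id", "tissue": "tissue_type",
                                "cell_type": "major_cell_type"})
    if meta["barcode"].duplicated().any():
        dups = meta.loc[meta["barcode"].duplicated(), "barcode"].tolist()
        raise ValidationError(f"duplicate barcodes in metadata: {dups[:5]}")
    meta = meta.set_index("barcode")
    return SingleCellMatrix(counts, genes, barcodes, meta)


def write_10x_matrix(matrix: SingleCellMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"),
                     sp.coo_matrix(matrix.counts), field="integer")
    pd.Series(matrix.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    meta = matrix.cell_meta.copy()
    meta.index.name = "barcode"
    meta = meta.rename(columns={"patient_id": "patient", "sample_id": "sample",
                                "tissue_type": "tissue",
                                "major_cell_type": "cell_type"})
    meta.to_csv(outdir / "meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# QC and normalization

def qc_filter(matrix: SingleCellMatrix, min_cells_per_gene: int = 10,
              min_genes: int = 200, max_genes: int = 6000,
              max_mito_frac: float = 0.15) -> SingleCellMatrix:
    """Drop rarely detected genes, then low-quality cells.

    A gene is kept when detected (count >= 1) in at least ``min_cells_per_gene``
    cells; a cell when its detected-gene count (on the gene-filtered matrix)
    lies in [min_genes, max_genes] and its mitochondrial UMI fraction (symbols
    with case-insensitive prefix ``MT-``) is at most ``max_mito_frac``.
    Idempotent.
    """
    detected = matrix.counts > 0
    gene_keep = np.asarray(detected.sum(axis=1)).ravel() >= min_cells_per_gene
    counts = matrix.counts[gene_keep]
    genes = matrix.gene_ids[gene_keep]

    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    is_mito = np.array([g.upper().startswith("MT-") for g in genes])
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts[is_mito].sum(axis=0)).ravel() if is_mito.any() \
        else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 0.0)
    cell_keep = ((genes_per_cell >= min_genes) & (genes_per_cell <= max_genes)
                 & (mito_frac <= max_mito_frac))
    if not cell_keep.any():
        raise EmptyResultError("QC removed every cell")
    log.info("qc_filter: kept %d/%d genes, %d/%d cells",
             gene_keep.sum(), matrix.n_genes, cell_keep.sum(), matrix.n_cells)
    return SingleCellMatrix(counts[:, cell_keep], genes,
                            matrix.cell_ids[cell_keep],
                            matrix.cell_meta.loc[matrix.cell_ids[cell_keep]])


def normalize(matrix: SingleCellMatrix) -> sp.csr_matrix:
    """Counts-per-10k log normalization: log(1 + 1e4 * count / cell_total).

    Zeros stay zero, so the result remains sparse.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValidationError("cell with zero total counts (run qc_filter first)")
    out = sp.csr_matrix(matrix.counts, dtype=float)
    out = out.multiply(1e4 / totals[np.newaxis, :]).tocsr()
    out.data = np.log1p(out.data)
    return out


# ---------------------------------------------------------------------------
# Bulk cohorts

def collapse_duplicate_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene symbol, the row with highest total expression.

    ``expr`` is genes x samples.
    """
    if not expr.index.has_duplicates:
        return expr
    totals = expr.sum(axis=1).values
    pos = pd.Series(np.arange(len(expr)), index=expr.index)
    best = pos.groupby(level=0, sort=False).apply(
        lambda s: s.iloc[int(np.argmax(totals[s.values]))])
    return expr.iloc[np.sort(best.values)]


def read_bulk_cohort(expr_path, clinical_path, cohort_id: str) -> BulkCohort:
    """Read a genes x samples expression TSV and its clinical table.

    Samples missing any of age, stage, debulking, os_days or os_event are
    dropped (the drop count is logged); remaining ids must match the
    expression columns.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr = collapse_duplicate_genes(expr)
    clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing_cols:
        raise ValidationError(f"{cohort_id}: clinical table lacks {missing_cols}")
    before = len(clin)
    clin = clin.dropna(subset=CLINICAL_COLUMNS)
    dropped = before - len(clin)
    if dropped:
        log.info("%s: dropped %d samples with incomplete clinical data",
                 cohort_id, dropped)
    extra = set(clin.index) - set(expr.columns)
    if extra:
        raise ValidationError(f"{cohort_id}: clinical samples missing from "
                              f"expression: {sorted(extra)[:5]}")
    expr = expr[clin.index].T  # -> samples x genes
    return BulkCohort(cohort_id, expr, clin)


def write_bulk_cohort(cohort: BulkCohort, expr_path, clinical_path) -> None:
    cohort.expr.T.to_csv(expr_path, sep="\t")
    cohort.clinical.to_csv(clinical_path, sep="\t")


def read_cn_profile(path, one_based: bool = False) -> CNProfile:
    """Read a 4-column segment TSV (chrom, start, end, copy_number).

    Set ``one_based`` when the file uses 1-based inclusive coordinates; they
    are converted to the internal 0-based half-open convention.
    """
    seg = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "copy_number"],
                      comment="#")
    if one_based:
        seg["start"] = seg["start"] - 1
    return CNProfile(seg)
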