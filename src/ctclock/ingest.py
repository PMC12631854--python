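"""Reading expression matrices and applying nucleus-level QC.

Supports the 10x-style on-disk convention (MatrixMarket triplet with
``features.tsv`` rows and ``barcodes.tsv`` columns, plus optional
``cells.tsv`` / ``donors.tsv`` metadata) and a dense genes x cells TSV for
toy inputs.  QC retains nuclei with total counts in [min_counts,
max_counts] and detected genes in [min_genes, max_genes] (inclusive
bounds) and mitochondrial fraction strictly below the cut-off; flagged
mitochondrial and sex-chromosome genes are removed before modeling.
Log-normalization is counts-per-scale (CP10K by default) followed by
log1p, the standard Seurat/scanpy transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    LOG_NORMALIZED,
    RAW_COUNTS,
    CellMatrix,
    QCThresholds,
    ValidationError,
    validate_cell_table,
    validate_donor_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(path, matrix: CellMatrix, cells: pd.DataFrame | None = None,
                 donors: pd.DataFrame | None = None) -> None:
    """Write a cohort in the 10x-style layout (matrix.mtx + TSV sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(matrix.values))
    feats = matrix.genes.reset_index()[["gene_id", "mito", "sex"]]
    feats.to_csv(path / "features.tsv", sep="\t", index=False)
    pd.Series(matrix.cell_ids, name="cell_id").to_csv(
        path / "barcodes.tsv", sep="\t", index=False
    )
    if cells is not None:
        cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    if donors is not None:
        donors.to_csv(path / "donors.tsv", sep="\t", index=False)


def read_matrix(path) -> tuple[CellMatrix, pd.DataFrame | None]:
    """Read a matrix directory (MatrixMarket triplet) or a dense TSV file.

    Returns the raw-count :class:`CellMatrix` plus the cell annotation
    table when a ``cells.tsv`` sidecar exists (``None`` otherwise).  Row
    and column order are preserved from the files.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    return _read_dense_tsv(path), None


def read_donors(path) -> pd.DataFrame:
    donors = pd.read_csv(Path(path), sep="\t")
    return validate_donor_table(donors)


def _read_mtx_dir(path: Path) -> tuple[CellMatrix, pd.DataFrame | None]:
    mtx_path = path / "matrix.mtx"
    if not mtx_path.exists():
        raise ValidationError(f"no matrix.mtx under {path}")
    values = scipy.io.mmread(str(mtx_path)).tocsc()
    feats = pd.read_csv(path / "features.tsv", sep="\t")
    if "gene_id" not in feats.columns:  # headerless 10x-style triplet
        feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        feats = feats.rename(columns={0: "gene_id"})
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t")
    if "cell_id" not in barcodes.columns:
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
        barcodes = barcodes.rename(columns={0: "cell_id"})
    if values.shape[0] != len(feats):
        raise ValidationError(
            f"matrix has {values.shape[0]} rows but features.tsv lists "
            f"{len(feats)} genes"
        )
    if values.shape[1] != len(barcodes):
        raise ValidationError(
            f"matrix has {values.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} cells"
        )
    genes = feats.set_index("gene_id")
    for flag in ("mito", "sex"):
        if flag in genes.columns:
            genes[flag] = genes[flag].astype(bool)
        else:
            genes[flag] = False
    matrix = CellMatrix(
        values=values,
        genes=genes[["mito", "sex"]],
        cell_ids=pd.Index(barcodes["cell_id"]),
        state=RAW_COUNTS,
    )
    cells_path = path / "cells.tsv"
    cells = None
    if cells_path.exists():
        cells = validate_cell_table(pd.read_csv(cells_path, sep="\t"), matrix)
    return matrix, cells


def _read_dense_tsv(path: Path) -> CellMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        raise ValidationError(f"negative counts in {path}")
    return CellMatrix(
        values=values,
        genes=pd.DataFrame(index=pd.Index(df.index, name="gene_id")),
        cell_ids=pd.Index(df.columns, name="cell_id"),
        state=RAW_COUNTS,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

QC_METRICS = ("total_counts", "n_genes_detected", "mito_fraction")


def _ensure_metrics(matrix: CellMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    """Fill in QC metric columns from the matrix where the table lacks them.

    Supplied values win over recomputation, which lets toy fixtures pin
    metrics directly.
    """
    cells = cells.copy()
    order = matrix.cell_ids.get_indexer(cells["cell_id"])
    if (order < 0).any():
        raise ValidationError("cell table contains ids absent from the matrix")
    computed = {
        "total_counts": matrix.total_counts()[order],
        "n_genes_detected": matrix.n_genes_detected()[order],
        "mito_fraction": matrix.mito_fraction()[order],
    }
    for col, vals in computed.items():
        if col not in cells.columns:
            cells[col] = vals
        else:
            cells[col] = cells[col].fillna(pd.Series(vals, index=cells.index))
    return cells


def qc_filter(
    matrix: CellMatrix,
    cells: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CellMatrix, pd.DataFrame, dict]:
    """Drop nuclei failing the QC gates; returns per-filter removal counts.

    Count and gene bounds are inclusive; the mitochondrial-fraction gate is
    strict (a cell at exactly the cut-off is removed).
    """
    if matrix.state != RAW_COUNTS:
        raise ValidationError("qc_filter expects raw counts")
    cells = _ensure_metrics(matrix, validate_cell_table(cells, matrix))
    t = thresholds
    ok_counts = cells["total_counts"].between(t.min_counts, t.max_counts)
    ok_genes = cells["n_genes_detected"].between(t.min_genes, t.max_genes)
    ok_mito = cells["mito_fraction"] < t.max_mito_fraction
    keep = ok_counts & ok_genes & ok_mito
    report = {
        "n_input": len(cells),
        "removed_counts": int((~ok_counts).sum()),
        "removed_genes_detected": int((~ok_genes).sum()),
        "removed_mito": int((~ok_mito).sum()),
        "n_kept": int(keep.sum()),
    }
    logger.info("qc_filter: %s", report)
    if report["n_kept"] == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    kept_cells = cells.loc[keep].reset_index(drop=True)
    kept_matrix = matrix.subset_cells(kept_cells["cell_id"].to_numpy())
    return kept_matrix, kept_cells, report


def log_normalize(matrix: CellMatrix, scale: float = 10_000.0) -> CellMatrix:
    """CP-scale + log1p: entry (g,c) -> ln(1 + count/total_c * scale)."""
    if matrix.state != RAW_COUNTS:
        raise ValidationError("log_normalize expects raw counts")
    totals = matrix.total_counts()
    zero = totals <= 0
    if zero.any():
        ids = list(matrix.cell_ids[zero][:10])
        raise ValidationError(f"cells with zero total counts: {ids}")
    if sp.issparse(matrix.values):
        vals = matrix.values.tocsc().astype(float)
        # scale each column, then log1p on stored entries (zeros unchanged)
        vals = vals @ sp.diags(scale / totals)
        vals.data = np.log1p(vals.data)
    else:
        vals = np.log1p(np.asarray(matrix.values, dtype=float) / totals * scale)
    return replace(matrix, values=vals, state=LOG_NORMALIZED)


def drop_mito_sex_genes(matrix: CellMatrix) -> CellMatrix:
    """Remove flagged mitochondrial and sex-related genes, preserving order."""
    flagged = (matrix.genes["mito"] | matrix.genes["sex"]).to_numpy()
    if flagged.all() and len(flagged):
        warnings.warn("all genes flagged; result has zero genes", stacklevel=2)
    logger.info("drop_mito_sex_genes: removing %d of %d genes",
                int(flagged.sum()), matrix.n_genes)
    return matrix.subset_genes(~flagged)


def identify_mito_sex_genes(
    matrix: CellMatrix,
    mito_prefix: str = "MT-",
    sex_genes: list[str] | None = None,
) -> CellMatrix:
    """Set mito/sex flags from gene names for datasets without explicit flags.

    Mitochondrial genes are matched by the ``MT-`` prefix; sex-related
    genes by an explicit chrX/chrY gene list.
    """
    genes = matrix.genes.copy()
    genes["mito"] = genes["mito"] | genes.index.str.startswith(mito_prefix)
    if sex_genes:
        genes["sex"] = genes["sex"] | genes.index.isin(sex_genes)
    return replace(matrix, genes=genes)
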