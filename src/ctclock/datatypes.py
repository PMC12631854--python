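"""Core containers for the snRNA-seq aging-clock pipeline.

The pipeline moves a genes x cells expression matrix (:class:`CellMatrix`)
together with per-cell (:class:`CellTable` columns) and per-donor metadata
through QC, normalization, pseudobulk aggregation and model fitting.  Cell
and donor metadata are plain :class:`pandas.DataFrame` objects validated by
the functions below; the matrix gets a thin dataclass so that its
normalization state and gene flags travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"

#: The six major cortical cell types modeled by the clocks.
MAJOR_CELL_TYPES = (
    "oligodendrocyte",
    "astrocyte",
    "microglia",
    "OPC",
    "excitatory_neuron",
    "inhibitory_neuron",
)

#: Aggregation levels for non-cell-type-specific clocks.
LEVELS = {
    "glia": ("oligodendrocyte", "astrocyte", "OPC"),
    "neuron": ("excitatory_neuron", "inhibitory_neuron"),
    "all_cells": MAJOR_CELL_TYPES,
}

CELL_TABLE_COLUMNS = ("cell_id", "donor_id", "cell_type")
DONOR_TABLE_COLUMNS = ("donor_id", "age", "sex", "pmi", "condition")


class ValidationError(ValueError):
    """Raised when a container violates one of its declared invariants."""


@dataclass
class CellMatrix:
    """Genes x cells expression matrix with gene flags and a normalization state.

    Parameters
    ----------
    values
        Non-negative expression values, shape ``(n_genes, n_cells)``.  Raw
        counts or log-normalized values depending on ``state``.  Sparse
        (CSR/CSC) or dense.
    genes
        Gene annotation frame indexed by unique gene id, with boolean
        columns ``mito`` and ``sex`` flagging genes slated for removal.
    cell_ids
        Unique cell/barcode identifiers, one per matrix column.
    state
        ``"raw_counts"`` or ``"log_normalized"``.  The only legal transition
        is raw -> log-normalized (performed by
        :func:`ctclock.ingest.log_normalize`).
    """

    values: sp.spmatrix | np.ndarray
    genes: pd.DataFrame
    cell_ids: pd.Index
    state: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if not isinstance(self.genes, pd.DataFrame):
            self.genes = pd.DataFrame(index=pd.Index(self.genes, name="gene_id"))
        for flag in ("mito", "sex"):
            if flag not in self.genes.columns:
                self.genes[flag] = False
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.state not in (RAW_COUNTS, LOG_NORMALIZED):
            raise ValidationError(f"unknown matrix state {self.state!r}")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.genes):
            raise ValidationError(
                f"matrix has {n_genes} rows but {len(self.genes)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if self.genes.index.has_duplicates:
            dup = self.genes.index[self.genes.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dup[:5])}")
        if self.cell_ids.has_duplicates:
            dup = self.cell_ids[self.cell_ids.duplicated()].unique()
            raise ValidationError(f"duplicate cell ids: {list(dup[:5])}")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and float(np.min(data)) < 0:
            raise ValidationError("expression values must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Expression as a dense ``(genes, cells)`` float array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def total_counts(self) -> np.ndarray:
        """Per-cell column sums."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return np.asarray(self.values).sum(axis=0)

    def n_genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with nonzero expression."""
        if sp.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=0)).ravel()
        return (np.asarray(self.values) > 0).sum(axis=0)

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts in mito-flagged genes (0 where total 0)."""
        totals = self.total_counts()
        mask = np.asarray(self.genes["mito"].values, dtype=bool)
        if sp.issparse(self.values):
            mito = np.asarray(self.values[mask, :].sum(axis=0)).ravel()
        else:
            mito = np.asarray(self.values)[mask, :].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray | Iterable[str]) -> "CellMatrix":
        """Return a matrix restricted to the given cells (bool mask or ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cell_ids.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5]
                raise ValidationError(f"unknown cell ids: {list(missing)}")
        vals = self.values.tocsc()[:, idx] if sp.issparse(self.values) else self.values[:, idx]
        return replace(self, values=vals, cell_ids=self.cell_ids[idx])

    def subset_genes(self, keep: np.ndarray | Iterable[str]) -> "CellMatrix":
        """Return a matrix restricted to the given genes (bool mask or ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.genes.index.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5]
                raise ValidationError(f"unknown gene ids: {list(missing)}")
        vals = self.values.tocsr()[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return replace(self, values=vals, genes=self.genes.iloc[idx])


def validate_cell_table(cells: pd.DataFrame, matrix: CellMatrix | None = None) -> pd.DataFrame:
    """Check a per-cell annotation table (cell_id, donor_id, cell_type, QC metrics)."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise ValidationError("cell table has duplicate cell_id values")
    if matrix is not None:
        unknown = ~cells["cell_id"].isin(matrix.cell_ids)
        if unknown.any():
            raise ValidationError(
                f"{int(unknown.sum())} cell table rows not present in the matrix"
            )
    return cells


def validate_donor_table(donors: pd.DataFrame) -> pd.DataFrame:
    """Check a per-donor covariate table (age, sex, PMI, condition...)."""
    missing = [c for c in DONOR_TABLE_COLUMNS if c not in donors.columns]
    if missing:
        raise ValidationError(f"donor table missing columns: {missing}")
    if donors["donor_id"].duplicated().any():
        raise ValidationError("donor table has duplicate donor_id values")
    if (donors["age"] <= 0).any():
        raise ValidationError("donor ages must be positive")
    bad = ~donors["condition"].isin(["control", "disease"])
    if bad.any():
        raise ValidationError(
            f"condition must be control/disease; offending rows: {int(bad.sum())}"
        )
    return donors


@dataclass(frozen=True)
class QCThresholds:
    """Nucleus-level inclusion thresholds.

    Defaults follow the standard frozen-cortex snRNA-seq gates: total read
    counts within [1200, 100000], detected genes within [800, 12000]
    (both bounds inclusive), and mitochondrial fraction strictly below 5%.
    """

    min_counts: float = 1200
    max_counts: float = 100_000
    min_genes: int = 800
    max_genes: int = 12_000
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_counts >= self.max_counts:
            raise ValidationError("min_counts must be < max_counts")
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must lie in (0, 1]")


@dataclass
class PseudobulkSet:
    """A set of aggregated expression samples.

    ``expression`` is samples x genes (rows indexed by sample id, columns by
    gene id); ``meta`` carries one row per sample with ``sample_id``,
    ``donor_id``, ``unit`` (cell type or level), ``replicate`` (0 for simple
    pseudobulk and single cells), ``n_cells_used`` and
    ``sampled_with_replacement``.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.expression) != len(self.meta):
            raise ValidationError("expression and meta row counts differ")
        if not (self.meta["n_cells_used"] >= 1).all():
            raise ValidationError("every pseudobulk sample must use >= 1 cell")

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_samples(self) -> int:
        return len(self.expression)
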