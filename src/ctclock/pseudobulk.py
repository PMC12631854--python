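"""Pseudobulk aggregation: simple per-donor means and bootstrapped samples.

Simple pseudobulk averages the log-normalized expression of all of a
donor's cells of a given cell type (or level), yielding one sample per
donor.  Bootstrapped pseudobulk instead draws ``n_replicates`` random
subsets of ``k`` cells per donor and averages each, yielding many samples
per donor and so restoring variance the simple average removes.  ``k`` is
chosen per unit from a candidate grid so that at least 80% of donors have
more cells than ``k`` available (the donor-coverage rule); donors with
fewer than ``k`` cells are sampled with replacement and flagged.

Units are either one of the six major cell types or an aggregation level:
``glia`` (oligodendrocytes, astrocytes, OPCs), ``neuron`` (excitatory +
inhibitory neurons) or ``all_cells``.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    LEVELS,
    LOG_NORMALIZED,
    CellMatrix,
    PseudobulkSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default cells-per-sample for each unit (donor-coverage calibrated).
DEFAULT_K = {
    "oligodendrocyte": 200,
    "astrocyte": 50,
    "microglia": 50,
    "OPC": 50,
    "excitatory_neuron": 100,
    "inhibitory_neuron": 100,
    "glia": 100,
    "neuron": 100,
    "all_cells": 100,
}

#: Candidate grid scanned by :func:`choose_k`.
K_GRID = (25, 50, 100, 200, 500)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrapped-pseudobulk sampling parameters."""

    k_per_unit: dict = field(default_factory=lambda: dict(DEFAULT_K))
    n_replicates: int = 100
    seed: int = 0
    donor_coverage_quantile: float = 0.8

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for unit, k in self.k_per_unit.items():
            if k < 1:
                raise ValidationError(f"k_per_unit[{unit!r}] must be >= 1")
        if not 0 < self.donor_coverage_quantile <= 1:
            raise ValidationError("donor_coverage_quantile must lie in (0, 1]")


def _unit_mask(cells: pd.DataFrame, unit: str) -> pd.Series:
    """Boolean mask of cells belonging to a cell type or level."""
    if unit in LEVELS:
        return cells["cell_type"].isin(LEVELS[unit])
    return cells["cell_type"] == unit


def _require_log_normalized(matrix: CellMatrix) -> None:
    if matrix.state != LOG_NORMALIZED:
        raise ValidationError("pseudobulk aggregation expects log-normalized data")


def simple_pseudobulk(matrix: CellMatrix, cells: pd.DataFrame, unit: str) -> PseudobulkSet:
    """One sample per donor: the mean over all of the donor's unit cells."""
    _require_log_normalized(matrix)
    mask = _unit_mask(cells, unit)
    pool = cells.loc[mask]
    if pool.empty:
        warnings.warn(f"no cells for unit {unit!r}; empty pseudobulk set", stacklevel=2)
        empty = pd.DataFrame(columns=matrix.gene_ids)
        meta = pd.DataFrame(
            columns=["sample_id", "donor_id", "unit", "replicate",
                     "n_cells_used", "sampled_with_replacement"]
        )
        return PseudobulkSet(expression=empty, meta=meta)

    col_idx = matrix.cell_ids.get_indexer(pool["cell_id"])
    values = matrix.values.tocsc() if sp.issparse(matrix.values) else np.asarray(matrix.values)
    rows, meta_rows = [], []
    for donor_id, grp in pool.groupby("donor_id", sort=True):
        idx = col_idx[pool.index.get_indexer(grp.index)]
        sub = values[:, idx]
        mean = np.asarray(sub.mean(axis=1)).ravel()
        sample_id = f"{donor_id}|{unit}|simple"
        rows.append(mean)
        meta_rows.append(
            {
                "sample_id": sample_id,
                "donor_id": donor_id,
                "unit": unit,
                "replicate": 0,
                "n_cells_used": len(idx),
                "sampled_with_replacement": False,
            }
        )
    meta = pd.DataFrame(meta_rows)
    expression = pd.DataFrame(
        np.vstack(rows), index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=matrix.gene_ids,
    )
    return PseudobulkSet(expression=expression, meta=meta)


def choose_k(
    cells: pd.DataFrame,
    unit: str,
    quantile: float = 0.8,
    grid: tuple = K_GRID,
) -> int:
    """Largest grid k such that > k unit cells are available for >= `quantile` of donors.

    Falls back to the grid minimum (with a warning) when no candidate
    satisfies the coverage rule.
    """
    pool = cells.loc[_unit_mask(cells, unit)]
    if pool.empty:
        raise ValidationError(f"no cells for unit {unit!r}")
    counts = pool.groupby("donor_id")["cell_id"].count()
    feasible = [k for k in grid if (counts > k).mean() >= quantile]
    if not feasible:
        k = min(grid)
        warnings.warn(
            f"no k in {grid} covers {quantile:.0%} of donors for {unit!r}; "
            f"falling back to k={k}",
            stacklevel=2,
        )
        return k
    return max(feasible)


def bootstrap_pseudobulk(
    matrix: CellMatrix,
    cells: pd.DataFrame,
    unit: str,
    config: BootstrapConfig = BootstrapConfig(),
) -> PseudobulkSet:
    """``n_replicates`` samples per donor, each the mean of k sampled cells.

    Sampling is without replacement when the donor has at least k unit
    cells and with replacement otherwise (the sample is then flagged).
    Replicate RNG streams are derived per (seed, unit, donor, replicate),
    so output is independent of donor iteration order.
    """
    _require_log_normalized(matrix)
    k = config.k_per_unit.get(unit)
    if k is None:
        k = choose_k(cells, unit, config.donor_coverage_quantile)
    pool = cells.loc[_unit_mask(cells, unit)]
    if pool.empty:
        warnings.warn(f"no cells for unit {unit!r}; empty pseudobulk set", stacklevel=2)
        return simple_pseudobulk(matrix, cells, unit)

    col_idx = matrix.cell_ids.get_indexer(pool["cell_id"])
    values = matrix.values.tocsc() if sp.issparse(matrix.values) else np.asarray(matrix.values)
    rows, meta_rows = [], []
    for donor_id, grp in pool.groupby("donor_id", sort=True):
        # canonical matrix-column order, so sampling is independent of the
        # cell table's row order
        idx = np.sort(col_idx[pool.index.get_indexer(grp.index)])
        n_avail = len(idx)
        with_replacement = n_avail < k
        sub = values[:, idx]
        dense = np.asarray(sub.todense()) if sp.issparse(sub) else sub
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, zlib.crc32(str(unit).encode()),
                     zlib.crc32(str(donor_id).encode()), rep]
                )
            )
            pick = rng.choice(n_avail, size=k, replace=with_replacement)
            rows.append(dense[:, pick].mean(axis=1))
            meta_rows.append(
                {
                    "sample_id": f"{donor_id}|{unit}|boot{rep:03d}",
                    "donor_id": donor_id,
                    "unit": unit,
                    "replicate": rep,
                    "n_cells_used": k,
                    "sampled_with_replacement": with_replacement,
                }
            )
    meta = pd.DataFrame(meta_rows)
    expression = pd.DataFrame(
        np.vstack(rows), index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=matrix.gene_ids,
    )
    logger.info(
        "bootstrap_pseudobulk: unit=%s k=%d donors=%d replicates=%d",
        unit, k, meta["donor_id"].nunique(), config.n_replicates,
    )
    return PseudobulkSet(expression=expression, meta=meta)


def level_pseudobulk(
    matrix: CellMatrix,
    cells: pd.DataFrame,
    level: str,
    config: BootstrapConfig | None = None,
) -> PseudobulkSet:
    """Pseudobulk at an aggregation level (glia / neuron / all_cells).

    Pools the level's cell types, then delegates: simple pseudobulk when
    ``config`` is None, bootstrapped otherwise.
    """
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level!r}; expected one of {sorted(LEVELS)}")
    if config is None:
        return simple_pseudobulk(matrix, cells, level)
    return bootstrap_pseudobulk(matrix, cells, level, config)


def single_cell_samples(matrix: CellMatrix, cells: pd.DataFrame, unit: str) -> PseudobulkSet:
    """Wrap individual cells of a unit as samples (for single-cell clocks)."""
    _require_log_normalized(matrix)
    pool = cells.loc[_unit_mask(cells, unit)]
    if pool.empty:
        raise ValidationError(f"no cells for unit {unit!r}")
    col_idx = matrix.cell_ids.get_indexer(pool["cell_id"])
    values = matrix.values.tocsc() if sp.issparse(matrix.values) else np.asarray(matrix.values)
    sub = values[:, col_idx]
    dense = np.asarray(sub.todense()).T if sp.issparse(sub) else np.asarray(sub).T
    meta = pd.DataFrame(
        {
            "sample_id": pool["cell_id"].to_numpy(),
            "donor_id": pool["donor_id"].to_numpy(),
            "unit": unit,
            "replicate": 0,
            "n_cells_used": 1,
            "sampled_with_replacement": False,
        }
    )
    expression = pd.DataFrame(
        dense, index=pd.Index(meta["sample_id"], name="sample_id"), columns=matrix.gene_ids
    )
    return PseudobulkSet(expression=expression, meta=meta)
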