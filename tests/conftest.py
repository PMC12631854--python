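"""Shared fixtures: small synthetic cohorts and a trained reference clock.

All fixtures are generated programmatically with fixed seeds; sizes are
kept small (hundreds of genes, tens of cells per donor) so the suite runs
quickly while still exercising every pipeline stage end to end.
"""

import numpy as np
import pandas as pd
import pytest

import ctclock as cc
from ctclock.datatypes import MAJOR_CELL_TYPES

#: permissive gates for synthetic toy cohorts, whose per-cell depths are far
#: below real snRNA-seq totals
LOOSE_QC = cc.QCThresholds(
    min_counts=1, max_counts=1e12, min_genes=1, max_genes=10**7, max_mito_fraction=1.0
)


def small_spec(**overrides):
    base = dict(
        n_donors=10,
        age_range=(20.0, 90.0),
        cell_types={ct: (25.0, 5.0) for ct in MAJOR_CELL_TYPES},
        n_genes=300,
        n_age_genes_pos=15,
        n_age_genes_neg=15,
        age_effect=0.03,
        base_expression=0.8,
        seed=11,
    )
    base.update(overrides)
    return cc.CohortSpec(**base)


def normalize_cohort(cohort):
    matrix, cells, _ = cc.qc_filter(cohort.matrix, cohort.cells, LOOSE_QC)
    matrix = cc.log_normalize(matrix)
    matrix = cc.drop_mito_sex_genes(matrix)
    return matrix, cells, cohort.donors


def donor_aggregate(predictions: pd.DataFrame) -> pd.DataFrame:
    """Donor-level predictions: mean over a donor's sample predictions."""
    return (
        predictions.groupby("donor_id")
        .agg(
            predicted_age=("predicted_age", "mean"),
            chronological_age=("chronological_age", "first"),
        )
        .reset_index()
    )


@pytest.fixture(scope="session")
def small_cohort():
    return cc.generate_cohort(small_spec())


@pytest.fixture(scope="session")
def norm_small(small_cohort):
    return normalize_cohort(small_cohort)


@pytest.fixture(scope="session")
def astro_pbs(norm_small):
    matrix, cells, _ = norm_small
    config = cc.BootstrapConfig(k_per_unit={"astrocyte": 10}, n_replicates=20, seed=3)
    return cc.bootstrap_pseudobulk(matrix, cells, "astrocyte", config)


@pytest.fixture(scope="session")
def astro_clock(astro_pbs, norm_small):
    _, _, donors = norm_small
    model, predictions = cc.train_clock(
        astro_pbs, donors, unit="astrocyte", mode="bootstrapped_pseudobulk",
        alpha=0.5, seed=5,
    )
    return model, predictions
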