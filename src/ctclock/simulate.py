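"""Synthetic snRNA-seq aging cohorts.

Generates gene-by-cell count matrices with the statistical structure the
clock pipeline assumes: donors spanning adulthood, several cell types with
heterogeneous per-donor cell counts, a subset of genes whose log-mean
expression drifts monotonically with age (up or down), many null genes, and
negative-binomial count noise.  A disease cohort is emulated by sampling a
diseased donor's expression at a shifted *effective* age, which makes
age-acceleration recovery a well-defined ground truth.

Randomness is split off one root seed via ``numpy.random.SeedSequence``
streams keyed by purpose, so that gene-level parameters (which genes are
age-responsive, baseline abundances) depend only on the root seed while the
donor draw can be re-randomized independently — the mechanism behind
:func:`make_external_variant`, which produces a cohort from the same gene
program but with fresh donors and a fraction of genes unmeasured.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import MAJOR_CELL_TYPES, RAW_COUNTS, CellMatrix, ValidationError


class Cohort(NamedTuple):
    matrix: CellMatrix
    cells: pd.DataFrame
    donors: pd.DataFrame


class ExternalCohort(NamedTuple):
    matrix: CellMatrix
    cells: pd.DataFrame
    donors: pd.DataFrame
    removed_genes: list


def _stream(*key) -> np.random.Generator:
    """Derive an independent RNG stream from a purpose-keyed seed sequence.

    String keys are hashed with crc32 so the scheme is stable across runs
    and platforms; integer keys pass through.
    """
    words = [k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass
class CohortSpec:
    """Parameters of a synthetic aging cohort.

    Defaults describe the study conditions the pipeline is exercised under:
    30 donors aged 20-90, the six major cortical cell types at ~150 cells
    per donor each, 2000 genes of which 100 carry monotone age trends
    (half up, half down) at ``age_effect`` log-units per year.
    """

    n_donors: int = 30
    age_range: tuple[float, float] = (20.0, 90.0)
    #: cell type -> (mean cells per donor, negative-binomial dispersion of
    #: that count across donors); heterogeneous depths exercise the
    #: choose-k 80% coverage rule downstream.
    cell_types: dict = field(
        default_factory=lambda: {ct: (150.0, 8.0) for ct in MAJOR_CELL_TYPES}
    )
    n_genes: int = 2000
    n_age_genes_pos: int = 50
    n_age_genes_neg: int = 50
    #: slope of log-mean expression per year of effective age.
    age_effect: float = 0.02
    #: median baseline mean count per cell; per-gene baselines are
    #: log-normal around this with sigma 1, giving snRNA-seq-like sparsity.
    base_expression: float = 0.5
    #: negative-binomial dispersion theta of counts (var = mu + mu^2/theta).
    count_dispersion: float = 2.0
    mito_gene_fraction: float = 0.02
    sex_gene_fraction: float = 0.02
    disease_fraction: float = 0.0
    #: years added to a diseased donor's effective age when sampling counts.
    age_shift: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range must satisfy min < max")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_age_genes_pos < 0 or self.n_age_genes_neg < 0:
            raise ValidationError("n_age_genes_pos/n_age_genes_neg must be >= 0")
        if self.n_age_genes_pos + self.n_age_genes_neg > self.n_genes:
            raise ValidationError(
                "n_age_genes_pos + n_age_genes_neg must not exceed n_genes"
            )
        if not 0 <= self.disease_fraction <= 1:
            raise ValidationError("disease_fraction must lie in [0, 1]")
        if not 0 <= self.mito_gene_fraction < 1:
            raise ValidationError("mito_gene_fraction must lie in [0, 1)")
        if not 0 <= self.sex_gene_fraction < 1:
            raise ValidationError("sex_gene_fraction must lie in [0, 1)")
        if not self.cell_types:
            raise ValidationError("cell_types must name at least one cell type")
        for ct, (mean, disp) in self.cell_types.items():
            if mean <= 0 or disp <= 0:
                raise ValidationError(f"cell_types[{ct!r}] mean/dispersion must be > 0")
        if self.base_expression <= 0:
            raise ValidationError("base_expression must be > 0")
        if self.count_dispersion <= 0:
            raise ValidationError("count_dispersion must be > 0")
        return self


def _gene_table(spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gene ids, flags, baseline means and age slopes — root-seed only."""
    rng = _stream(spec.seed, "genes")
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    base = spec.base_expression * np.exp(rng.normal(0.0, 1.0, size=spec.n_genes))

    slopes = np.zeros(spec.n_genes)
    order = rng.permutation(spec.n_genes)
    pos = order[: spec.n_age_genes_pos]
    neg = order[spec.n_age_genes_pos : spec.n_age_genes_pos + spec.n_age_genes_neg]
    slopes[pos] = spec.age_effect
    slopes[neg] = -spec.age_effect

    # mito/sex flags live on null genes so removal never deletes signal.
    null = order[spec.n_age_genes_pos + spec.n_age_genes_neg :]
    n_mito = int(round(spec.mito_gene_fraction * spec.n_genes))
    n_sex = int(round(spec.sex_gene_fraction * spec.n_genes))
    mito = np.zeros(spec.n_genes, dtype=bool)
    sex = np.zeros(spec.n_genes, dtype=bool)
    flagged = null[: n_mito + n_sex]
    mito[flagged[:n_mito]] = True
    sex[flagged[n_mito : n_mito + n_sex]] = True

    genes = pd.DataFrame(
        {"mito": mito, "sex": sex, "age_slope": slopes},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return genes, base, slopes


def _donor_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = spec.age_range
    n = spec.n_donors
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["male", "female"], size=n)
    pmi = rng.uniform(1.0, 12.0, size=n)
    n_disease = int(round(spec.disease_fraction * n))
    condition = np.array(["control"] * n, dtype=object)
    condition[rng.choice(n, size=n_disease, replace=False)] = "disease"
    donors = pd.DataFrame(
        {
            "donor_id": [f"D{i:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "pmi": pmi,
            "condition": condition,
        }
    )
    donors["effective_age"] = donors["age"] + np.where(
        donors["condition"] == "disease", spec.age_shift, 0.0
    )
    return donors


def generate_cohort(spec: CohortSpec, donor_seed: int | None = None) -> Cohort:
    """Sample a cohort: raw counts, cell annotations and donor covariates.

    Counts for gene *g* in a cell of donor *d* are negative binomial with
    log-mean ``log(base_g) + slope_g * (effective_age_d - age_midpoint)``
    and dispersion ``count_dispersion``; the age midpoint is the center of
    ``spec.age_range``.  ``donor_seed`` re-randomizes donors and counts
    while keeping the gene program fixed (used for external variants);
    by default it equals ``spec.seed``.
    """
    spec.validate()
    genes, base, slopes = _gene_table(spec)
    dseed = spec.seed if donor_seed is None else donor_seed
    donors = _donor_table(spec, _stream(spec.seed, "donors", dseed))
    age_mid = 0.5 * (spec.age_range[0] + spec.age_range[1])

    blocks: list[sp.csr_matrix] = []
    cell_rows: list[dict] = []
    theta = spec.count_dispersion
    for di, donor in donors.iterrows():
        mu_d = base * np.exp(slopes * (donor["effective_age"] - age_mid))
        for ct, (mean, disp) in spec.cell_types.items():
            rng = _stream(spec.seed, "cells", dseed, donor["donor_id"], ct)
            # donor-level cell count: NB(mean, disp), at least one cell
            lam = rng.gamma(shape=disp, scale=mean / disp)
            n_cells = max(1, int(rng.poisson(lam)))
            # gamma-poisson mixture = negative binomial per gene x cell
            shape = (spec.n_genes, n_cells)
            lam_gc = rng.gamma(shape=theta, scale=(mu_d / theta)[:, None], size=shape)
            counts = rng.poisson(lam_gc).astype(np.int32)
            blocks.append(sp.csr_matrix(counts))
            for j in range(n_cells):
                cell_rows.append(
                    {
                        "cell_id": f"{donor['donor_id']}_{ct}_{j:04d}",
                        "donor_id": donor["donor_id"],
                        "cell_type": ct,
                    }
                )

    values = sp.hstack(blocks, format="csc") if blocks else sp.csc_matrix((spec.n_genes, 0))
    cells = pd.DataFrame(cell_rows)
    matrix = CellMatrix(
        values=values,
        genes=genes,
        cell_ids=pd.Index(cells["cell_id"]),
        state=RAW_COUNTS,
    )
    cells["total_counts"] = matrix.total_counts()
    cells["n_genes_detected"] = matrix.n_genes_detected()
    cells["mito_fraction"] = matrix.mito_fraction()
    return Cohort(matrix, cells, donors.drop(columns=["effective_age"]))


def make_external_variant(
    spec: CohortSpec, gene_dropout_fraction: float, seed: int
) -> ExternalCohort:
    """An independent cohort from the same gene program, minus some genes.

    Emulates transfer to an external dataset: donors are drawn afresh
    (stream keyed by ``seed``) and ``gene_dropout_fraction`` of the genes
    are removed entirely, as if unmeasured.  The removed gene list is
    returned so transfer diagnostics can be checked against ground truth.
    """
    if not 0 <= gene_dropout_fraction < 1:
        raise ValidationError("gene_dropout_fraction must lie in [0, 1)")
    cohort = generate_cohort(spec, donor_seed=seed)
    n_remove = int(round(gene_dropout_fraction * cohort.matrix.n_genes))
    rng = _stream(spec.seed, "dropout", seed)
    removed_idx = np.sort(rng.choice(cohort.matrix.n_genes, size=n_remove, replace=False))
    removed = list(cohort.matrix.gene_ids[removed_idx])
    keep = np.ones(cohort.matrix.n_genes, dtype=bool)
    keep[removed_idx] = False
    matrix = cohort.matrix.subset_genes(keep)
    # QC metrics refer to the measured gene set
    cells = cohort.cells.copy()
    cells["total_counts"] = matrix.total_counts()
    cells["n_genes_detected"] = matrix.n_genes_detected()
    cells["mito_fraction"] = matrix.mito_fraction()
    return ExternalCohort(matrix, cells, cohort.donors, removed)
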