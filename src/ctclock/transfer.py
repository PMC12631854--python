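"""Applying trained clocks to independent datasets.

External data rarely measures exactly the clock's gene universe.  Columns
are therefore reordered to the model universe, genes the external data
lacks are imputed with the model's training means (computed on the exact
samples the clock was trained on), extra genes are dropped, and the five
per-round models are ensembled per sample.  Diagnostics quantify how much
of the clock's feature-gene set the external data supports: the fraction
of feature genes expressed at all, and the proportion whose age trend
(Spearman, Benjamini-Hochberg adjusted) is significant in the same
direction as the clock's average coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clock import ClockModel, extract_feature_genes
from .datatypes import CellMatrix, PseudobulkSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TransferReport:
    n_genes_matched: int
    n_genes_imputed: int
    n_genes_dropped: int

    @property
    def universe_size(self) -> int:
        return self.n_genes_matched + self.n_genes_imputed


@dataclass
class ConcordanceRecord:
    n_feature_genes: int
    n_significant_same_sign: int
    proportion_same_sign: float
    per_gene: pd.DataFrame


def _as_expression(data) -> pd.DataFrame:
    """Samples x genes frame from a PseudobulkSet, CellMatrix or DataFrame."""
    if isinstance(data, PseudobulkSet):
        return data.expression
    if isinstance(data, CellMatrix):
        return pd.DataFrame(data.dense().T, index=data.cell_ids, columns=data.gene_ids)
    return data


def align_genes(model: ClockModel, external) -> tuple[pd.DataFrame, TransferReport]:
    """Reorder external samples to the model universe, imputing missing genes.

    Missing genes get the model's constant training mean; extra genes are
    dropped and counted.  Proceeds with a prominent warning when more than
    half the universe must be imputed (the degraded-transfer regime).
    """
    expr = _as_expression(external)
    matched = model.gene_universe.intersection(expr.columns)
    missing = model.gene_universe.difference(expr.columns)
    dropped = expr.columns.difference(model.gene_universe)
    if len(missing) > 0.5 * len(model.gene_universe):
        warnings.warn(
            f"{len(missing)}/{len(model.gene_universe)} model genes missing from "
            "external data; predictions will be dominated by imputed training means",
            stacklevel=2,
        )
    aligned = pd.DataFrame(
        np.tile(model.training_gene_means, (len(expr), 1)),
        index=expr.index,
        columns=model.gene_universe,
    )
    aligned.loc[:, matched] = expr.loc[:, matched].to_numpy(dtype=float)
    report = TransferReport(
        n_genes_matched=len(matched),
        n_genes_imputed=len(missing),
        n_genes_dropped=len(dropped),
    )
    logger.info("align_genes: matched=%d imputed=%d dropped=%d",
                report.n_genes_matched, report.n_genes_imputed, report.n_genes_dropped)
    return aligned, report


def apply_clock_external(
    model: ClockModel,
    aligned: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    aggregate_by_donor: bool = False,
) -> pd.DataFrame:
    """Per-sample ensemble predictions (mean of the five per-round models).

    ``meta`` supplies donor ids (row-aligned with ``aligned``); required
    when aggregating by donor.  Per-fold predictions are kept as columns
    for auditability.
    """
    if list(aligned.columns) != list(model.gene_universe):
        raise ValidationError("samples are not aligned to the model gene universe")
    X = aligned.to_numpy(dtype=float)
    per_fold = np.column_stack([f.predict(X) for f in model.folds])
    table = pd.DataFrame(
        {
            "sample_id": aligned.index,
            "unit": model.unit,
            "predicted_age": per_fold.mean(axis=1),
            "source": "external_ensemble",
        }
    )
    for k in range(per_fold.shape[1]):
        table[f"fold_{k}_prediction"] = per_fold[:, k]
    if meta is not None:
        table["donor_id"] = np.asarray(meta["donor_id"])
    if aggregate_by_donor:
        if meta is None:
            raise ValidationError("donor aggregation needs sample metadata with donor_id")
        table = (
            table.groupby("donor_id", as_index=False)
            .agg(predicted_age=("predicted_age", "mean"))
            .assign(unit=model.unit, source="external_ensemble_donor")
        )
        table.insert(0, "sample_id", table["donor_id"])
    return table


def feature_gene_expression_fraction(
    model: ClockModel, external, min_value: float = 0.0
) -> float:
    """Fraction of the clock's feature genes detected in the external data.

    A gene counts as expressed when it exceeds ``min_value`` in at least
    one cell/sample (default: nonzero anywhere).
    """
    features = extract_feature_genes(model)["gene"]
    if len(features) == 0:
        return float("nan")
    expr = _as_expression(external)
    present = features[features.isin(expr.columns)]
    expressed = 0
    if len(present):
        expressed = int((expr.loc[:, present].to_numpy() > min_value).any(axis=0).sum())
    return expressed / len(features)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def feature_gene_trend_concordance(
    model: ClockModel,
    samples,
    donors: pd.DataFrame,
    alpha_level: float = 0.05,
) -> ConcordanceRecord:
    """Do feature-gene age trends in a dataset match the clock's coefficients?

    For each feature gene: Spearman rho of expression against donor age
    over the provided samples (per cell for single-cell clocks, per
    donor/cell-type mean for pseudobulk clocks — the caller controls the
    aggregation by what it passes in).  P-values are BH-adjusted; a gene
    is concordant when adjusted p < ``alpha_level`` and sign(rho) matches
    the sign of its average clock coefficient.  Constant genes have
    undefined rho and count as non-concordant.
    """
    features = extract_feature_genes(model)
    if features.empty:
        return ConcordanceRecord(0, 0, float("nan"), pd.DataFrame())
    expr = _as_expression(samples)
    meta = samples.meta if isinstance(samples, PseudobulkSet) else None
    if meta is None:
        raise ValidationError("concordance needs sample metadata (a PseudobulkSet)")
    age_by_donor = donors.set_index("donor_id")["age"]
    ages = age_by_donor.loc[meta["donor_id"]].to_numpy(dtype=float)
    if pd.Series(ages).nunique() < 4:
        raise ValidationError("concordance needs >= 4 age-distinct donors")

    rows = []
    for _, frow in features.iterrows():
        gene, coef_sign = frow["gene"], int(frow["sign"])
        if gene not in expr.columns:
            rows.append({"gene": gene, "rho": np.nan, "p": np.nan, "coef_sign": coef_sign})
            continue
        x = expr[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"gene": gene, "rho": np.nan, "p": np.nan, "coef_sign": coef_sign})
            continue
        rho, p = stats.spearmanr(x, ages)
        rows.append({"gene": gene, "rho": float(rho), "p": float(p), "coef_sign": coef_sign})
    per_gene = pd.DataFrame(rows)
    per_gene["p_adjusted"] = bh_adjust(per_gene["p"].to_numpy())
    per_gene["concordant"] = (
        (per_gene["p_adjusted"] < alpha_level)
        & (np.sign(per_gene["rho"]) == per_gene["coef_sign"])
    ).fillna(False)
    n_conc = int(per_gene["concordant"].sum())
    return ConcordanceRecord(
        n_feature_genes=len(per_gene),
        n_significant_same_sign=n_conc,
        proportion_same_sign=n_conc / len(per_gene),
        per_gene=per_gene,
    )
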