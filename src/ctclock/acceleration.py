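"""Age-acceleration statistics and disease-vs-control inference.

Age acceleration is the residual of a sample's predicted age from the
least-squares line of predicted age on chronological age: positive values
mean an older-than-expected molecular profile.  The reference line is
fitted on all provided samples by default (controls and disease pooled, so
the two groups' residuals share one scale); a controls-only fit is
available for display-style analyses.

Group differences are tested with covariate-adjusted linear models: a
Gaussian GLM (equivalently OLS) on donor-level accelerations, or a linear
mixed model with a per-donor random intercept when testing per-cell
accelerations (many rows per donor).  The effect of interest is the
coefficient of the 0/1 disease indicator, in years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "pmi", "brain_ph", "hemisphere")


@dataclass
class AgeAccelerationResult:
    """Per-sample accelerations plus the fitted reference line."""

    table: pd.DataFrame
    slope: float
    intercept: float
    fitted_on: str  # 'pooled' or 'control'


@dataclass
class GroupTest:
    model_kind: str  # 'glm' or 'mixed'
    disease_coefficient: float
    std_error: float
    p_value: float
    covariates_used: list
    converged: bool = True
    n_samples: int = 0


def compute_age_acceleration(
    predictions: pd.DataFrame,
    fit_on: str = "pooled",
    conditions: pd.Series | None = None,
) -> AgeAccelerationResult:
    """Residuals from the least-squares line of predicted on chronological age.

    ``fit_on='control'`` restricts the line fit to control samples (the
    residuals are still computed for every sample); this needs a
    ``condition`` column or a donor-indexed ``conditions`` series.
    """
    table = predictions.copy()
    for col in ("chronological_age", "predicted_age"):
        if col not in table.columns:
            raise ValidationError(f"predictions lack required column {col!r}")
    if conditions is not None and "condition" not in table.columns:
        table["condition"] = conditions.loc[table["donor_id"]].to_numpy()
    if len(table) < 3:
        raise ValidationError("need >= 3 samples to fit the reference line")
    age = table["chronological_age"].to_numpy(dtype=float)
    pred = table["predicted_age"].to_numpy(dtype=float)
    if fit_on == "control":
        if "condition" not in table.columns:
            raise ValidationError("fit_on='control' needs condition information")
        mask = (table["condition"] == "control").to_numpy()
        if mask.sum() < 3:
            raise ValidationError("need >= 3 control samples for a controls-only fit")
    elif fit_on == "pooled":
        mask = np.ones(len(table), dtype=bool)
    else:
        raise ValidationError("fit_on must be 'pooled' or 'control'")
    if np.ptp(age[mask]) == 0:
        raise ValidationError("zero variance in chronological age")
    slope, intercept = np.polyfit(age[mask], pred[mask], deg=1)
    table["acceleration"] = pred - (intercept + slope * age)
    return AgeAccelerationResult(
        table=table, slope=float(slope), intercept=float(intercept), fitted_on=fit_on
    )


def _design_frame(
    result: AgeAccelerationResult, donors: pd.DataFrame, covariates
) -> tuple[pd.DataFrame, list]:
    table = result.table.copy()
    donor_cols = donors.set_index("donor_id")
    if "donor_id" not in table.columns:
        raise ValidationError("acceleration table lacks donor_id")
    joined = table.join(
        donor_cols.drop(columns=[c for c in donor_cols.columns if c in table.columns]),
        on="donor_id",
    )
    if "condition" not in joined.columns:
        joined["condition"] = donor_cols.loc[joined["donor_id"], "condition"].to_numpy()
    if joined["condition"].nunique() < 2:
        raise ValidationError("group comparison needs both control and disease samples")
    joined["disease"] = (joined["condition"] == "disease").astype(int)
    if "age" not in joined.columns:
        joined["age"] = joined["chronological_age"]

    used, dropped = [], []
    for cov in covariates:
        if cov == "disease":
            continue
        if cov in joined.columns and joined[cov].notna().all() and joined[cov].nunique() > 1:
            used.append(cov)
        else:
            dropped.append(cov)
    if dropped:
        logger.info("compare_groups: dropping unavailable covariates %s", dropped)
    return joined, used


def _formula(used: list) -> str:
    terms = ["disease"]
    for cov in used:
        terms.append(f"C({cov})" if cov in ("sex", "hemisphere") else cov)
    return "acceleration ~ " + " + ".join(terms)


def compare_groups(
    result: AgeAccelerationResult,
    donors: pd.DataFrame,
    per_cell: bool = False,
    covariates=DEFAULT_COVARIATES,
) -> GroupTest:
    """Disease-vs-control difference in acceleration, covariate adjusted.

    ``per_cell=False``: Gaussian GLM (OLS) on donor-level accelerations.
    ``per_cell=True``: linear mixed model with a random intercept per
    donor, for tables with many samples per donor.  Missing optional
    covariates are dropped with a log entry.  Returns the disease
    coefficient (years), its standard error and p-value.
    """
    data, used = _design_frame(result, donors, covariates)
    formula = _formula(used)
    if per_cell:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, data=data, groups=data["donor_id"]).fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception as err:  # singular / non-convergent mixed fit
            logger.warning("mixed model failed (%s); falling back to GLM", err)
            return compare_groups(result, donors, per_cell=False, covariates=covariates)
        coef = float(fit.params["disease"])
        se = float(fit.bse["disease"])
        p = float(fit.pvalues["disease"])
        return GroupTest("mixed", coef, se, p, used, converged, len(data))

    fit = smf.glm(formula, data=data, family=sm.families.Gaussian()).fit()
    return GroupTest(
        "glm",
        float(fit.params["disease"]),
        float(fit.bse["disease"]),
        float(fit.pvalues["disease"]),
        used,
        True,
        len(data),
    )
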