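"""Elastic-net aging clocks with donor-level cross-validation.

A clock for one unit (cell type or level) and one sampling mode
(single-cell, simple pseudobulk, bootstrapped pseudobulk) is a set of five
elastic-net regressions of donor age on gene expression, one per
cross-validation round.  Folds partition *donors*, never samples, so no
individual contributes to both training and test data.  Out-of-fold
predictions pooled over rounds measure training performance (Pearson r and
MAE in years); the five per-round models are kept verbatim and ensembled
(mean prediction) whenever the clock is applied to new data.

Penalty parameterization follows the glmnet convention: the objective is
``1/(2n) * ||y - Xb||^2 + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||^2)``
with ``alpha`` the L1/L2 mixing weight.  At ``alpha = 0`` the problem is
ridge regression and is solved in closed form; on centered features that
solution satisfies ``(X'X + n*lambda*I) b = X'y``.  By default features
are standardized before fitting and coefficients are reported back on the
original scale; ``lambda`` is selected by inner cross-validation over a
log-spaced path (minimum validation MSE) unless fixed explicitly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import GroupKFold, KFold

from .datatypes import PseudobulkSet, ValidationError

logger = logging.getLogger(__name__)

MODES = ("single_cell", "simple_pseudobulk", "bootstrapped_pseudobulk")
ALPHA_GRID = (0.0, 0.5, 1.0)


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

def assign_donor_folds(donor_ids, n_folds: int = 5, seed: int = 0) -> pd.Series:
    """Seeded partition of donors into folds with sizes differing by <= 1."""
    donor_ids = pd.Index(donor_ids).unique()
    if len(donor_ids) < n_folds:
        raise ValidationError(
            f"need >= {n_folds} donors for {n_folds}-fold CV, got {len(donor_ids)}"
        )
    order = np.array(sorted(donor_ids))
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(order)]))
    rng.shuffle(order)
    folds = pd.Series(np.arange(len(order)) % n_folds, index=order, name="fold")
    return folds.sort_index()


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    coefficients: np.ndarray
    intercept: float
    lam: float


def _make_estimator(alpha: float, lam: float, n: int):
    if alpha == 0.0:
        # glmnet-scale ridge: RSS + n*lam*||b||^2
        return Ridge(alpha=n * lam, solver="cholesky")
    return ElasticNet(
        alpha=lam, l1_ratio=alpha, max_iter=10_000, tol=1e-4,
        selection="cyclic", precompute=True,
    )


def _ridge_path_mse(X_tr, y_tr, X_va, y_va, path):
    """Validation MSE of centered ridge at every lambda via one SVD."""
    m = X_tr.mean(axis=0)
    ym = y_tr.mean()
    U, S, Vt = np.linalg.svd(X_tr - m, full_matrices=False)
    Uty = U.T @ (y_tr - ym)
    n = len(y_tr)
    out = np.empty(len(path))
    for li, lam in enumerate(path):
        beta = Vt.T @ (S / (S**2 + n * lam) * Uty)
        pred = (X_va - m) @ beta + ym
        out[li] = np.mean((pred - y_va) ** 2)
    return out


def _lambda_path(Xs, yc, alpha, n_lambdas, lambda_min_ratio):
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def fit_elasticnet(
    X,
    y,
    alpha: float = 0.5,
    lam: float | None = None,
    standardize: bool = True,
    cv_groups=None,
    seed: int = 0,
    n_lambdas: int = 10,
    lambda_min_ratio: float = 1e-2,
    n_inner_folds: int = 3,
) -> FitResult:
    """Fit one penalized age regression; returns original-scale coefficients.

    ``lam=None`` selects the penalty by inner cross-validation (grouped by
    ``cv_groups`` — donor ids — when given, so the inner splits respect
    donors too); a fixed ``lam`` skips selection, which supports
    closed-form oracle checks.  Constant-y input yields an intercept-only
    model rather than an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression inputs")
    if alpha < 0 or alpha > 1:
        raise ValidationError("alpha (L1/L2 mixing) must lie in [0, 1]")
    n, p = X.shape

    if np.ptp(y) == 0:
        return FitResult(np.zeros(p), float(y[0]) if n else 0.0, lam or 0.0)

    if standardize:
        m = X.mean(axis=0)
        s = X.std(axis=0)
        s_safe = np.where(s > 0, s, 1.0)
        Xs = (X - m) / s_safe
    else:
        m = np.zeros(p)
        s_safe = np.ones(p)
        Xs = X

    if lam is None:
        lam = _select_lambda(
            Xs, y, alpha, cv_groups, seed, n_lambdas, lambda_min_ratio, n_inner_folds
        )

    est = _make_estimator(alpha, lam, n)
    est.fit(Xs, y)
    coef_std = np.asarray(est.coef_, dtype=float).ravel()
    coef = coef_std / s_safe
    intercept = float(est.intercept_) - float(np.dot(coef_std, m / s_safe))
    return FitResult(coef, intercept, float(lam))


def _select_lambda(Xs, y, alpha, groups, seed, n_lambdas, lambda_min_ratio, n_inner):
    """Minimum-MSE lambda over a log-spaced path, by inner CV."""
    yc = y - y.mean()
    path = _lambda_path(Xs, yc, alpha, n_lambdas, lambda_min_ratio)
    n = len(y)
    if groups is not None and pd.Index(groups).nunique() >= n_inner:
        splits = list(GroupKFold(n_splits=n_inner).split(Xs, y, groups=np.asarray(groups)))
    else:
        kf = KFold(n_splits=min(n_inner, n), shuffle=True, random_state=seed)
        splits = list(kf.split(Xs))
    mse = np.zeros((len(splits), len(path)))
    for si, (tr, va) in enumerate(splits):
        if alpha == 0.0:
            mse[si] = _ridge_path_mse(Xs[tr], y[tr], Xs[va], y[va], path)
        else:
            est = ElasticNet(
                alpha=path[0], l1_ratio=alpha, max_iter=2000, tol=1e-4,
                warm_start=True, selection="cyclic", precompute=True,
            )
            # the smallest path lambdas may stop at max_iter; they are only
            # being scored, never returned, so their warnings are noise
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                for li, lam in enumerate(path):  # descending, warm starts
                    est.set_params(alpha=lam)
                    est.fit(Xs[tr], y[tr])
                    mse[si, li] = np.mean((est.predict(Xs[va]) - y[va]) ** 2)
    return float(path[int(np.argmin(mse.mean(axis=0)))])


# ---------------------------------------------------------------------------
# clock model
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    coefficients: np.ndarray
    intercept: float
    lam: float
    train_donors: list

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


@dataclass
class ClockModel:
    """A trained aging clock: five per-round elastic-net models plus metadata."""

    unit: str
    mode: str
    alpha: float
    folds: list
    gene_universe: pd.Index
    training_gene_means: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_universe = pd.Index(self.gene_universe, name="gene_id")
        if len(self.training_gene_means) != len(self.gene_universe):
            raise ValidationError("training_gene_means length != gene universe size")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def ensemble_predict(self, X: np.ndarray) -> np.ndarray:
        """Mean prediction of the per-round models (the transfer rule)."""
        preds = np.column_stack([f.predict(X) for f in self.folds])
        return preds.mean(axis=1)


def _sample_ages(meta: pd.DataFrame, donors: pd.DataFrame) -> np.ndarray:
    age_by_donor = donors.set_index("donor_id")["age"]
    unknown = ~meta["donor_id"].isin(age_by_donor.index)
    if unknown.any():
        raise ValidationError(
            f"{int(unknown.sum())} samples reference donors missing from the donor table"
        )
    return age_by_donor.loc[meta["donor_id"]].to_numpy(dtype=float)


def train_clock(
    samples: PseudobulkSet,
    donors: pd.DataFrame,
    unit: str,
    mode: str,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 5,
    lam: float | None = None,
    **fit_kwargs,
) -> tuple[ClockModel, pd.DataFrame]:
    """Train a clock with donor-level CV; returns the model and cv_test predictions.

    Each round fits on the samples of the out-of-round donors and predicts
    every sample of the held-out donors; the pooled predictions carry
    ``source='cv_test'``.  Training gene means (used later for
    missing-gene imputation on external data) are computed over the exact
    samples the clock was trained on.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    meta = samples.meta.reset_index(drop=True)
    X = samples.expression.to_numpy(dtype=float)
    y = _sample_ages(meta, donors)
    fold_of_donor = assign_donor_folds(meta["donor_id"], n_folds=n_folds, seed=seed)
    sample_fold = fold_of_donor.loc[meta["donor_id"]].to_numpy()

    fold_models: list[FoldModel] = []
    pred_frames = []
    for f in range(n_folds):
        tr = sample_fold != f
        te = ~tr
        train_donors = sorted(meta.loc[tr, "donor_id"].unique())
        if len(train_donors) < 2:
            raise ValidationError(f"fold {f} has < 2 training donors")
        fit = fit_elasticnet(
            X[tr], y[tr], alpha=alpha, lam=lam, seed=seed,
            cv_groups=meta.loc[tr, "donor_id"].to_numpy(), **fit_kwargs,
        )
        fm = FoldModel(fit.coefficients, fit.intercept, fit.lam, train_donors)
        fold_models.append(fm)
        pred_frames.append(
            pd.DataFrame(
                {
                    "sample_id": meta.loc[te, "sample_id"].to_numpy(),
                    "donor_id": meta.loc[te, "donor_id"].to_numpy(),
                    "unit": unit,
                    "fold": f,
                    "chronological_age": y[te],
                    "predicted_age": fm.predict(X[te]),
                    "source": "cv_test",
                }
            )
        )
    model = ClockModel(
        unit=unit,
        mode=mode,
        alpha=alpha,
        folds=fold_models,
        gene_universe=samples.gene_ids,
        training_gene_means=X.mean(axis=0),
        seed=seed,
    )
    predictions = pd.concat(pred_frames, ignore_index=True)
    logger.info(
        "train_clock: unit=%s mode=%s alpha=%.2f samples=%d donors=%d",
        unit, mode, alpha, len(meta), fold_of_donor.size,
    )
    return model, predictions


def predict_donor_age(
    model: ClockModel, samples: PseudobulkSet, aggregate: bool = True
) -> pd.DataFrame:
    """Ensemble predictions for samples already on the model's gene universe.

    With ``aggregate`` set, replicate predictions are averaged to one row
    per donor (the donor-age rule for bootstrapped clocks).
    """
    extra = samples.gene_ids.difference(model.gene_universe)
    missing = model.gene_universe.difference(samples.gene_ids)
    if len(extra) or len(missing):
        raise ValidationError(
            f"gene universe mismatch ({len(extra)} unknown, {len(missing)} missing); "
            "route external data through ctclock.transfer.align_genes first"
        )
    X = samples.expression.loc[:, model.gene_universe].to_numpy(dtype=float)
    preds = model.ensemble_predict(X)
    table = pd.DataFrame(
        {
            "sample_id": samples.meta["sample_id"].to_numpy(),
            "donor_id": samples.meta["donor_id"].to_numpy(),
            "unit": model.unit,
            "predicted_age": preds,
            "source": "ensemble",
        }
    )
    if aggregate:
        table = (
            table.groupby("donor_id", as_index=False)
            .agg(predicted_age=("predicted_age", "mean"))
            .assign(unit=model.unit, source="ensemble_donor")
        )
        table.insert(0, "sample_id", table["donor_id"])
    return table


# ---------------------------------------------------------------------------
# evaluation & baseline
# ---------------------------------------------------------------------------

@dataclass
class ClockPerformance:
    pearson_r: float
    r_p_value: float
    mae: float
    n_points: int


def evaluate(predictions: pd.DataFrame, donors: pd.DataFrame | None = None) -> ClockPerformance:
    """Pearson r (two-sided p) and MAE of predicted vs chronological age.

    Chronological ages are taken from the prediction table or joined from
    the donor table.  Zero variance in either variable leaves r undefined
    (NaN), not zero.
    """
    table = predictions.copy()
    if "chronological_age" not in table.columns:
        if donors is None:
            raise ValidationError("need chronological_age column or a donor table")
        table["chronological_age"] = _sample_ages(table, donors)
    if len(table) < 3:
        raise ValidationError("need >= 3 points to evaluate")
    age = table["chronological_age"].to_numpy(dtype=float)
    pred = table["predicted_age"].to_numpy(dtype=float)
    mae = float(np.mean(np.abs(pred - age)))
    if np.ptp(age) == 0 or np.ptp(pred) == 0:
        return ClockPerformance(float("nan"), float("nan"), mae, len(table))
    r, p = stats.pearsonr(age, pred)
    return ClockPerformance(float(r), float(p), mae, len(table))


def naive_mean_baseline(
    samples: PseudobulkSet, donors: pd.DataFrame, folds: pd.Series
) -> pd.DataFrame:
    """Fold-wise mean-age predictor: each test sample gets its round's training mean age."""
    meta = samples.meta.reset_index(drop=True)
    y = _sample_ages(meta, donors)
    sample_fold = folds.loc[meta["donor_id"]].to_numpy()
    rows = []
    for f in np.unique(sample_fold):
        tr = sample_fold != f
        te = ~tr
        mean_age = float(y[tr].mean())
        for (_, row), age in zip(meta.loc[te].iterrows(), y[te]):
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "donor_id": row["donor_id"],
                    "unit": row["unit"],
                    "fold": int(f),
                    "chronological_age": float(age),
                    "predicted_age": mean_age,
                    "source": "baseline",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature genes
# ---------------------------------------------------------------------------

def extract_feature_genes(model: ClockModel) -> pd.DataFrame:
    """Genes with non-zero coefficients in every CV round.

    Returns gene id, the coefficient averaged across rounds, and its sign
    (the modeled direction of the age trend).  The average coefficient is
    interpretive only — predictions always use the per-round models.
    """
    coef = np.vstack([f.coefficients for f in model.folds])
    nonzero_all = (coef != 0).all(axis=0)
    avg = coef.mean(axis=0)
    out = pd.DataFrame(
        {
            "gene": model.gene_universe[nonzero_all],
            "average_coefficient": avg[nonzero_all],
        }
    )
    out["sign"] = np.sign(out["average_coefficient"]).astype(int)
    return out.reset_index(drop=True)


def feature_overlap(models: list[ClockModel]) -> dict:
    """Cross-clock feature-gene membership and sharing counts."""
    sets = {m.unit: set(extract_feature_genes(m)["gene"]) for m in models}
    all_genes = sorted(set().union(*sets.values())) if sets else []
    membership = pd.DataFrame(
        {unit: [g in genes for g in all_genes] for unit, genes in sets.items()},
        index=pd.Index(all_genes, name="gene"),
    )
    n_models = membership.sum(axis=1) if len(all_genes) else pd.Series(dtype=int)
    common = list(membership.index[n_models == len(sets)]) if len(sets) else []
    return {
        "membership": membership,
        "n_unique": int((n_models == 1).sum()),
        "n_shared": int((n_models > 1).sum()),
        "common_to_all": common,
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model: ClockModel, path=None) -> str:
    """Serialize a clock to JSON (sparse per-round coefficients)."""
    payload = {
        "unit": model.unit,
        "mode": model.mode,
        "alpha": model.alpha,
        "seed": model.seed,
        "gene_universe": list(model.gene_universe),
        "training_gene_means": [float(v) for v in model.training_gene_means],
        "folds": [
            {
                "intercept": f.intercept,
                "lambda": f.lam,
                "train_donors": list(f.train_donors),
                "nonzero_index": np.flatnonzero(f.coefficients).tolist(),
                "nonzero_values": f.coefficients[f.coefficients != 0].tolist(),
            }
            for f in model.folds
        ],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source) -> ClockModel:
    """Inverse of :func:`model_to_json`; accepts a path or a JSON string."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:  # long JSON strings overflow path-name limits
        is_file = False
    text = Path(str(source)).read_text() if is_file else str(source)
    payload = json.loads(text)
    universe = pd.Index(payload["gene_universe"], name="gene_id")
    folds = []
    for f in payload["folds"]:
        coef = np.zeros(len(universe))
        coef[np.asarray(f["nonzero_index"], dtype=int)] = f["nonzero_values"]
        folds.append(FoldModel(coef, f["intercept"], f["lambda"], f["train_donors"]))
    return ClockModel(
        unit=payload["unit"],
        mode=payload["mode"],
        alpha=payload["alpha"],
        folds=folds,
        gene_universe=universe,
        training_gene_means=np.asarray(payload["training_gene_means"], dtype=float),
        seed=payload["seed"],
    )
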