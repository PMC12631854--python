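"""Elastic-net clocks: fold assignment, fitting, CV bookkeeping, features."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import ctclock as cc
from ctclock.clock import (
    ClockModel,
    FoldModel,
    assign_donor_folds,
    evaluate,
    extract_feature_genes,
    feature_overlap,
    fit_elasticnet,
    model_from_json,
    model_to_json,
    naive_mean_baseline,
    predict_donor_age,
    train_clock,
)
from ctclock.datatypes import PseudobulkSet, ValidationError

from conftest import donor_aggregate


def ridge_closed_form(X, y, lam):
    """Independent ridge oracle: (Xc'Xc + n*lam*I) b = Xc'y on centered X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc + n * lam * np.eye(p), Xc.T @ yc)
    intercept = y.mean() - X.mean(axis=0) @ beta
    return beta, intercept


class TestFolds:
    def test_ten_donors_five_folds_of_two(self):
        folds = assign_donor_folds([f"d{i}" for i in range(10)], seed=1)
        assert sorted(folds.value_counts()) == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        donors = [f"d{i}" for i in range(13)]
        folds = assign_donor_folds(donors, seed=4)
        assert set(folds.index) == set(donors)
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_seeded_determinism(self):
        donors = [f"d{i}" for i in range(9)]
        a = assign_donor_folds(donors, seed=7)
        b = assign_donor_folds(donors, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValidationError):
            assign_donor_folds(["d1", "d2"], n_folds=5)


class TestFitElasticNet:
    def test_constant_target_gives_intercept_only(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        fit = fit_elasticnet(X, np.full(6, 5.0), alpha=0.5)
        assert np.all(fit.coefficients == 0)
        assert fit.intercept == 5.0

    def test_huge_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        y = rng.uniform(20, 90, size=20)
        for alpha in (0.0, 0.5, 1.0):
            fit = fit_elasticnet(X, y, alpha=alpha, lam=1e9)
            # ridge shrinks asymptotically, the L1 branches exactly
            atol = 1e-6 if alpha == 0.0 else 0.0
            assert np.allclose(fit.coefficients, 0.0, atol=atol)
            assert np.isclose(fit.intercept, y.mean(), atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ridge_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=10)
        lam = 0.37
        fit = fit_elasticnet(X, y, alpha=0.0, lam=lam, standardize=False)
        beta, intercept = ridge_closed_form(X, y, lam)
        assert np.allclose(fit.coefficients, beta, rtol=1e-4, atol=1e-8)
        assert np.isclose(fit.intercept, intercept, rtol=1e-4)

    def test_non_finite_inputs_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_elasticnet(X, np.arange(4.0))

    def test_matches_r_glmnet_on_fixed_lambda(self, tmp_path):
        """Cross-check the coordinate-descent solution against R glmnet.

        Uses the pure-lasso corner (alpha = 1), where the two packages'
        penalty conventions coincide exactly; glmnet's internal response
        standardization remixes the L1/L2 weights at intermediate alpha.
        """
        rng = np.random.default_rng(3)
        n, p, lam = 40, 8, 0.25
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=n) * 0.5
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
            y <- scan("{tmp_path}/y.csv", quiet=TRUE)
            fit <- glmnet(X, y, alpha=1, lambda={lam}, standardize=FALSE,
                          thresh=1e-14)
            cat(as.numeric(coef(fit)), sep=",")
        """)
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                timeout=120, check=True,
            )
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/glmnet unavailable")
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        fit = fit_elasticnet(X, y, alpha=1.0, lam=lam, standardize=False)
        assert np.isclose(fit.intercept, ref[0], atol=1e-4)
        assert np.allclose(fit.coefficients, ref[1:], atol=1e-4)


class TestTrainClock:
    def test_every_sample_predicted_exactly_once(self, astro_pbs, astro_clock):
        _, predictions = astro_clock
        counts = predictions["sample_id"].value_counts()
        assert (counts == 1).all()
        assert set(predictions["sample_id"]) == set(astro_pbs.meta["sample_id"])

    def test_no_donor_leakage(self, astro_clock):
        model, predictions = astro_clock
        for _, row in predictions.iterrows():
            assert row["donor_id"] not in model.folds[int(row["fold"])].train_donors

    def test_clock_beats_naive_baseline_on_signal_cohort(self, astro_pbs, astro_clock,
                                                         norm_small):
        _, _, donors = norm_small
        model, predictions = astro_clock
        perf = evaluate(donor_aggregate(predictions))
        folds = assign_donor_folds(astro_pbs.meta["donor_id"], seed=model.seed)
        base = naive_mean_baseline(astro_pbs, donors, folds)
        base_perf = evaluate(donor_aggregate(base))
        assert perf.pearson_r > 0.5
        assert perf.mae < base_perf.mae

    def test_training_determinism(self, astro_pbs, norm_small):
        _, _, donors = norm_small
        kw = dict(unit="astrocyte", mode="bootstrapped_pseudobulk", alpha=0.5, seed=5)
        m1, p1 = train_clock(astro_pbs, donors, **kw)
        m2, p2 = train_clock(astro_pbs, donors, **kw)
        for f1, f2 in zip(m1.folds, m2.folds):
            assert np.array_equal(f1.coefficients, f2.coefficients)
            assert f1.intercept == f2.intercept
        pd.testing.assert_frame_equal(p1, p2)

    def test_fold_with_too_few_training_donors_rejected(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(2, 3)),
                            index=pd.Index(["s1", "s2"], name="sample_id"),
                            columns=["g0", "g1", "g2"])
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "donor_id": ["d1", "d2"], "unit": "astrocyte",
             "replicate": 0, "n_cells_used": 1, "sampled_with_replacement": False}
        )
        donors = pd.DataFrame(
            {"donor_id": ["d1", "d2"], "age": [30.0, 60.0], "sex": "male",
             "pmi": 5.0, "condition": "control"}
        )
        with pytest.raises(ValidationError):
            train_clock(PseudobulkSet(expr, meta), donors, unit="astrocyte",
                        mode="simple_pseudobulk", n_folds=2)

    def test_model_json_roundtrip(self, astro_clock, astro_pbs):
        model, _ = astro_clock
        restored = model_from_json(model_to_json(model))
        X = astro_pbs.expression.to_numpy()
        assert np.allclose(model.ensemble_predict(X), restored.ensemble_predict(X))
        assert list(restored.gene_universe) == list(model.gene_universe)


def tiny_model(fold_coefs, intercepts=None, genes=("g0",)):
    genes = pd.Index(genes, name="gene_id")
    intercepts = intercepts or [0.0] * len(fold_coefs)
    folds = [
        FoldModel(np.asarray(c, dtype=float), float(b), 0.1, ["dX"])
        for c, b in zip(fold_coefs, intercepts)
    ]
    return ClockModel(unit="astrocyte", mode="simple_pseudobulk", alpha=0.5,
                      folds=folds, gene_universe=genes,
                      training_gene_means=np.zeros(len(genes)))


class TestPredictDonorAge:
    def make_samples(self, values, donor="d1"):
        expr = pd.DataFrame(
            {"g0": values},
            index=pd.Index([f"s{i}" for i in range(len(values))], name="sample_id"),
        )
        meta = pd.DataFrame(
            {"sample_id": expr.index, "donor_id": donor, "unit": "astrocyte",
             "replicate": range(len(values)), "n_cells_used": 1,
             "sampled_with_replacement": False}
        )
        return PseudobulkSet(expr, meta)

    def test_replicate_mean(self):
        model = tiny_model([[1.0]])
        table = predict_donor_age(model, self.make_samples([50.0, 60.0]))
        assert len(table) == 1
        assert table.loc[0, "predicted_age"] == 55.0

    def test_single_replicate_identity(self):
        model = tiny_model([[1.0]])
        table = predict_donor_age(model, self.make_samples([42.0]))
        assert table.loc[0, "predicted_age"] == 42.0

    def test_one_row_per_donor(self, astro_clock, astro_pbs):
        model, _ = astro_clock
        table = predict_donor_age(model, astro_pbs, aggregate=True)
        assert len(table) == astro_pbs.meta["donor_id"].nunique()

    def test_unknown_genes_direct_to_alignment(self, astro_clock):
        model, _ = astro_clock
        samples = self.make_samples([1.0])  # gene g0 not in the model universe
        with pytest.raises(ValidationError, match="align_genes"):
            predict_donor_age(model, samples)


class TestEvaluate:
    def frame(self, ages, preds):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(ages))],
             "donor_id": [f"d{i}" for i in range(len(ages))],
             "chronological_age": ages, "predicted_age": preds}
        )

    def test_perfect_predictions(self):
        perf = evaluate(self.frame([20, 50, 80], [20, 50, 80]))
        assert perf.pearson_r == pytest.approx(1.0)
        assert perf.mae == 0.0

    def test_constant_shift(self):
        perf = evaluate(self.frame([20, 50, 80], [25, 55, 85]))
        assert perf.pearson_r == pytest.approx(1.0)
        assert perf.mae == pytest.approx(5.0)

    def test_three_point_toy_matches_formula(self):
        ages = np.array([20.0, 50.0, 80.0])
        preds = np.array([30.0, 45.0, 90.0])
        perf = evaluate(self.frame(ages, preds))
        r_manual = (
            np.sum((ages - ages.mean()) * (preds - preds.mean()))
            / np.sqrt(np.sum((ages - ages.mean()) ** 2) * np.sum((preds - preds.mean()) ** 2))
        )
        assert perf.pearson_r == pytest.approx(r_manual)
        assert perf.mae == pytest.approx(np.mean(np.abs(preds - ages)))

    def test_zero_variance_gives_nan_not_zero(self):
        perf = evaluate(self.frame([20, 50, 80], [40, 40, 40]))
        assert np.isnan(perf.pearson_r)
        assert perf.mae == pytest.approx(70.0 / 3.0)


class TestNaiveBaseline:
    def build(self, donor_ages, n_folds=2):
        donors = pd.DataFrame(
            {"donor_id": list(donor_ages), "age": list(donor_ages.values()),
             "sex": "male", "pmi": 4.0, "condition": "control"}
        )
        ids = list(donor_ages)
        expr = pd.DataFrame(
            np.zeros((len(ids), 1)), columns=["g0"],
            index=pd.Index([f"{d}|s" for d in ids], name="sample_id"),
        )
        meta = pd.DataFrame(
            {"sample_id": expr.index, "donor_id": ids, "unit": "astrocyte",
             "replicate": 0, "n_cells_used": 1, "sampled_with_replacement": False}
        )
        pbs = PseudobulkSet(expr, meta)
        folds = assign_donor_folds(ids, n_folds=n_folds, seed=0)
        return pbs, donors, folds

    def test_prediction_is_training_mean_age(self):
        pbs, donors, folds = self.build({"d1": 20.0, "d2": 40.0, "d3": 60.0, "d4": 80.0})
        table = naive_mean_baseline(pbs, donors, folds)
        for _, row in table.iterrows():
            train_ages = [
                donors.set_index("donor_id").loc[d, "age"]
                for d in folds.index if folds[d] != row["fold"]
            ]
            assert row["predicted_age"] == pytest.approx(np.mean(train_ages))

    def test_constant_age_cohort_has_zero_mae(self):
        pbs, donors, folds = self.build({"d1": 50.0, "d2": 50.0, "d3": 50.0, "d4": 50.0})
        table = naive_mean_baseline(pbs, donors, folds)
        perf = evaluate(table)
        assert perf.mae == 0.0
        assert np.isnan(perf.pearson_r)  # constant predictions: r undefined


class TestFeatureGenes:
    def test_all_rounds_rule(self):
        model = tiny_model(
            fold_coefs=[[0.1, 0.3], [0.2, 0.0], [0.3, 0.1], [0.2, 0.4], [0.2, 0.2]],
            genes=("g_all", "g_partial"),
        )
        features = extract_feature_genes(model)
        assert list(features["gene"]) == ["g_all"]
        assert features.loc[0, "average_coefficient"] == pytest.approx(0.2)
        assert features.loc[0, "sign"] == 1

    def test_all_zero_model_has_no_features(self):
        model = tiny_model([[0.0]] * 5)
        assert extract_feature_genes(model).empty

    def test_recovers_simulated_age_genes(self, astro_clock, norm_small):
        """Most selected feature genes are true age genes of the generator."""
        matrix, _, _ = norm_small
        model, _ = astro_clock
        features = extract_feature_genes(model)
        assert len(features) > 0
        truth = matrix.genes["age_slope"]
        hits = truth.loc[features["gene"]]
        precision = (hits != 0).mean()
        assert precision >= 0.5
        concordant_sign = (np.sign(hits[hits != 0]) ==
                           features.set_index("gene")["sign"].loc[hits[hits != 0].index])
        assert concordant_sign.mean() >= 0.9


class TestFeatureOverlap:
    def test_disjoint_models(self):
        a = tiny_model([[1.0, 0.0]] * 5, genes=("gA", "gB"))
        b = tiny_model([[0.0, 1.0]] * 5, genes=("gA", "gB"))
        a.unit, b.unit = "astrocyte", "microglia"
        out = feature_overlap([a, b])
        assert out["common_to_all"] == []
        assert out["n_unique"] == 2

    def test_identical_models(self):
        a = tiny_model([[1.0, 2.0]] * 5, genes=("gA", "gB"))
        b = tiny_model([[1.0, 2.0]] * 5, genes=("gA", "gB"))
        a.unit, b.unit = "astrocyte", "microglia"
        out = feature_overlap([a, b])
        assert out["common_to_all"] == ["gA", "gB"]
        assert out["n_shared"] == 2

    def test_single_shared_gene_across_three_models(self):
        models = []
        for i, unit in enumerate(["astrocyte", "microglia", "OPC"]):
            coefs = np.zeros((5, 3))
            coefs[:, 0] = 1.0      # gene shared by all
            coefs[:, 1 + (i % 2)] = 0.5 if i < 2 else 0.0
            m = tiny_model([row for row in coefs], genes=("g_common", "gX", "gY"))
            m.unit = unit
            models.append(m)
        out = feature_overlap(models)
        assert out["common_to_all"] == ["g_common"]
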