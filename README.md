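# ctclock

Cell-type-specific transcriptomic aging clocks for single-nucleus RNA-seq.

Brain aging proceeds differently in different cell types, and bulk-tissue
aging clocks cannot resolve that. `ctclock` implements the full analysis
needed to build and apply *per-cell-type* transcriptomic age predictors
from snRNA-seq count matrices: nucleus-level QC and log-normalization,
pseudobulk aggregation (simple and bootstrapped), elastic-net age
regression with donor-level cross-validation, transfer of trained clocks
to independent datasets with missing-gene imputation, and residual-based
age-acceleration inference for disease cohorts. A negative-binomial cohort
simulator with known ground truth (age-trending genes, disease cohorts
with a shifted effective age) makes every stage testable without access to
human data.

It is aimed at computational biologists studying aging and
neurodegeneration who have a gene-by-cell count matrix, per-cell
annotations (donor, cell type) and donor covariates (age, sex, PMI,
condition).

## The model

For a unit *u* (one of the six major cortical cell types —
oligodendrocytes, astrocytes, microglia, OPCs, excitatory and inhibitory
neurons — or an aggregation level: glia, neuron, all cells), samples are
either single cells, one per-donor mean (simple pseudobulk), or *B*
bootstrapped pseudobulk replicates per donor, each the average of *k*
randomly sampled cells. A clock is a penalized linear regression of donor
age on log-normalized expression **x**:

  minimize  (1/2n) Σᵢ (yᵢ − β₀ − **xᵢ**ᵀ**β**)² + λ [ α‖**β**‖₁ + (1−α)/2 ‖**β**‖₂² ]

with mixing weight α = 0.5 by default (α ∈ {0, 0.5, 1} supported) and λ
chosen by inner cross-validation over a log-spaced path. Training uses
donor-level 5-fold cross-validation — folds partition donors, never
samples — so no individual contributes to both training and test data.
Performance is the Pearson correlation and mean absolute error (years)
between chronological and predicted age of the pooled out-of-fold
predictions, compared against a naive baseline that predicts each fold's
training-mean age. *Feature genes* are those with non-zero coefficients in
all five rounds; the sign of their averaged coefficient is the modeled age
trend.

Applying a clock elsewhere: external samples are aligned to the clock's
gene universe, unmeasured genes are imputed with the clock's training
means, and the five per-round models are ensembled (mean prediction). *Age
acceleration* is the residual of predicted age from the least-squares line
of predicted on chronological age; disease-vs-control differences are
tested with a covariate-adjusted Gaussian GLM on donor-level accelerations
(or a donor-random-intercept mixed model for per-cell data), the effect of
interest being the coefficient of the 0/1 disease indicator, in years.

## Worked example

```python
import ctclock as cc

spec = cc.CohortSpec(                      # 12 donors, ages 20-90, one cell type
    n_donors=12,
    cell_types={"astrocyte": (60.0, 8.0)}, # ~60 cells/donor, NB dispersion 8
    n_genes=500, n_age_genes_pos=25, n_age_genes_neg=25,
    seed=0,
)
cohort = cc.generate_cohort(spec)

loose = cc.QCThresholds(min_counts=1, max_counts=1e12, min_genes=1,
                        max_genes=10**7, max_mito_fraction=1.0)
matrix, cells, _ = cc.qc_filter(cohort.matrix, cohort.cells, loose)
matrix = cc.log_normalize(matrix)          # CP10K + log1p
matrix = cc.drop_mito_sex_genes(matrix)

config = cc.BootstrapConfig(k_per_unit={"astrocyte": 25}, n_replicates=50, seed=1)
pbs = cc.bootstrap_pseudobulk(matrix, cells, "astrocyte", config)
model, predictions = cc.train_clock(
    pbs, cohort.donors, unit="astrocyte", mode="bootstrapped_pseudobulk",
    alpha=0.5, seed=2,
)

donor_preds = (predictions.groupby("donor_id")
               .agg(predicted_age=("predicted_age", "mean"),
                    chronological_age=("chronological_age", "first"))
               .reset_index())
perf = cc.evaluate(donor_preds)
features = cc.extract_feature_genes(model)
print(f"donor-level cv r = {perf.pearson_r:.3f} (p = {perf.r_p_value:.1e}), "
      f"MAE = {perf.mae:.1f} years")
print(f"feature genes selected in all 5 folds: {len(features)}")
print(features.head(3).to_string(index=False))
```

Output:

```
donor-level cv r = 0.998 (p = 5.5e-13), MAE = 2.5 years
feature genes selected in all 5 folds: 52
 gene  average_coefficient  sign
G0000             0.883331     1
G0028             0.545320     1
G0045             0.232955     1
```

The clock tracks donor age far better than the naive mean (here MAE 2.5 y
on held-out donors), and the genes it keeps in every round recover the
simulator's planted age-trending genes with the right coefficient signs.

A thin CLI mirrors the library
(`ctclock simulate-cohort | qc | normalize | pseudobulk | train | apply |
accelerate`); trained clocks serialize to JSON and pseudobulk sets and
prediction tables to TSV.

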