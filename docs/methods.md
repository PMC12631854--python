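# Methods

## Scope and assumptions

`ctclock` models chronological age as a linear function of log-normalized
gene expression within one cell population at a time. The core assumptions
are (i) expression changes monotonically (on the model's linear scale)
with age for a subset of genes, (ii) donors are exchangeable given age and
the recorded covariates, and (iii) cells of a donor are conditionally
i.i.d. draws from that donor's cell-type-specific expression state — which
is what justifies averaging them into pseudobulk samples. Cell-type labels
are taken as given; clustering, annotation, doublet removal and batch
integration are upstream of this package.

## Ingest and QC

Matrices are genes x cells, raw counts, read from MatrixMarket triplets
with `features.tsv` / `barcodes.tsv` sidecars (10x convention) or a dense
TSV for toys. Nucleus filters retain cells with total counts in
[1200, 100000] and detected genes in [800, 12000] — both bounds
inclusive, following the usual reading of "between" — and mitochondrial
fraction strictly below 0.05 (a cell at exactly the cut-off is removed).
All five gates are overridable. QC metrics are recomputed from the matrix
when the cell table lacks them; supplied values win, so toy fixtures can
pin metrics directly. Normalization is counts-per-10000 followed by
log1p; 10,000 is the default scale of the standard single-cell workflow
this mirrors, and the transform preserves zeros and within-cell rank
order. Mitochondrial and sex-chromosome genes are removed before
modeling; synthetic data carries explicit `mito`/`sex` flags, real data
can derive them from the `MT-` name prefix and a configurable chrX/chrY
gene list.

## Pseudobulk aggregation

Simple pseudobulk is the mean log-normalized profile over all of a
donor's cells of a unit (cell type, or the glia / neuron / all-cells
pools), one sample per donor. Bootstrapped pseudobulk draws
`n_replicates = 100` subsets of `k` cells per donor and averages each;
this restores the sample-to-sample variance that the simple mean
destroys, which is what lets the downstream regression see within-donor
variability. `k` defaults per unit (oligodendrocytes 200; astrocytes,
microglia, OPCs 50; excitatory and inhibitory neurons 100; levels 100)
and can be chosen automatically as the largest value on the grid
{25, 50, 100, 200, 500} for which at least 80% of donors have more than
`k` cells. Sampling is without replacement when a donor has at least `k`
unit cells and with replacement otherwise (the sample is flagged):
without replacement preserves within-donor variance structure, and the
fallback keeps shallow donors usable rather than silently dropping them.
Replicate RNG streams derive from (seed, unit, donor, replicate), and a
donor's column indices are put in canonical matrix order before sampling,
so results are independent of iteration order and of the cell table's row
order.

## Clock fitting

The regression objective follows the glmnet convention,
`1/(2n)·RSS + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²)`, with mixing weight α = 0.5 by
default and α ∈ {0, 0.5, 1} supported. Features are standardized before
fitting (zero-variance features get zero coefficients) and coefficients
are reported back on the original scale; an unstandardized mode exists
for analytic checks. α > 0 is solved by coordinate descent
(scikit-learn `ElasticNet`, Gram precomputation, tolerance 1e-4); α = 0
maps to ridge with penalty matrix `n·λ·I` on centered features, i.e.
`(XᶜᵀXᶜ + nλI)β = Xᶜᵀy`, solved directly. The response is used unscaled —
note that R glmnet standardizes the response internally, so its reported
λ only matches this convention exactly at α = 1.

λ is selected per training fold by inner 3-fold cross-validation
(grouped by donor when donor ids are available) over a 10-point
log-spaced path from λ_max — the smallest λ with an all-zero solution —
down two decades, taking the minimum mean validation MSE; ridge
validation errors along the path are obtained from a single SVD per inner
fold. A fixed λ can be passed instead, which is how the oracle tests pin
the solution. Degenerate inputs are handled, not errored: a constant-age
training fold yields an intercept-only model.

Clocks are trained with donor-level 5-fold cross-validation: a seeded
shuffle partitions donors into folds differing in size by at most one;
every sample inherits its donor's fold; each round fits on the
out-of-round donors' samples and predicts every held-out sample. The five
per-round models are kept verbatim and always ensembled (mean) when the
clock predicts new data; the "average coefficient" reported for feature
genes is interpretive only. Training gene means — used later for
imputation — are computed over the exact samples the clock was trained
on. The naive baseline predicts each round's training-sample mean age and
is evaluated with the same fold structure. Evaluation reports Pearson r
(two-sided p) and MAE in years; zero variance in either variable leaves r
undefined (NaN), never coerced to 0.

## External transfer

External samples are reordered to the clock's gene universe; genes the
external data lacks are filled with the clock's training means (so they
contribute a constant, exactly as if the gene were measured at its
training average — the package tests this equivalence exactly); extra
genes are dropped and counted. When more than half the universe is
imputed the transfer proceeds under a prominent warning, since
predictions then collapse toward a constant. Two diagnostics quantify
transfer support: the fraction of feature genes expressed at all in the
external data (default: nonzero in at least one cell or sample;
threshold configurable), and trend concordance — per feature gene, the
Spearman correlation of expression with donor age, Benjamini-Hochberg
adjusted across the feature set, a gene counting as concordant when the
adjusted p < 0.05 and the correlation sign matches the clock
coefficient's sign. Constant genes have undefined correlation and count
as non-concordant. Single-cell clocks are diagnosed on per-cell
expression; pseudobulk clocks on per-donor unit means — the caller
controls this by what samples it passes.

## Age acceleration

Acceleration is the residual of predicted age from the ordinary
least-squares line of predicted on chronological age. The line is fitted
on all provided samples by default — pooling controls and disease puts
both groups' residuals on one scale, which is what the group test needs —
with a controls-only fit available for display-style analyses where each
condition gets its own line; neither mode is claimed to be the only
defensible one. Group inference regresses acceleration on the 0/1 disease
indicator plus covariates (age, sex, PMI, and brain pH / hemisphere when
present; unavailable covariates are dropped with a log entry): a Gaussian
GLM (equivalently OLS) on donor-level accelerations, or, for per-cell
tables, a linear mixed model with a random intercept per donor — donors
are the only grouping structure assumed. A non-convergent mixed fit
falls back to the GLM and says so. With no covariates the GLM coefficient
reduces exactly to the difference in group mean acceleration.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes: `n_donors`
(default 30) with ages uniform on [20, 90] years, the six major cell
types at negative-binomially dispersed per-donor cell counts (default
mean 150, dispersion 8), and `n_genes` (default 2000) with log-normal
baseline abundances (median 0.5 counts/cell, σ = 1). A subset of genes
(default 50 + 50) carries age trends: counts for gene *g* in a cell of
donor *d* are negative binomial (dispersion θ = 2) with
`log μ = log(base_g) + slope_g · (effective_age_d − 55)`, slope
±0.02/year, centered at the midpoint of the age range so the gene table
is independent of the donor draw. Null genes are age-flat; a fraction of
them (2% + 2%) is flagged mito/sex to exercise gene removal. Disease is
an effective-age shift: diseased donors (a `disease_fraction` of the
cohort) sample expression at `age + age_shift` years while keeping their
chronological age — making age-acceleration recovery a well-defined
ground truth. All randomness flows from one root seed through
purpose-keyed `SeedSequence` streams; gene-level parameters depend only
on the root seed, so an independent donor draw from the same gene program
(the external-transfer scenario) is available by re-seeding the donor
stream, optionally with a fraction of genes removed entirely to emulate
unmeasured genes.

What the generator does *not* emulate: batch and chemistry effects,
ambient RNA, doublets, cell-type misannotation, non-monotone or
cell-type-interacting age trajectories, and realistic gene-gene
correlation. Passing tests therefore demonstrate that the machinery is
correct and recovers planted signal under the stated noise model — not
that clocks trained on real tissue will attain comparable accuracy.

## Null clocks and the sign of cross-validated correlation

With no age signal, the inner CV drives λ to full shrinkage and each
round predicts (close to) its training-mean age. Pooled out-of-fold
predictions of that form are *negatively* correlated with age: a round's
training mean moves opposite to its held-out donors' mean, giving
r ≈ −0.37 in expectation for pure fold-mean predictions with 30 donors in
5 folds (observed ≈ −0.22 on average, since some rounds retain noise
coefficients). This cross-validation artifact is worth knowing when
reading near-null clock performance: the honest no-signal signature is a
*negative* pooled r together with MAE no better than the naive baseline,
not r = 0.

## Problem sizes used in the test suite

The acceptance-style tests run the full study design where it matters and
scaled-down cohorts where replication dominates the cost: signal recovery
uses the default design (30 donors, six cell types at ~150 cells/donor,
2000 genes, k = 100, 100 bootstrap replicates); null calibration uses 20
replicate single-cell-type cohorts (30 donors, 400 null genes, 20
replicates, k = 25); disease inference trains one clock on a 30-donor
single-cell-type design (400 genes, 80 age genes) and then draws 200
fresh 40-donor cohorts per branch (50% diseased, shift 0 or +8 years);
the transfer-degradation sweep averages donor-level r over five external
draws at each of 0%, 30% and 60% gene dropout. The whole suite runs in a
few minutes on one CPU.

## Known limitations

Alignment, integration, clustering and annotation are out of scope, as
are tree-ensemble regressors and multiple-testing correction across cell
types in the disease tests. The λ path (10 points, two decades) trades
resolution for speed; a finer path changes selected penalties slightly
but not the qualitative behaviour. Mixed-model inference uses the
asymptotic Wald p-value of the disease coefficient; with few donors per
arm a permutation test would be more defensible.
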