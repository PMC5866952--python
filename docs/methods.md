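# Methods

`drymarker` implements a marker-discovery workflow for predicting potato
drought tolerance from leaf metabolite and transcript profiles. This note
documents the statistical procedures, the parameters that matter, the
synthetic data the package is validated on, and the limits of what those
validations show.

## Tolerance quantification (DRYM)

Drought tolerance is defined as starch-yield *stability*, not absolute
yield. For cultivar c in trial t with paired control/drought arms:

* replicate yields are averaged per (cultivar, trial, treatment) cell;
* relative starch yield `rel(c,t)` = drought cell mean / control cell mean;
* `DRYM(c,t) = rel(c,t) − median_c rel(c,t)` — subtracting the per-trial
  median removes trial-level severity, so the per-trial median of DRYM is
  zero by construction and values are comparable across years and sites;
* per-cultivar scores average DRYM unweighted over trials, with the
  standard error `sd/√(#trials)` (undefined for one trial);
* trial severity is summarized separately by the stress index
  `SI(t) = 1 − mean drought yield / mean control yield` over all cultivars.

Cultivars are ranked by mean DRYM and split at the empirical 1/3 and 2/3
quantiles into low / intermediate / high tolerance. A value exactly on a
boundary goes to the lower class; tied values therefore always share a
class, making the assignment order-invariant and monotone. For 31 cultivars
with distinct values this yields class sizes 11/10/10. Degenerate inputs
(all scores equal, single-cultivar trials, zero control yields) raise or
are excluded with warnings rather than silently producing zeros.

## Feature-table preprocessing

**Log transform.** Metabolite intensities are log10-transformed; missing
cells propagate; non-positive values are an error naming the cell.

**Nuisance correction.** GC-MS campaigns leave additive technical
structure. Per feature, an ordinary-least-squares model is fit on present
cells with genotype (sum-to-zero coded) plus the nuisance terms:
measurement batch (sum-coded factor), run-order position (centred
continuous), and each sample's mean log-intensity over all features (the
"response" covariate, centred continuous). The fitted nuisance
contribution, mean-centred over the fitted samples, is subtracted, leaving
grand mean + genotype effects + residual. Because the subtraction is a
projection, refitting the same model on corrected data returns nuisance
coefficients of exactly zero, and the correction is idempotent — provided
the response covariate is not recomputed from corrected values, so it is
computed once from the input and stored in the sample metadata. Nuisance
factors with a single level drop out; designs where a batch is nested
inside one genotype are flagged with a warning (effects are then not
separable and shared variation stays with genotype).

**NIPALS imputation.** Missing cells are completed by principal components
estimated with NIPALS on present cells only: scores and loadings are
computed with inner products restricted to observed entries, components
are extracted sequentially with deflation, and missing cells are replaced
by the rank-k reconstruction (column mean + scores × loadings). The column
means used for centring themselves depend on the missing cells, so the
means and imputed values are refined in an outer loop until they stabilize
(relative change < 1e−6, stall-detected, ≤ 30 passes); on exactly low-rank
data this converges to the exact completion (a masked cell of a rank-1
matrix is recovered to ~1e−8). Defaults: 5 components (2 in the pipeline
driver, see below), inner tolerance 1e−9 on the score-change norm, 500
inner iterations. Present cells are never altered. Features with > 40%
missing cells are dropped first (configurable guard; the emulated global
missingness is 5.5% / 2.2%).

**PCA QC.** Centred PCA (full SVD) of the completed matrix provides score
plots and explained-variance fractions for quality control only.

**qPCR normalization.** For each sample, ΔCt(gene) = Ct(gene) − mean Ct of
the designated reference genes; relative expression is 2^−ΔCt, carried on
the log10 scale for modelling. Samples missing any reference Ct are
excluded with a warning; missing target Cts stay missing. Adding a
constant to all Cts of a sample cancels exactly.

## Reference-gene and marker-candidate screening

Reference candidates are taken from an RNA-Seq matrix as genes whose mean
FPKM lies in an absolute window (default 5–45, deliberately not
scale-invariant) ranked ascending by variance of log2 FPKM. Measured
candidates are then ranked by the coefficient of variation of raw Ct
across all samples, with an additive ANOVA of Ct on cultivation type,
cultivar and treatment (statsmodels, type-II tests); genes with any factor
significant at α = 0.05 are flagged unstable. Note the α = 0.05 screen has
the usual type-I rate: with many candidate × factor tests, occasional
flags on genuinely stable genes are expected.

Transcript marker candidates must show (i) strictly higher mean expression
in tolerant than in sensitive cultivars in control-condition samples,
separately within field and within glasshouse material, and (ii) median
CPM strictly above 5 across all tolerant-cultivar samples. The candidate
set shrinks monotonically as the CPM threshold rises.

## Random-Forest models and marker selection

Classification uses a bagged ensemble of decision trees
(scikit-learn `RandomForestClassifier`) with ntree = 1000 and
mtry = floor(√p) features per split; mtry is configurable, including
mtry = p (plain bagged trees). Every sample inherits its cultivar's
tolerance class. Model error is estimated out-of-bag: each sample is voted
on only by trees whose bootstrap excluded it; per-class OOB error is
reported alongside. Feature relevance is the Gini importance (mean
decrease in impurity). The OOB standard error uses the binomial formula
√(e(1−e)/n).

Backward elimination starts from the full model and removes
`max(1, floor(0.2 × current count))` least-important features per step
(ties broken by feature id), refitting and recording (panel size, OOB
error, OOB SE) down to 2 features. The elimination order is taken from the
full model's importance and not re-ranked at later steps — re-ranking on
ever-smaller models induces selection bias — with `recompute_importance`
available as a switch. The final panel is the 1-SE choice: the smallest
panel whose OOB error is within one standard error of the minimum across
steps (SE taken at the first step attaining the minimum; ties on size go
to the earlier step).

All stochastic stages are bit-reproducible for a fixed seed.

## Validation metrics

Confusion matrices use rows = predicted, columns = observed (low /
intermediate / high), so column totals are observed class sizes.
Sensitivity(c) = counts[c,c] / column total; specificity is one-vs-rest
TN/(TN+FP) on the collapsed table; overall accuracy is the trace over the
total. A class absent from the observations has undefined (NaN)
sensitivity. Per-trial accuracies are computed within each validation
trial with a pooled "overall" row. Display tables round to one decimal in
percent; machine-readable output keeps full precision.

## Synthetic study

The generator reproduces the structure of a multi-year, multi-site field
study, with ground truth recorded for every planted parameter.

**Yields.** Each of 31 cultivars carries a latent tolerance effect
τ ~ N(0, 0.06) — its proportional yield advantage under drought — spanning
the roughly −6%…+10% DRYM range typical of European cultivar panels. True
classes are tertiles of τ. Control replicate yields are cultivar-specific
log-normal draws (base 10 t/ha, cultivar spread 0.15 log units); drought
yields multiply by (1 − severity) × (1 + τ), with per-trial severities
uniform on 0.2–0.5 (the planted severity equals the trial's true SI). The
plot-level noise default (CV 1%, 4 replicate plots) is deliberately low:
it makes the phenotype reference clean enough that downstream validation
measures the marker pipeline rather than phenotype noise (recovered
classes match the planted ones for ~29–31 of 31 cultivars, median 30;
DRYM–τ Spearman ρ ≈ 0.98). Real field trials are considerably noisier;
`replicate_cv` exposes that regime.

**Feature blocks.** The metabolite block covers 5 experimental trials × 31
cultivars × 2 treatments × 3 replicate pools (930 training samples) plus
16 agronomic trials × 31 cultivars (496 validation samples, control-like,
no drought arm) over 115 features; the transcript block covers 3
experimental trials (186 samples) and 6 agronomic trials (186 samples)
over 43 features, sharing sample ids with the metabolite block on common
trials so the blocks can be joined for combined models. 10 metabolite and
8 transcript features are class-informative and constitutive: their means
shift with tolerance class in control and drought samples alike. Per
feature, the low-to-high span is fixed at 2 × effect_size noise-SD units
(default effect_size 1.0) and the intermediate-class mean sits at a
uniform random position inside the span — each marker discriminates one
boundary of the tolerance range more sharply, as real marker panels do;
the mean adjacent-class separation remains effect_size. The remaining
features are pure noise: with effect_size 0 the data carry no class
information at all and downstream OOB error sits at chance (2/3). An
optional `cultivar_sd` adds cultivar-level offsets within class (off by
default, for the same reason), and `n_stress_responsive` adds
drought-shifted confounder features. Technical structure is added on the
log scale: per-campaign batch offsets (SD 0.5; batch = trial), a linear
run-order drift (slope SD 0.3), and missing cells (5.5% / 2.2%, MCAR by
default; an optional left-censored mode masks low-intensity cells
preferentially, as GC-MS missingness usually is). Metabolites are
delivered as raw intensities spanning ~4–6 decades (expecting the log
step); transcripts as log10 relative expression.

With these defaults the Monte-Carlo Bayes error of the planted metabolite
geometry is 5.4–6.1% and the full 115-feature forest lands at a 7–12% OOB
error (5-seed mean ≈ 10%) — the gap is inherent forest inefficiency in
the presence of 105 irrelevant features. Backward elimination recovers the
planted 10-marker panel essentially always, the reduced model's OOB
matches the full model's within 2 points, and the combined
metabolite+transcript model is at least as good as metabolite-only on the
shared samples.

**qPCR tables.** 124 screening samples (31 cultivars × field/glasshouse ×
control/drought) with: stable reference genes (gene-specific base Ct
18–24, across-sample spread 1 cycle → CV ≈ 0.05, no factor effects);
unstable decoys carrying either a +2-cycle drought shift or
cultivar-specific offsets (SD 1 cycle); and target genes encoding a
planted log10 expression through Ct = observed reference mean − log2
expression + noise (0.1 cycles), so normalization recovers the planted
expression up to that noise by construction.

**What the synthetic validations do not show.** Features are conditionally
independent given class; real metabolite profiles are strongly
inter-correlated and carry dominant genotype variance in every feature.
Class effects are planted directly on the tertile classes; in reality
molecular state and yield stability are joint consequences of physiology,
and phenotype classes are themselves noisy. Validation samples come from
the same 31 cultivars as training (as in the emulated design) — accuracy
on *unseen genotypes* is a different and harder question the package's
validation deliberately does not claim. Passing tests therefore
demonstrate correctness of the algorithms and qualitative reproduction of
the published regime, not expected field performance.

## Numerical and design choices

* Tertile boundary convention: boundary values to the lower class
  (deterministic, order-invariant); degenerate all-equal scores are an
  error.
* OLS correction uses numpy least squares on an explicit sum-coded design
  (per-feature present-cell subsets make formula re-parsing the
  bottleneck); rank-deficient designs fall back to the pseudoinverse
  solution with a nesting warning.
* The pipeline driver imputes with 2 NIPALS components (the corrected
  matrices have a low-dimensional biological structure; rank-5
  reconstructions were observed to propagate noise into imputed cells,
  costing ~1.5 OOB points on synthetic data). The library function's
  default remains 5 components for general use.
* Elimination refits use the same seed as the full fit; OOB estimates at
  500 trees are indistinguishable from 1000 at these sample sizes, and the
  test suite uses the smaller forests to halve runtime. The acceptance
  script runs ntree = 1000.
* Problem sizes in the test suite (tiny designs for end-to-end,
  determinism and monotonicity checks; 5 seeds for the selection regime)
  are chosen to keep the full suite in a few minutes on one CPU.

## Known limitations

* `classify_tolerance` implements tertiles only (`n_classes=3`).
* The ANOVA correction is additive; interaction or non-linear batch
  effects are out of scope (as are median scaling, quantile normalization
  and empirical-Bayes batch correction).
* No permutation importance, nested cross-validation, class weights or
  stratified bootstraps; alternative learners are out of scope.
* The 1-SE rule's SE is the binomial formula; it ignores the correlation
  between OOB errors of nested models.
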