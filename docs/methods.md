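# Methods

## Program-level inference

A sample's preprocessed expression vector is regressed, by ordinary least
squares, on a three-column design: an intercept, the confounder weight
vector and the program weight vector. The resistance pair couples R with
its confounder T; the systemic-inflammation pair couples SI with IM1. The
two pairs are fitted as *separate* two-predictor models (matching the
model's presentation as two independent decompositions), not one joint
four-predictor model; because the weight vectors are near-orthogonal in
practice, the omitted-variable bias from fitting pairs separately is small
(see *Generator* below for the stress case). The weight vectors themselves
are external inputs — the package never re-derives them.

Missing genes are excluded per sample (pairwise deletion inside that
sample's regression), never by dropping the gene cohort-wide. A design
whose condition number exceeds 1e8 on the observed-gene overlap is rejected
as collinear. Inference requires at least `min_overlap = 50` genes shared
between matrix and weight map: with two predictors plus intercept this
keeps the regression overdetermined by more than an order of magnitude.

Levels are standardized against healthy controls (mean/SD of the control
samples' levels; population SD, see *Numerical conventions*), and the
balance score is the standardized R level minus the standardized SI level.
For cohorts without healthy controls the reference falls back to the
cohort itself and outputs carry `reference_mode = "cohort"` — the only
self-contained option, chosen over importing an external reference.

## Preprocessing

Four steps, in fixed order, applied per input matrix:

1. **Missing-data policy.** Zero counts on a linear scale are treated as
   missing. The regime is chosen by the overall missing fraction *m*:
   *m* < 1% — drop any gene with a missing value; 1% ≤ *m* < 15% — drop
   genes missing in > 75% of samples, then KNN-impute (k = 5); *m* ≥ 15% —
   drop high-missing genes, leave the rest missing (downstream fits use
   pairwise deletion). KNN neighbors are genes, the standard convention for
   expression imputation; gene–gene distance is Euclidean over co-observed
   samples normalized by the number of shared samples, neighbors are
   restricted to genes observed at the target sample, and a hole with no
   usable neighbor stays missing (warned) rather than being filled with a
   column mean.
2. **Log2 transform** (skipped, with the zero-to-missing rule disabled, for
   data flagged already-log: zeros are meaningful on a log scale).
3. **Per-sample standardization** across genes (observed entries only).
4. **Per-gene standardization anchored on healthy controls**: gene means
   and SDs come from controls only and the transform is applied to all
   samples, so patient values read as deviations from the healthy
   distribution. Genes constant in controls are dropped with a warning.

Both standardizations are exact invariants after the pipeline (mean 0, SD 1
to 1e-9) and the pipeline is deterministic.

## Validation

**Inter-individual (hold-out) scheme.** Genes are partitioned into ten
disjoint folds ("10 repeats of 10% without replacement" read as one random
partition — the without-replacement clause forces disjointness). For each
fold, program levels are re-inferred with the fold's genes excluded, and
each held-out gene is regressed on the inferred levels under three nested
models: joint (R + SI), R-only, SI-only. Per gene we record R² and the
overall-regression F-test p from the fold where it was held out. The
permutation null reshuffles the sample order of the level matrix relative
to the held-out expression before the same regressions (identity
permutation excluded); null R² values are pooled across genes and
permutations. Empirical p uses the +1-corrected estimator
(1 + #{null ≥ real}) / (1 + N), which is never exactly zero. TPR(c) and
FPR(c) are the fractions of real and permuted genes with R² > c; precision
is TPR/(TPR+FPR) under the matched equal-size convention of one permuted
copy per real run.

**Inter-gene scheme.** Per sample, R² of the expression profile on the
weight design; the null permutes the gene weights (both columns jointly)
over genes. Default 100 permutations for gene-level nulls and 200 for
sample-level — enough resolution for p < 0.05 decisions at desk-scale
runtime; all permutation RNG is seeded.

## Benchmarking candidate programs

Geneset programs are scored per sample by the member-gene mean; weighted
programs by the fitted program coefficient. The disease-response statistic
is a two-sample Mann–Whitney z (tie-corrected), signed positive for
upregulation in disease; the "signed-rank" naming in the source tradition
notwithstanding, an unpaired disease-vs-healthy comparison requires the
rank-sum form. Cross-dataset covariation uses a local statistic — mean
pairwise Pearson correlation among program genes, z-scored against ≥ 50
size-matched random genesets from the same dataset (drawn with a
per-dataset seeded RNG so identical datasets tie exactly) — as a stand-in
for a remote co-expression search engine; externally computed rankings can
be fed to the F1 layer verbatim. The covariation-F1 score averages F1 over
cutoffs at each positive dataset's rank. Note that a perfect ranking does
not score 1 unless there is a single positive: at cutoff j of k positives
recall is j/k, so the optimum is mean_j 2j/(j+k) (5/6 for k = 2). For
weighted programs used as covariation queries, the 100 top-|weight| genes
form the query geneset.

## Single cells

Cells are scored exactly like bulk samples after a deliberately different
preprocessing: dropout zeros are kept as zeros (not missing), counts are
depth-normalized (counts-per-10k, default on for raw counts) and
log2(1+x)-transformed, each cell is standardized across genes, and
gene-level standardization is anchored on the *control cells of the same
subpopulation* — a subpopulation-matched reference that avoids composition
artifacts. A patient's R (or SI) response in a subpopulation is the signed
log10 p of a Welch t test (cell counts and variances differ grossly across
patients) of the patient's cells against all pooled control cells; p is
floored at 1e-300, capping |score| at 300. Responses need ≥ 10 cells on
both sides. The per-cell-type summary counts a patient as responsive when
any subpopulation × program test has p < α.

## Association and stratification

Variance explained regresses a phenotype on [intercept] + level columns
(SI-only, R-only or joint) and calibrates R² against phenotype
permutations; optional covariate columns give confounder-adjusted variants.
Correlation maps place features by Pearson r with z_SI and z_R
(pairwise-complete, n ≥ 10). Balance markers are genes whose per-cohort
Pearson correlation with the balance score averages (unweighted across
cohorts) above 0.6 (good balance) or below −0.45 (impaired); within each
set the top 300 markers are chosen by the monocyte-cohort correlation
magnitude. Enrichment uses the upper-tail hypergeometric test against a
caller-supplied universe with Benjamini–Hochberg adjustment; gene-set
collections are read from GMT, none are bundled.

Endotypes: balance ≥ threshold → moderate imbalance; otherwise high-SI if
z_SI reaches the cohort quantile cut, else severe imbalance. No numeric
thresholds are canonical, so they are explicit inputs with defaults of 0
(balance, "limited reduction" = non-negative) and the 85th z_SI percentile
(echoing a reported ≈16% high-SI share); `calibrate_thresholds` matches
target class proportions instead. Survival uses Kaplan–Meier curves,
log-rank or Breslow (generalized Wilcoxon) tests, and Cox
proportional-hazards fits with Efron tie handling (daily-resolution times
tie often) and age plus binary-coded sex as covariates, all via lifelines.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth retained. Per condition, per-sample latents (R, T, SI,
IM1) are multivariate normal. Default condition means: healthy (0,0,0,0),
moderate infection (2, 0.5, 1, 0.3), sepsis (0.5, 0.5, 2.5, 0.5); unit
latent SDs with a +0.5 within-condition correlation between R and SI —
both programs are co-activated arms of the immune response and co-vary
across individuals, and this correlation concentrates the within-group
spread of the balance (with independent latents the group means above
would cap the true-balance AUC for sepsis vs moderate at Φ(1.5) ≈ 0.93;
with the correlation the design reaches ≈ 0.98, matching the sharp
separation the framework is built around). Gene expression is baseline
N(8, 1) + weights · latents + N(0, noise_sd = 1) on the log2 scale, then
exponentiated to linear scale so the full preprocessing pipeline (zeros to
missing, log2, standardizations) is exercised. Weight vectors are standard
normal, orthogonalized when raw draws exceed the pairwise |corr| ≤ 0.1
target. Proteins load linearly on the latents (named CXCL11/IFNg analogs
on R, IL6/IL8 analogs on SI, plus noise proteins) so the biomarker proxies
run out of the box. Per-cell latents scatter N(0, 0.5) around patient
means drawn per condition; counts come from Poisson sampling of
depth-scaled exponentiated expression. Survival times are exponential with
hazard λ·exp(0.7·SI − 0.7·R), λ tuned so the expected event fraction by the
28-day administrative-censoring horizon is 59% (the high-mortality
ICU-sepsis regime).

All generators are pure functions of (config, seed). Deliberate
misspecification is preserved: all four latents act simultaneously while
inference fits pairs separately, reproducing the real pipeline's
omitted-variable risk (small under near-orthogonal weights).

What the generator does *not* emulate: realistic gene–gene correlation
beyond the latent-factor model, platform/batch effects, count overdispersion
in bulk data, cell-type composition shifts, or informative censoring.
Passing tests therefore demonstrate correctness of the machinery and its
behavior under the assumed model, not performance on real cohorts.

Two quantitative consequences of the pipeline worth knowing: per-sample
standardization divides each profile by its SD across genes
(≈ √(1+‖latents‖²)), a sample-dependent rescale that compresses inferred
levels — even noiseless data recover true latents at r ≈ 0.95 through the
full pipeline, and the per-gene SD rescale of step 4 mixes latents slightly
(r ≈ 0.99 noiseless). Exact recovery holds for inference on gene-centered
data. At the default noise level the levels recover the true latents at
r ≈ 0.94 (n = 300, 2000 genes).

## Numerical conventions

- Population SD (divide by n) everywhere a standardization is defined, so
  the mean-0/SD-1 invariants are exact; `ddof` is configurable.
- Missing values: NaN in memory, empty cells on disk; zeros become missing
  only on linear scales.
- Ranking ties in covariation rankings break by stable input order and are
  flagged.
- Empirical p-values are +1-corrected; permutation counts below 20 warn.
- Scale transitions are one-way (linear → log2 → standardized) and
  enforced.
- Seeds are mandatory for every stochastic component; the pipeline derives
  per-stage substreams from one root seed, and reruns with the same config
  produce bit-identical output hashes.

## Problem sizes

Default test and reproduction sizes — 2000 genes × 300 samples for the
main cohort, 500 genes × 100 samples for null calibration (100
permutations), 400 genes × ~2900 cells for single-cell checks, n = 500 for
survival recovery — were chosen so that every property (recovery r ≥ 0.9,
AUC ≥ 0.95, calibration within binomial tolerance of 5%) is measured with
comfortable statistical margin while the whole suite runs in well under a
minute's compute per stage.

## Known limitations

- The covariation statistic is a local surrogate; absolute covariation-F1
  values are not comparable to rankings produced by a full co-expression
  compendium, only the F1 machinery is.
- Probe-to-gene collapsing, batch correction and library normalization
  beyond counts-per-10k are out of scope; inputs are expected pre-collapsed.
- The balance threshold and high-SI quantile defaults are conventions, not
  estimates; analyses should state them explicitly (they are recorded in
  the endotype output).
- Confounder-adjusted association is provided but off by default.
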