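# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the problem sizes the test suite and the
acceptance script use. Nothing here states an empirical result that the
tests or `scripts/acceptance.py` do not themselves compute.

## Intelligence scores (psychometrics)

Twelve cognitive measures enter three scores per subject:

* **g** — exploratory bifactor model. Stage 1: maximum-likelihood EFA
  (scikit-learn `FactorAnalysis`) with `n_group_factors` factors
  (default 4) on the z-scored measures, followed by oblimin rotation via
  a gradient-projection algorithm implemented in-package (quartimin
  criterion, unit-length oblique columns). Stage 2: a principal-axis
  one-factor model on the factor correlation matrix. Schmid–Leiman
  orthogonalization (first-order pattern × second-order loadings) yields
  general-factor loadings on all measures. Scores are regression
  (Thurstone) scores, standardized. Sign convention: the majority of
  general loadings is non-negative, so flipping all measures flips g.
  We chose the exploratory route over confirmatory SEM because it needs
  no structural-equation dependency and is the standard two-stage
  exploratory bifactor construction; Heywood cases (loading² > 1) are
  flagged, not silently truncated.
* **gC** — sum of the two z-scored knowledge measures (picture
  vocabulary, reading recognition). Note SD(gC) = sqrt(2(1+r)), not 1;
  the composite is invariant to affine rescaling of either input.
* **gF** — single-factor ML EFA over the seven designated fluid
  measures. With one factor a rotation cannot change the solution; the
  configured rotation name ("oblimin") is recorded in the fit metadata
  for provenance.

Subjects with missing measures are dropped listwise before estimation.

## Connectivity (connectome)

* FC is atanh(Pearson r) between node time series; correlations with
  |r| ≥ 1−1e−7 are clipped before atanh with a logged warning (the
  transform is undefined at ±1 and the upstream pipeline never addresses
  degenerate correlations).
* Phase-encoding runs are averaged elementwise **on the Fisher-z
  scale** — the sources describe computing FC per run "separately and
  averaged afterward", which we read as averaging the transformed
  matrices; this is flagged as an interpretation.
* Edge vectorization: strict upper triangle, row-major, 0-based. The
  convention is recorded in every array-container sidecar.
* **Latent FC**: for each edge independently, a one-factor model across
  states (observations = subjects, variables = states), fit by ML
  factor analysis with a principal-axis fallback on non-convergence.
  Loadings signs are fixed so the per-edge mean loading is positive;
  scores are standardized. Edges with a zero-variance state (relative
  tolerance 1e−10) fall back to the standardized state mean and are
  flagged. Two modes: all states, or task states only.
* **Retest reliability**: ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — computed vectorized per edge from
  ANOVA mean squares. This form is the standard retest choice; the unit
  tests pin it to pingouin's ICC(A,1) to 1e−10.

## Connection selection

All selections are boolean edge masks with a provenance string that,
given the atlas and seed, fully determines the mask (serialized to JSON
for reproducibility). For m networks the network-based families count
1 + m + C(m,2) + m + m (43 at m = 7). Theory-driven selections map each
proposed cluster coordinate to the nearest atlas centroid (Euclidean
distance, ties to the lowest node id, logged); node sets are data, not
code, because they derive from external coordinate tables. Top-k
selections rank by absolute relevance by default — the source material
colors relevance displays by FC sign but ranks "most relevant"
magnitude-like — with ties broken by edge index.

## Prediction

* **Folds**: families sorted by family-average target, dealt
  round-robin in strata of `n_folds` consecutive families with a seeded
  shuffle inside each stratum. This keeps families intact and
  approximately equalizes fold target distributions; the test suite
  verifies fold-mean SD is less than half that of random family
  assignment.
* **Deconfounding**: OLS of target and every feature on
  [1, confounds], residuals z-standardized; coefficients and M/SD come
  from the training fold only and are applied unchanged to the test
  fold. A target fully explained by confounds raises by default
  (`on_zero_variance="keep"` passes raw zero residuals through, for
  degenerate-case analysis).
* **MLP**: hand-written numpy feed-forward regressor — ReLU hidden
  layers, scalar linear output, He initialization, inverted dropout
  0.25, full-batch SGD at lr 0.01 on MSE (mini-batches configurable),
  early stopping against the best-so-far validation loss with patience
  100 and a 20 000-epoch cap. "No decrease within the last 100 epochs"
  is implemented as best-so-far + patience, flagged as an
  interpretation. A numpy implementation was chosen because the models
  are small and the attribution module needs direct weight access.
* **Tuning**: inner family-aware 3-fold CV over the architecture grid
  (1–3 layers × 10/50/100 units); ties broken by parameter count.
* **Early-stop validation splits** are family-aware and seeded (20%
  outer, 30% inner).
* **Metrics**: Pearson r(y, ŷ); MSE/RMSE/MAE after dividing both
  vectors by range(y observed).
* **Determinism and leakage**: every random draw (folds, splits,
  weights, dropout) derives from explicit integer seeds, never from
  data values. `leakage_audit` corrupts one test fold's targets and
  features at a time and requires the fold's training artifacts
  (deconfounder bytes, chosen architecture, validation-loss history,
  final weights) to hash identically to the clean run.
* **Transfer**: a model trained on one cohort (deconfounder +
  predictor) applies unchanged to another; per-selection performance
  vectors across cohorts are compared by Pearson correlation.

## Relevance (LRP)

Epsilon-rule backward pass (ε = 1e−6) through the trained MLP's layers;
dropout inactive at attribution time. For bias-free networks the
per-input relevances sum to the output (conservation); with biases the
absorbed share is reported, not renormalized away. Per-edge relevance
is aggregated as the mean |R| across attribution inputs (signed means
are retained for reporting) because per-sample signed relevances of a
useful feature alternate with the feature's sign and would cancel.
Attribution inputs are training-fold subjects only. Stepwise LRP
removes the top `schedule[i]` edges per round and retrains; the default
schedule removes the top 1% of remaining edges (minimum 10) per round.
Aggregation across runs sorts per-edge values before the mean so the
result is bit-identical under any run order.

## Inference

Permutation tests shuffle targets **before** fold construction and
deconfounding, so the null preserves the full pipeline including
stratification; p = (b+1)/(m+1) on Fisher-z-transformed correlations
(never exactly zero). The model-difference test runs both selections on
the same shuffled targets (paired null) and is two-sided. With m
permutations the smallest attainable p is 1/(m+1) — tests that assert
p < 0.05 must use m ≥ 39. Multiple comparisons use Benjamini–Hochberg
at q = 0.05 (statsmodels). Graph metrics (participation coefficient,
within-module degree z) are computed on weighted matrices with negative
weights set to zero by default (binarization/absolute-value options
exist); zero-strength nodes get PC = 0 and zero-SD modules get z = 0,
both logged. The relevant-vs-random comparison evaluates per-edge
properties as selection means and per-node metrics as
occurrence-weighted node averages against 1 000 equally sized random
edge sets, two-sided.

## Synthetic study generator

The generator emulates the statistical structure of a large young-adult
family cohort; defaults are the study conditions, not tuning knobs:

* n = 806 subjects; family sizes truncated-geometric (p = 0.45, cap 5);
  a family-level random effect carries 30% of latent variance, leaving
  marginal correlations unchanged.
* Component correlation targets 0.78 (g–gC), 0.76 (g–gF), 0.49
  (gC–gF); rejected if not positive semi-definite.
* Confound–target correlations: age −0.13, sex 0.18, handedness 0.00,
  mean FD −0.20, spike proportion −0.20. Sex is a thresholded latent
  with the point-biserial correction (target/0.798); handedness is
  independent uniform on [−100, 100]; FD and spike proportion are
  affine in correlated latents (clipping at physical bounds is rare by
  construction).
* Measures: fluid tasks load 0.5 on g and 0.55 on the orthogonalized
  fluid group factor; crystallized tasks load 0.94 on gC (chosen from
  the closed form 2c/sqrt(2+2c²) so the two-test composite attains
  validity ≈ 0.97 — vocabulary/reading-type tests are among the most
  reliable, most g-loaded measures); remaining measures load 0.7–0.8 on
  g. Noise completes unit variance.
* Connectomes: per-edge baseline N(0.3, 0.25) Fisher-z units, per-edge
  noise SD U(0.15, 0.3), plus per-subject node factors (SD 0.1) that
  correlate edges sharing a node — the low-rank structure real FC
  matrices exhibit, and the reason edge sets concentrated on few nodes
  carry redundant information. Planted edges (default 1 000 of 4 950)
  carry beta × state-signal × block-latent, where block latents
  (default 10 blocks) correlate 0.7 with the designated component —
  partially redundant signal, so removing a block leaves information
  elsewhere. Confound leakage is additive per edge with per-edge random
  coefficients, so linear deconfounding has a true target. Noise splits
  into retest-stable and run-specific parts to match per-edge ICC
  targets U(0.3, 0.8); state FC is the mean of the two runs.
* Motion exclusion: mean FD < 0.2 mm, spike proportion < 0.2, max
  spike ≤ 5 mm.
* Determinism: byte-identical outputs per (config, seed).

What the generator does **not** emulate: BOLD hemodynamics, scanner
noise spectra, task timing, non-linear confound effects, spatial
autocorrelation beyond node factors, and realistic network-specific FC
topography. Passing tests therefore demonstrate that the *machinery*
(selection, deconfounding, CV, attribution, inference) behaves
correctly under the assumed generative structure, not that real
neuroimaging data meet that structure.

## Problem sizes

Full-scale defaults (806 subjects, 100 nodes, 10 states, 43 selections,
10 repetitions, m = 100 permutations) are what a study-scale run would
use. The test suite and the acceptance script run the same code at
reduced sizes chosen to exercise every property with comfortable
statistical margins on one CPU: cohorts of 120–2 000 subjects, atlases
of 10–30 nodes (45–435 edges), single states, singleton or two-element
architecture grids, 60–600 epoch budgets, and permutation counts of
19–99 (the plus-one p-value formula makes m = 19 a 0.05-resolution
test). Type-I-error calibration uses 200 repetitions of the full
pipeline at m = 19, n = 48, 3 folds. These are statistical design
choices: each scaled experiment retains the property it checks (e.g.
calibration needs only exchangeability, which is size-invariant).

## Known limitations

* The bifactor estimator is exploratory; with few group factors and
  strongly correlated components, the general factor can absorb group
  variance (the recovery floor 0.9 reflects this).
* Stepwise-LRP rankings derived on the same cohort later used for
  CV evaluation of top-k selections carry selection optimism; the
  qualitative comparisons (top-k vs. random) are designed around it,
  matching the original protocol's within-sample ranking.
* The epsilon-rule conservation error grows with the share of
  relevance absorbed by biases; conservation checks are therefore
  stated for bias-free networks.
* Full-batch SGD makes training deterministic per seed but is not
  batch-size-equivalent to the original mini-batch implementations.
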