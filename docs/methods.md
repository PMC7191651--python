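# Methods

This note documents the models and procedures emodecode implements, the
defaults and why, what the synthetic generator does and does not
emulate, and the numerical conventions that matter when comparing runs.

## Regression engine

All decoders and encoding models are ridge regressions solved in closed
form. Predictors and targets are z-scored with training-fold statistics
(population SD; constant columns get SD 1, which zeroes their weights),
weights solve `(XᵀX + λI)W = XᵀY` — via SVD when a λ grid is evaluated,
via the kernel form `Xᵀ(XXᵀ + λI)⁻¹Y` when voxels outnumber samples —
and predictions are mapped back to original units. At λ = 0 a
minimum-norm least-squares solution is used and rank deficiency raises a
warning. With all weights zero the model predicts the training target
mean, so the shrinkage limit is the mean predictor.

Cross-validation uses 6 outer folds (the study's design) and 5 inner
folds by default; folds are contiguous blocks in video order, with an
optional seeded shuffle, because the original fold construction is not
specified and contiguity keeps runs deterministic without a seed. The
penalty is selected **per target** by inner out-of-fold Pearson r on the
training portion of each outer fold (grid: 10 log-spaced values in
[1e−3, 1e3]; ties go to the smaller λ by grid order), then the model is
refitted on the whole training fold. Outer test rows never reach inner
selection or normalization statistics — a property the tests enforce by
corrupting held-out rows.

Evaluation is the Pearson correlation between out-of-fold predictions
and observations across all videos. A column whose observed values are
literally constant has undefined correlation and is reported as NaN
(decoding/encoding aggregates skip it and log the count) rather than
silently as 0. The constancy check uses the exact range of the raw
values, not the centered denominator, because centering a constant
column leaves O(machine-eps) jitter that would otherwise correlate
spuriously with the equally jittery constant prediction.

### Permutation thresholds

Significance of a correlation is assessed against a permutation null:
rows of the reference (true scores or measured responses) are permuted,
|r| against the unpermuted copy is pooled over permutations, and the
critical value is the `1 − α/m` quantile (two-tailed, Bonferroni divisor
m = number of regions or voxels). At least `10 / (α/m)` permutations are
required so the corrected tail holds ≥ 10 samples; fewer raise an
error rather than returning an unstable quantile. At the full study size
(n = 2,181 videos, α = 0.01, m = 370) 10⁶ permutations run in well under
a minute vectorized and land within 0.01 of the normal approximation
`z₁₋α/(2m)/√(n−1) ≈ 0.090`.

## Decoding

Region-wise decoders use only a region's voxels as predictors; all
emotions are decoded jointly (shared folds, per-emotion λ). The
ensemble decoder, per emotion and outer fold:

1. ranks regions by inner out-of-fold accuracy on the training fold
   (ties broken by registry order, which is stable and documented);
2. evaluates candidate sizes N ∈ {1, 2, 4, …, all} by the inner accuracy
   of the averaged prediction and keeps the best (smaller N on ties);
3. averages the selected regions' z-scored test predictions and maps the
   average back with the mean of the selected regions' own training
   (mean, SD).

Step 3's un-normalization convention is this package's choice: z-scoring
equalizes regions with different output scales, and rescaling by the
selected regions' average statistics (rather than the training-target
statistics) makes a singleton ensemble exactly reproduce its region's
prediction. Pearson evaluation is invariant to this affine choice.

## Identification

Both tasks reduce to correlation matching. The n-way emotion task draws
candidate sets without replacement (default 10,000 seeded resamples per
emotion; the exact resample count of the original analysis is not
published) or enumerates them exhaustively when `n_resamples=None`; a
trial is correct only when the congruent correlation is **strictly**
maximal, so exact ties count as errors. The pairwise video task scores
each of the n−1 foils once and credits exact ties 0.5 — symmetric, and
the convention is documented because the source analyses are silent on
ties. Chance levels are 100/s % and 50% respectively; the test suite
verifies both calibrations, with the caveat that for a single pair of
finite accuracy tables the null accuracy concentrates on a
table-dependent value (the congruent correlation's rank among 33 foils),
so calibration is assessed across independent table pairs.

## Encoding comparisons

Accuracy-vs-accuracy scatter plots are summarized by the angle of the
total-least-squares line through the origin (leading eigenvector of the
uncentered second-moment matrix). TLS is used because both axes are
noisy accuracy estimates; an ordinary regression of A on B would bias
the slope toward the predictor axis. The fit is origin-constrained so
the 45° parity line is a member of the model family. Model A is plotted
on the vertical axis: deviation θ − 45° > 0 means A wins.

Uncertainty comes from a **fold jackknife**: voxel accuracies are
re-evaluated omitting one outer fold's videos at a time (helper
`fold_deleted_accuracies`), giving 6 leave-one-out slope estimates and
the usual jackknife SE with a t test on 5 degrees of freedom. A
voxel-level jackknife was rejected because it conflates spatial
variability with sampling variability of the accuracy estimates.

Gradient profiles assign voxels to 10 equal-count bins by rank of a
per-voxel scalar (e.g., a principal connectivity gradient supplied as
input; its derivation is out of scope), report per-bin mean accuracy per
model, and — for two models — run per-bin paired two-tailed t tests with
Bonferroni correction over bins plus a two-factor bin x model ANOVA
interaction on voxel-level accuracies. Best-model maps label only voxels
significant under at least one model; ties go to the earlier model in
the stated priority order, and the labeling is invariant to any common
monotone rescaling of all models' accuracies.

## Structure

The 2-D embedding is UMAP (n_neighbors 15, min_dist 0.1, Euclidean,
fixed seed — recorded in the model's metadata since the original
hyperparameters are unpublished), chosen because its fitted mapping
projects held-out points: decoded scores are projected into the map
built from reported scores and compared per axis by Pearson r. The
per-axis metric is deliberately simple and fails under axis swaps or
rotations of an otherwise identical geometry; a test documents this
limitation.

k-means (k = 27 by default, matching the number of reliably distinct
emotion varieties reported for this stimulus set; 10 seeded restarts,
best inertia) clusters activity patterns of emotion-selected voxels
(those beating the voxel threshold under either emotion encoding model)
without ever seeing the scores. For each emotion, the `floor(0.05 n)`
top-scoring videos (109 at n = 2,181; cutoff ties resolved by stable
video order) are histogrammed over clusters; concentration is measured
by base-2 Shannon entropy (the base is this package's labeled choice),
bounded by log₂ k, with a permutation baseline defined as the
`α / n_emotions` lower quantile of entropies of random same-size
selections. Dimension-based profiles use the 28 positive/negative
columns obtained by splitting each dimension at the neutral point 5.

## Synthetic data

The generator emulates the study's data shapes and the linear-encoding
assumption, not fMRI physics. Category scores are zero-inflated
Beta(1.5, 5) (default zero mass 0.7, matching the sparse rater-proportion
histograms of this kind of rating), dimensions truncated Normal(5, 1.5)
on [1, 9]. A voxel in region r responds as
`Σ_e gain[r,e] · w[v,e] · z(score_e) + N(0, σ²)` with standard-normal
subject-specific weights, so the region x emotion informativeness map is
shared across subjects while voxel weights are not — exactly the
structure the cross-subject identification analyses assume. A variant
generator derives the dimension columns as noisy linear readouts of the
categories, the regime in which category models must outperform
dimension models; the category-primacy tests use it with 400 videos,
10 + 4 emotions, 12 regions x 15 voxels and noise SD 1.0 (strong signal,
as appropriate for voxels pre-selected for emotion prediction), and the
ensemble tests use 120 videos, 10 regions with 3 informative and noise
SD 3.0 (moderate signal, where pooling pays off). Not emulated:
hemodynamic convolution, spatial autocorrelation, motion artifacts,
inter-subject anatomical variability. Passing recovery tests therefore
shows the estimators are correct and leak-free under the linear model,
not that real scans meet its assumptions.

Test and example problem sizes (hundreds of videos, tens of regions) are
the package's default desk scale; every statistic is size-agnostic and
the full-size printed quantities that are analytically forced (the
370-decoder count, the 109-video top-5% selection, the 0.095-level
permutation threshold at n = 2,181) are exercised at full size in the
acceptance tests.

## Known limitations

- The original regularization family, λ grid, ensemble inner-CV depth
  and slope estimator are in an unavailable supplement; ridge, the grid
  above, one inner level and origin-constrained TLS are this package's
  documented choices.
- Headline empirical results of the motivating study (e.g., 71.4%
  five-way identification, 81.9% video identification, 34.6° slope)
  depend on the original subjects' scans and are not reproduction
  targets; the package reproduces the procedures and their forced
  statistics, and demonstrates the phenomena on planted ground truth.
- Per-axis map-reconstruction correlation is not rotation-invariant.
- UMAP determinism holds for a fixed seed and library version.
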