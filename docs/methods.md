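# Methods

This note documents the models and procedures implemented in `imctme`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical decisions a maintainer
would want written down.

## Marker masks

A marker mask declares, per pixel, whether the channel's signal is
present. Construction per channel:

1. **Median smoothing** — 3×3 window (configurable, odd), borders by
   edge replication (`scipy.ndimage.median_filter`, mode `nearest`).
2. **Intensity quantization** — pixels are clustered in one dimension
   into `n_levels = 6` groups. Because optimal 1-D k-means clusters are
   contiguous in sorted order, we solve the partition *exactly* by
   dynamic programming over the (weighted) distinct values rather than
   by randomized Lloyd restarts: the result is globally optimal and a
   pure function of the input, which removes the only stochastic step
   from mask construction. Channels with more than 2,048 distinct
   values are first collapsed onto 2,048 quantile bins (the DP is
   O(U²k)); at 16-bit count data this binning changes thresholds by
   less than the inter-level spacing. A `seed` argument is accepted for
   interface stability but has no effect.
3. **Foreground selection** — the brightest `foreground_level` groups
   are foreground. Signal is bright-on-dark, so levels are counted from
   the top. Default `foreground_level = 4` of 6: on realistic channels
   the background occupies the dimmest one or two groups and the
   log-normal signal spreads over the top three to four. Channels whose
   on-target mass is large (a tumour marker covering a third of the
   tissue) push the k-means boundaries upward and want
   `foreground_level = 5`; this is exactly the per-marker curation the
   panel configuration exists for, and every marker's parameters live
   in the panel, not in code. If quantization collapses below
   `n_levels` (low intensity diversity), the dimmest realized group is
   never made foreground — otherwise a clean two-valued channel would
   become all-foreground — and a constant channel yields an empty mask.
4. **Blob removal** — 8-connected components under `min_blob_area = 2`
   pixels are dropped (isolated noise pixels survive median filtering
   at realistic noise). Idempotent.
5. **Adaptive refinement** (off by default) — intersect with a local
   threshold mask, t(p) = mean₁₅ₓ₁₅(p) · (1 − s·(1 − I(p)/I_max)),
   sensitivity s = 0.4. The published description names only a
   sensitivity, so the formula is this package's decision; "amalgamated"
   is read as intersection, so refinement can only remove foreground.
   Both points are configurable rather than asserted as the original
   authors' choices.

Boundary pixels of small objects are intrinsically eroded by median
smoothing (a pixel whose window is majority-background reads as
background): with 3-px-radius cells, per-pixel mask recall saturates
near 70–75% while per-cell majority votes remain essentially perfect.
Mask fidelity is therefore assessed on larger structures (8-px radius),
where curated parameters give ≥95% pixel recall at ≤0.1% background
false positives.

## Phenotyping

The majority vector counts, per lineage marker, how many of a cell's
pixels fall in that marker's mask; argmax assigns the winning marker.
Decisions:

- **Ties** go to the lower `priority_rank` (more specific lineages rank
  first in the default panel: FOXP3 < CD8a < CD4 < … < panCK).
- **All-zero votes** yield `undefined` rather than a forced call.
- **Combination rules** map a winning marker to a label conditioned on
  a secondary marker's pixel fraction: CD68 splits into CD163⁺/CD163⁻
  macrophages, CD14/CD16 resolve classical, intermediate and
  non-classical monocytes. The default secondary threshold is 0.3 of
  the cell's pixels: masks recover roughly 60–75% of truly positive
  pixels on small cells (boundary erosion, above), so demanding a
  strict 0.5 majority of *all* pixels would systematically miss
  double-positives. The threshold is per-rule configurable.
- The supervised hierarchy shipped as `luad_type_rules()` (16 types +
  undefined) is a documented default, not a reproduction of any
  specific cohort's curated hierarchy, which is not published in
  machine-readable form.

Expression is the raw mean pixel value per channel (no transformation);
95th-percentile normalization (values/q₉₅ clipped at 1, linear
interpolation percentile) and z-scoring (ddof = 1) are display helpers.
Functional positivity is foreground fraction ≥ 0.5 by default.

## Interaction testing

Adjacency: minimum pixel-to-pixel distance between two cells' masks
≤ d = 6 px (inclusive), computed by a KD-tree over labelled pixels; a
centroid-distance rule is available. Statistic per ordered pair (A, B):
mean B-neighbour count over A cells — the histoCAT-family convention.
Null: joint shuffle of all labels within the core (not stratified).
P-values use the add-one estimator, so p ≥ 1/(n_perm + 1); ties count
toward the null tail (conservative). A two-sided call takes the smaller
of p_interact/p_avoid at α = 0.01. Group summaries average signed calls
(+1 interaction, −1 avoidance, 0 none) over a group's cores; the
fraction-significant alternative is a one-line change at the call site.

On sparse graphs the discrete statistic makes the permutation test
strictly conservative (type-I error below α) — a validity property, not
a defect. The calibration experiment therefore measures the test's size
on a well-connected graph (100 cells of 5 types on a 128² core,
adjacency radius 14 px, mean degree ≈ 5), where the per-one-sided-test
flagged fraction sits at α within Monte-Carlo error.

## Cellular neighbourhoods

Windows use Euclidean distance on centroids, within cores only, ties
broken by cell id, index cell excluded by default (`include_self`
switches to the convention that includes it; both appear in the
literature). Cores smaller than the window use all available cells and
are flagged. Clustering is scikit-learn `MiniBatchKMeans`
(batch 1,024, fixed `random_state`) fit on all cores jointly, giving
cohort-level CNs; tCN is a user choice (10 and 30 are the conventional
operating points, with an n = 3..30 sweep helper that refits CNs and
reports each CN's survival association). Prevalence is percent of a
core's cells per CN; largest-remainder rounding makes displayed rows
sum to exactly 100 at the chosen precision while raw fractions are kept
internally.

## Survival

Stratification at z = 0 (z ≥ 0 high, sample s.d.); zero variance is an
error. Patients with two cores contribute the mean of their cores
(configurable at the call site). Kaplan–Meier fitting delegates to
lifelines; the log-rank test is computed directly from the O/E/V
tabulation (the result object exposes observed/expected events and
at-risk trajectories, which the tabulation produces anyway) and is
cross-checked against lifelines in the tests. Tied event times use the
standard hypergeometric variance with the (n−d)/(n−1) correction.
Raw p-values are reported when scanning many CNs, matching the
field's convention for these analyses; `adjust_pvalues` applies
Benjamini–Hochberg when wanted.

## Outcome prediction

- **Backbones.** `testhash` is a deterministic, download-free
  embedding: per scale ∈ {1, 2, 4, 8}, 4×4 grid-pooled mean/std/max of
  intensity and mean/std of gradient magnitude plus a 16-bin histogram
  (384 features), projected to 2,048 dimensions by a Gaussian matrix
  seeded from the backbone id. It captures coarse spatial texture —
  sufficient to separate clustered from dispersed arrangements — with
  no learned weights, and keeps the pipeline's shape identical to the
  reference ResNet-50 backbone (single channel replicated across the
  three input planes, 2,048-d features before the classification
  layers), which requires torch + downloaded ImageNet weights.
- **Preprocessing**: per-channel scaling by the 99th percentile,
  clipped to [0, 1].
- **Reduction**: `MiniBatchSparsePCA`, 9 components, batch ≤ 50,
  `max_iter` 100, fit on training cores only; the l1 penalty is
  absolute, so low-rank structure is recovered when the signal scale
  dominates it.
- **Oversampling**: seeded resampling with replacement of each
  training class up to the majority count (exact parity), applied
  after reduction, training folds only.
- **Classifier**: `SVC(kernel="rbf", C=1, gamma="scale")`.
- **Folds**: stratified by class and grouped by patient, so both cores
  of a validation-style patient share a fold; per-fold artifacts carry
  a digest of the fitted components, which the leakage canary compares
  after permuting held-out labels.
- A two-core agreement helper reports the fraction of patients whose
  two cores receive the same prediction; it is reported, not asserted.

A consequence worth knowing: on features carrying *no* class signal,
oversampling to parity makes the RBF-SVM's kernel density favour the
duplicated minority class, so accuracy lands at or *below* the modal
baseline rather than exactly at it. The meaningful property — and the
one asserted — is that uninformative sources show no improvement over
baseline while the raw-channel source far exceeds it when the planted
signal is purely spatial.

## Synthetic cohorts

The generator emulates the *statistical structure* the analyses assume:
typed point patterns (uniform baseline; Gaussian niches around
rejection-separated centres, membership probability = niche weight;
pairwise attraction/repulsion by 30 bounded displacement steps of
|strength| px toward/away from the nearest heterotypic neighbour,
followed by collision relaxation), disc-shaped cells (radius 3 px,
minimum separation 4 px, truncated at collisions, every cell keeps ≥1
pixel), channels as on-target mean 10 / off-target mean 0.5 counts
under multiplicative log-normal noise σ = 0.3, and outcomes linked to
z-scored realized features (logistic progression; exponential
proportional-hazards survival, baseline scale 60 months; independent
exponential censoring calibrated to the requested rate). Default
density 40 cells / 10⁴ px² matches ~4,000 cells per 1-mm² core; default
cohort size 120 patients mirrors a validation-scale cohort. Histology
frequencies follow a 416-patient LUAD distribution
(lepidic 40 : papillary 33 : acinar 190 : micropapillary 35 :
solid 118).

It does **not** emulate: isotope spillover or channel crosstalk,
irregular cell morphology, intensity gradients across the core,
segmentation errors (ground-truth label maps stand in for the external
segmenter), spatially varying tissue composition beyond the planted
niches, or covariate-outcome confounding. Passing tests therefore show
that the *algorithms* recover planted structure under realistic noise —
not that a particular biological cohort would yield a particular
result.

## Problem sizes

The reference experiments run at desk scale, chosen so each completes
in seconds to a couple of minutes on one CPU: ~520-cell cores for
phenotyping; 100 random ≤64×64 rasters for the mask oracles; 30 cores ×
100 cells × 1,000 permutations for calibration and 50 density-60 cores
for planted-effect recovery; four 320² cores for CN recovery; 200
replicate 200-patient cohorts (power) and 500 replicate 100-patient
cohorts (null uniformity) for survival; a 120-core spatial-signal
cohort (90/30 split) for prediction. Prediction-cohort cell frequencies
come from the ground-truth tables; at these conditions phenotyping is
>99% accurate, so phenotyped frequencies are statistically
indistinguishable from them.

## Known limitations

- The real-data TIFF reader is best-effort: deposited cohort layouts
  vary, and only multipage-in-panel-order and one-file-per-marker
  directories are recognized.
- The exact quantization is optimal for the binned distribution; at
  more than 2,048 distinct values it is exact only up to quantile
  binning.
- Avoidance is statistically invisible in sparse cores (expected
  co-adjacency near zero); detecting planted repulsion needs contact
  densities high enough that its absence is surprising.
- The `testhash` backbone is a texture summarizer, not a learned
  feature extractor; absolute accuracies with it are not comparable to
  transfer-learning results on real cohorts, only the *relative*
  ordering of feature sources is.
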