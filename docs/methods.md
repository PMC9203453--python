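# Methods

`lesioncast` estimates, region by region, whether a stroke patient has a
lesion in each region of a brain parcellation, using only non-imaging
clinical data (cognitive/motor test scores, mood scales, blood values,
demographics, medication). This note documents the models, the conventions
behind every numerical choice, and what the synthetic cohorts do and do not
establish.

## Lesion characterization

A subject's lesion profile is the vector of **lesion degrees**
D_r ∈ [0, 100] — the percentage of lesioned voxels in region r. Presence is
binarized strictly as D_r > 0.

* **Occurrence** = (number of regions with D_r > 0) / (number of regions).
* **Sparsity** = the mean of the normalized inter-region distances W_{mn}
  over all unordered pairs {m, n} with D_m > 0 AND D_n > 0. Pairs failing
  the AND contribute nothing (they are excluded, not zeroed): intact tissue
  must not move the statistic. Subjects with fewer than two lesioned
  regions have no valid pair; their sparsity is defined as 0, which places
  single-lesion subjects in the low-sparsity corner of the plane.

W is built from Euclidean centroid-to-centroid distances, min-max
normalized over the off-diagonal upper triangle so the closest region pair
maps to 0 and the farthest to 1. Centroid distance is a desk-scale proxy
for averaged voxel-to-voxel distances; the ordering agrees for compact
regions, and users with a label volume can extract degrees per voxel via
`extract_region_degrees`. A two-region atlas is degenerate under min-max
normalization (its one pair maps to 0, with a warning); fully coincident
centroids raise an error.

Per-region dispersion across subjects is the coefficient of variation,
sample SD (ddof = 1) over mean, with an all-zero region reported as CV 0
(no lesion found).

## Atlas and hierarchy

The bundled registry (`data/aal116_synthetic_registry.csv`) is a
**synthetic stand-in**: the standard 116 AAL region names with approximate,
hand-assigned centroid coordinates and a constructed Talairach-style
hierarchy — 18 lobes (frontal/temporal/parietal/occipital/limbic/sub-lobar
per hemisphere, anterior/posterior cerebellum per side, anterior/posterior
vermis) under 5 hemispheric divisions (left/right cerebrum, left/right
cerebellum, midline). It is a plain CSV so a real registry can be dropped
in. The hierarchy is validated to be total and consistent (a lobe never
straddles two divisions), so rolling up AAL → lobes → hemispheres equals
rolling up AAL → hemispheres directly.

## Subject categorization and subset prediction

Subjects are clustered by k-means (k = 3, 10 restarts, seeded) on the raw
(occurrence, sparsity) plane — both coordinates already live in [0, 1], so
no standardization is applied. Because k-means labels are arbitrary,
clusters are relabeled canonically by ascending centroid occurrence, making
"subset 1/2/3" stable across runs.

The subset classifier predicts this label from clinical features alone:

1. drop features missing in > 20% of subjects (threshold configurable),
   median-impute the rest (medians stored for new subjects);
2. keep features with a Kruskal–Wallis subset effect at p < 0.05;
3. z-score and project onto the minimal leading principal components
   reaching ≥ 95% cumulative explained variance (z-scoring because the
   features span incommensurate scales);
4. tune a random forest over a small grid (trees {100, 300}, depth
   {None, 5, 10}, features-per-split {sqrt, all} by default) on repeated
   stratified 75/25 resamples, each training side scored by threefold
   stratified CV; the candidate with the highest mean multiclass MCC wins,
   ties broken by mean correct rate; the winner is refit on all data.

The multiclass MCC is the generalized (covariance-form) coefficient
computed from the k×k confusion matrix, with value 0 when a marginal is
degenerate. It is implemented in-package and cross-checked against
scikit-learn's `matthews_corrcoef` in the tests.

## Per-region lesion models

For each region the binarized presence y is modelled as
P(y = 1 | x) = 1/(1 + exp(−(a·x + b))), predicted presence iff P ≥ 0.5
(the boundary counts as presence — screening use prioritizes sensitivity).
Three variants:

* **none** — unpenalized maximum likelihood on features pre-selected by a
  Kendall τ-b screen (p < 0.05 against y; constant features, whose τ is
  undefined, are excluded). τ-b and its p-value come from scipy
  (exact-vs-asymptotic policy per scipy's defaults); the statistic is
  verified against an O(n²) pair-counting oracle in the tests. Under
  perfect separation the coefficients are deterministically capped at
  |a| ≤ 20 and flagged rather than left to diverge.
* **l1 / l2** — LASSO / Ridge on min-max normalized features (train
  min/max stored; transformed held-out values may fall outside [0, 1] and
  are passed through unclipped so the predictor stays affine in the raw
  feature). The penalty weight λ runs over 20 log-spaced values in
  [1e−4, 1e2] (glmnet-style; the sklearn C is 1/(nλ)). Constant features
  are excluded from penalized fits.

**Nested cross-validation and resampling.** With at least 4 presence (and
absence) subjects, fold assignment is a stratified 4-fold outer split
re-randomized over 100 resampling repetitions. Each outer training fold
contributes one candidate model (4 × 100 = 400 candidates): its inner
3-fold loop either (none) screens features on each inner-training part,
fits, and keeps the feature set with the highest inner-validation
sensitivity, refit on the whole outer-training fold; or (l1/l2) picks the
λ with the best mean inner-validation log-likelihood (sensitivity drives
the unregularized search, where candidates differ in feature sets; for
penalized tuning the likelihood is the standard criterion and is smoother
in λ). Below the presence floor the CV
machinery is skipped and a single all-data model is produced; the same
path is taken when the *absence* count is below the floor, since
stratified 4-fold CV is then infeasible.

**Selection.** Every candidate carries AIC = 2k − 2 ln L computed on its
outer-training fit, where ln L is always the unpenalized Bernoulli
log-likelihood and k counts the intercept plus slopes (penalized: nonzero
slopes only — a documented convention, since AIC for penalized fits has no
canonical definition). The selected model is the AIC minimum; ties go to
fewer parameters, then to higher validation sensitivity. Regions with no
presence (or no absence) across subjects are recorded as unmodellable.

## Resolution transfer

*Modified estimation*: a lobe (or hemisphere) is predicted lesioned iff any
constituent fine region is — pure OR logic, which can add but never lose a
fine-level detection. True coarse occurrence is derived the same way from
binarized fine truth (not by re-thresholding summed degrees). *Direct
estimation* runs the full per-region pipeline on that coarse truth. The
two routes are compared by the rank-sum test on their region-wise
sensitivities.

## Evaluation statistics

Accuracy, specificity and sensitivity come from per-region confusion
counts; a ratio with a zero denominator is reported as missing and
excluded from medians (coding it 0 would bias region-wise summaries).
Association between truth and prediction uses the two-sided Fisher exact
test (zero margin ⇒ p = 1). Cross-method comparisons use Kruskal–Wallis
(tie-corrected; identical data ⇒ H = 0, p = 1) with a Tukey–Kramer post
hoc applied to rank-transformed data — the common "multcompare after KW"
convention, not an exact joint procedure. The rank-sum z uses the normal
approximation with tie correction and no continuity correction. Spearman ρ
(tie-aware) correlates region-wise CVs between true and predicted subsets;
constant inputs are reported missing.

## Synthetic cohorts

The generator plants the structure each stage is meant to recover:

* **Subsets**: 67/86/42 subjects with 1–3 / 5–12 / 16–26 lesioned regions
  on the 116-region atlas (subset 1 includes a 23/67 fraction of
  single-lesion subjects). Lesion sets grow from a random seed region by
  nearest-to-set expansion with an exponential distance kernel (length
  scales 0.04 / 0.10 / uniform), and are re-drawn until the achieved
  sparsity lands in per-subset bands (≤ 0.12 / 0.18–0.34 / 0.42–0.58).
  The bands are part of the design: kernel strength alone controls
  sparsity too loosely to produce three distinguishable strata on the
  plane, and the planted subsets are meant to be exactly the kind of
  k-means-separable clouds the categorization stage assumes.
* **Degrees**: Beta(0.8, 5) × 100 conditional on presence (right-skewed,
  most lesioned regions mildly involved), floored at 0.01% so presence is
  well-defined.
* **Features**: 241 candidate variables named after clinical-test families
  (BIT, CAT, MMSE, …) for realistic I/O. One feature per region (by
  default) is shifted by ±2 SD in subjects where that region is lesioned —
  an additive-shift signal, which induces the logistic relation the models
  assume; the rest are exchangeable noise. Missingness is injected
  completely at random at 5%. The planted map (feature → region, signed
  effect) is exported for recovery scoring.

What the synthetic cohorts do **not** emulate: correlated clinical
batteries (real test scores are strongly inter-correlated), informative
missingness, measurement floors/ceilings, lesion degrees correlated across
adjacent regions, and any true anatomy in the centroids. Passing recovery
tests therefore demonstrates correctness of the machinery — not expected
performance on real patients.

## Problem sizes and reproducibility

Everything is driven by explicit seeds; the same config + seed reproduces
a byte-identical report (floats are rounded to 10 decimals before
serialization). Defaults are the full procedure (4 × 3 nested CV,
100 resamples, 100 classifier resamples). The test suite and the
acceptance script scale the *repeat* counts down (region-model resamples
3, classifier resamples 10 in the acceptance run; smaller still in unit
tests) — a problem-size choice that leaves the per-candidate machinery
untouched, while the candidate-count checks exercise the full 4 × 100
scheme on a single region. Region-wise performance in the reports is
in-sample (the selected model applied to the cohort it was selected for),
matching how the selected models are meant to be audited; held-out
sensitivity per candidate is recorded in each model's provenance.

## Known limitations

* Continuous lesion degree is not estimated — only presence/absence.
* The bundled registry's centroids are approximate; sparsity values on it
  are internally consistent but not anatomically exact.
* AIC for penalized fits uses a convention (see above), so AIC values are
  comparable within a method, not across methods.
* The Tukey–Kramer-on-ranks post hoc is a practical convention; its error
  control under heavy ties is approximate.
* With strongly imbalanced regions the unpenalized fit can separate
  perfectly; capped coefficients keep predictions deterministic but the
  reported AIC of such fits is optimistic.
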