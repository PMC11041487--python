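# Methods

This note documents the models, conventions and design choices behind
`painmap`: what each stage computes, the parameters that matter, what
the synthetic cohort does and does not emulate, and the numerical
corner cases.

## Coordinate and data model

CT volumes are 3-D Hounsfield-unit grids indexed `(z, y, x)` =
(slice, row, column) with per-axis spacing and an axis-aligned world
frame whose origin is the world position of voxel `(0, 0, 0)`. This is
a deliberate simplification of DICOM geometry: no direction cosines,
no gantry tilt. DICOM series are read through the rescale
slope/intercept so pixel data become HU; NRRD volumes round-trip values
and spacing exactly. Center-point tables use `x_mm, y_mm, z_mm`
columns where `x` is the column axis.

## Pain NLP

A note is split into sentences on `.?!;` and newlines and scanned in
full. Mentions of *pain* are scored:

* numeric patterns (`N/10`, `N out of 10`) → the number, clipped to
  [0, 10]; numeric scores take precedence over verbal wording in the
  same sentence;
* a verbal grade within three tokens before the mention — the 4-grade
  scale maps no → 0, mild → 2, moderate → 5, severe → 8;
* a bare, ungraded "pain" defaults to 5.

Only the *sign* of the note-level average matters for the binary label,
so the positive grade values are a convention; the map is configurable
on `PainLexicon`. Context rules: negation, hypothetical triggers are
matched before the mention within its sentence; conditional and
historical triggers anywhere in the sentence; a history section header
(e.g. "Past medical history:") marks following sentences historical
until the next header. Hypothetical/conditional/historical mentions
are dropped; negated mentions are *retained at severity 0*, because a
documented denial is evidence of "no pain", not missing documentation.
A note with no retained mention raises "pain not documented" and is
excluded rather than labeled. API is the arithmetic mean of retained
severities; VDP = pain iff API > 0.

Limitations: the rule system is designed to be complete over the
synthetic note templates; real clinical text (typos, rare phrasings,
cross-sentence scope, site-specific pain) will break the 100% agreement
that holds on the synthetic corpus.

## ROI construction

A voxel belongs to a sphere iff its **center's world distance** to the
lesion center is at most the radius — distances in mm, so anisotropic
spacing is respected. Spheres that extend past the grid are clipped
with a warning (edge vertebrae would otherwise lose their 50 mm ROI).
The voxelized volume converges to (4/3)πr³ as spacing shrinks and is
within 2% at 1 mm isotropic spacing for the 50 mm sphere.

Fat/air removal: the HU grid is Gaussian-smoothed (σ = 1 mm by
default, configurable) and voxels whose *smoothed* value falls below
`hu_min = 0` are dropped from the mask; the raw HU values are never
modified, so downstream features see original intensities. One
smoothed field is shared across the nested diameters, which preserves
nesting under thresholding. An ROI emptied by the threshold raises a
dedicated error and the lesion is skipped with a log entry.

## Radiomics features (107 per ROI)

Gray levels: fixed bin width (default 25 HU), re-anchored at the ROI
minimum — `level = floor((x − min)/w) + 1` — so an additive HU shift
leaves all discretized-texture features unchanged. No voxel resampling
is performed before extraction (off by default, not implemented as a
resampling step).

* **First-order (18)** on raw HU; Entropy and Uniformity use the
  discretized histogram. Kurtosis is not excess-corrected. On a
  constant ROI, Skewness/Kurtosis are defined as 0 and flagged.
* **Shape (14)** on the *geometric* (pre-threshold) sphere by default —
  so "shape" describes ROI geometry, not tissue composition; a switch
  selects the thresholded mask. Surface area and mesh volume come from
  a marching-cubes mesh of the mask indicator smoothed with a one-voxel
  Gaussian (level 0.5): meshing the raw binary grid produces staircase
  facets that overestimate surface area by ~10% and would bias
  sphericity low. Axis lengths are 4·√eigenvalue of the voxel-center
  coordinate covariance; maximum 3-D/2-D diameters are maximal pairwise
  distances over boundary voxel centers (convex-hull accelerated).
* **GLCM (24)** — 13 unique offsets at Chebyshev distance 1, symmetric,
  normalized per offset; features computed per direction and averaged;
  pairs require both voxels in-mask. Degenerate single-level ROIs:
  Correlation and MCC are defined as 1, entropies 0, all flagged.
* **GLRLM (16)** — run lengths along the same 13 directions, averaged.
* **GLSZM (16)** — 26-connected zones, one matrix.
* **GLDM (14)** — dependence = 1 + number of 26-neighbors whose level
  differs by ≤ α (default 0).
* **NGTDM (5)** — neighborhood mean over in-mask 26-neighbors; voxels
  with no in-mask neighbor contribute to `n_i` with zero difference;
  Coarseness is capped at 1e6 when its denominator vanishes.

Every family equals an independent brute-force (loop-based) matrix
construction within 1e-9 relative error on randomized small ROIs; that
equivalence is part of the test suite. Ensemble vectors prefix each
feature with its sphere (`SP10_glcm_Contrast`), giving 321 (EN3) /
642 (EN6) columns.

## Modeling chain

Labels: one note-level VDP label propagates to every lesion of the
paired image (the dataset container enforces this invariant). The
70/30 split is stratified by label at the image level; by default all
images of a patient land on the same side (`allow_patient_overlap`
relaxes this). Covariate balance between splits is checked with
Welch's two-sample t test (numeric) and a chi-square test without
continuity correction (categorical); degenerate tables are flagged.

Scaling is z-score with train-only statistics (zero-variance features
map to 0, flagged). SMOTE oversamples the minority class to the
majority count: synthetic points are `x_i + u·(x_nn − x_i)`, `u∼U(0,1)`,
`x_nn` among the k = 5 minority nearest neighbors; the majority class
and the test set are untouched (the function only ever receives the
training split). LASSO selection fits an L1-penalized linear model
with the penalty chosen by internal CV on the training data; if the
chosen penalty zeroes everything, the smallest penalty with a nonzero
coefficient is used, flagged. Classifiers: random forest (300 trees),
Gaussian-process regression on the 0/1 labels (RBF + white noise,
scored continuously, thresholded at 0.5), linear SVM (decision
function, threshold 0), and an MLP (one hidden layer of 64). Exact
hyperparameters are open choices documented in `PipelineConfig`; all
seeds are fixed. 5-fold CV refits scaler, SMOTE and LASSO *inside
each fold* to avoid selection leakage.

Metrics: because the cohort is ~84% painful, the panel takes the
minority "no pain" class as positive — sensitivity is recall of
"no pain", specificity recall of "pain" — and additionally reports
macro-averaged precision and F1 over both classes. AUC is the
trapezoid over the empirical ROC of the continuous score; a
single-class test set makes AUC undefined and is refused.

## Synthetic cohort: what it emulates, what it does not

The phantom is a statistics-level stand-in for a thoracic-spine
simulation CT: a bone cylinder (300 HU) in a negative-HU fat/air shell
(−100 HU) with additive Gaussian noise (SD 35 HU), so the HU > 0
threshold is exercised nontrivially. Lesions are spheres planted
inside the bone cylinder: lytic −150 HU, blastic +200 HU, mixed a
spatially smoothed mixture; class frequencies ≈ 50/31/19%. Painful
lesions carry the planted signal: +20 HU inside the lesion, +30 HU in
a shell out to 22 mm radius, plus correlated texture noise
(correlation length 4 mm, SD 25 HU) over lesion + shell. Placing part
of the signal beyond the 7.5 mm reach of SP15 reflects the premise
that peri-lesional tissue carries pain information, and is what makes
the EN6 ensemble outperform EN3 on this cohort.

Cohort defaults mirror the study conditions: ~3.3 lesions per image
(1 + Poisson(2.3)), an 84% painful-lesion fraction achieved by marking
whole images painful until the lesion-level target is met (all lesions
of an image share the note's pain status), ages ≈ N(66, 14), 54% male,
and a realistic primary-site mix. Volumes default to 48×56×56 voxels
at 2.5×2×2 mm — coarse enough that a full ~200-lesion cohort extracts
in about a minute, fine enough that SP7 still spans several voxels.
The lesion-size range (8–16 mm) is a configurable default; no
lesion-size distribution is implied by the study.

Passing tests on this cohort therefore demonstrate *pipeline
correctness and sensitivity to a known planted effect*, not clinical
performance: the phantom has no anatomy, no scanner/reconstruction
physics, and its painful signal is an idealized construction.

## Numerical and degenerate-case policy

Degenerate inputs (constant ROI, single voxel, empty percentile band)
produce defined, finite sentinel values plus a flag on the feature
vector rather than NaNs or dropped lesions — the feature matrix stays
rectangular. Determinism: every stochastic component takes an explicit
seed; reruns of the orchestrated pipeline reproduce byte-identical
artifacts for the deterministic stages (checksummed in the run
manifest). In the end-to-end recovery test the label-shuffled null
AUC is summarized as the mean over 32 image-level shuffles, because a
single shuffle's test AUC is dominated by the handful of painless test
images (per-shuffle SD ≈ 0.1); the mean's standard error (~0.02) makes
the chance-band check meaningful.

## Known limitations

* The NLP stage is a lexicon/rule system, complete only over note
  styles resembling its templates; no UMLS mapping, no learned models.
* Sphere membership uses voxel-center inclusion; at coarse spacing the
  smallest sphere (SP7) may contain only a handful of voxels.
* Shape features on the geometric sphere are nearly constant across
  lesions by construction; they become informative only with the
  thresholded-mask option.
* GPR is used as a regressor on binary labels, scored continuously; it
  is not a calibrated probabilistic classifier.
* No wavelet/LoG filtered-image features, no 2-D aggregation, no
  scanner harmonization.
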