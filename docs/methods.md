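# Methods

`deformark` implements a deformation-based morphometry pipeline for
cohorts of single-slice 2D grayscale images: find where, on a common
reference anatomy, the local deformation needed to map each subject
onto the reference discriminates two diagnostic classes, and describe
what the classes do differently there. This note documents the model,
the parameter choices, the synthetic study conditions, and the known
limitations.

## Pipeline model

**Reference selection.** Each control subject carries seven ordered
anatomical landmarks; configurations are centered on landmark 1
(translation removal only — the later rigid stage also centers there)
and flattened to 14-vectors. PCA is run on the configuration matrix
and the reference is the *medoid*: the subject with the smallest score
norm over the leading components explaining ≥ 95 % of the variance.
The criterion behind "the most representative subject" is genuinely
open; nearest-to-mean in PC space is the natural reading and is
asserted by an exhaustive-comparison test. A pairwise Procrustes mode
(rotation + scale removal, alignment to the first subject) exists
behind a flag but is off by default.

**Rigid alignment.** The query is translated so its landmark 1 meets
the reference's landmark 1, then rotated about that point by the
least-squares rotation aligning the remaining six landmark pairs
(orthogonal Procrustes restricted to a proper rotation; degenerate
configurations fall back to translation only, flagged). Resampling is
bilinear with edge clamping.

**Demons registration.** Classic intensity-driven demons: per
iteration, with fixed image f, moving image m and accumulated field d,

    u(x) = e(x) ∇f(x) / (|∇f(x)|² + e(x)²),   e(x) = m(x + d(x)) − f(x),

subtracted from d, which is then Gaussian-smoothed (σ = 1.5 px) — an
elastic-like regularization. A 3-level coarse-to-fine pyramid
(downsampling ×4, ×2, ×1) provides capture range; each level runs at
most 100 iterations and stops early when the relative SSD improvement
over 5 iterations falls below 1e-4. The field uses the pull
convention `warped(x) = moving(x + d(x))` on the reference grid. The
returned field is the best-SSD state encountered, so registration can
never worsen the initial SSD. Both images are min-max normalized
first, discarding global affine intensity differences. A symmetric
force variant (averaging fixed and warped-moving gradients) was
evaluated during development and did not measurably change recovery on
the synthetic cohorts, so the simpler classic force is kept.

**Searchlight screening.** Per subject, the scalar field |d| (the
deformation magnitude in pixels) is the feature source. For every
valid seed pixel, the 9 × 9 locale (81 features) across the *training*
subjects feeds a linear-kernel SVM with unit cost, evaluated by
stratified 8-fold cross-validation: per fold, features are
standardized by fold-train statistics only, the SVM is fitted, and the
held-out decision values are scored by AUC (computed exactly as the
Mann–Whitney pair statistic, ties = ½). The per-seed mean validation
AUC forms the map; the reserved ~20 % test subjects are untouched
until the final combination stage. The fold partition is drawn once
per run so all seeds are scored under the same partition. For speed
the SVM is solved by calling libsvm's C-SVC directly (the solver
behind `sklearn.svm.SVC`); a test asserts exact agreement with
`SVC.decision_function`.

**Region refinement.** The map is thresholded at AUC > 0.62
(deliberately low, so small strong regions flanked by weak pixels
survive) into 8-connected components. Each is (1) dilated by whole
one-pixel rings while the region's cross-validated AUC keeps improving
(plateau: < 1e-3 improvement for 2 consecutive dilations, or any
decrease; rollback to the best state; at most 25 dilations), then
(2) swept pixel-by-pixel: every exterior neighbor is tested for
inclusion and every boundary pixel for exclusion, in raster order,
accepting only strict AUC improvements, for at most 10 passes.
Touching regions are merged and re-scored once. The search is greedy
and finds a local optimum by construction. A region's feature vector
is the per-subject magnitude at each member pixel — the locale
construction generalized to arbitrary pixel sets. At most
`max_regions` (default 10) best-scoring components enter refinement:
a signal-free map can produce hundreds of chance components, and the
exhaustive combination stage is exponential in the region count.

**Combination and evaluation.** All 2ⁿ − 1 nonempty subsets of the
refined regions are scored by cross-validated training AUC of the
union of their pixels (ties: smaller subset, then lexicographic). The
winner is refit once on the full training set and scored once on the
reserved test subjects: ROC curve, test AUC, and the operating point
maximizing Youden's J = sensitivity + specificity − 1 (ties resolve
toward higher sensitivity). The frozen model (standardization
statistics + linear weights) is serialized so an external registered
cohort can be scored later (`crosscheck`), reporting the fraction
classified negative.

**Morphology.** For a final region set, each subject contributes its
(drow, dcol) displacements over the region pixels in a fixed order.
Pooled (both-class) PCA of the mean-centered vectors summarizes how
concentrated deformation variability is. Per region, at the member
pixel nearest the region centroid, each class gets its mean
displacement and its principal direction — the first singular vector
of the *uncentered* class displacements, sign-aligned with the class
mean. Uncentered PCA is deliberate: the dominant direction should
carry the class's systematic displacement, not only its spread (a
cloud {(1, ε), (1, −ε)} must yield (1, 0)). Angles are measured in
image coordinates (row increases downward).

## Synthetic study conditions

No real cohort ships with the package; the generator fabricates one
with known ground truth so every stage is testable for recovery.

* **Phantom:** 128 × 128, 12 Gaussian blobs of varying size and
  contrast, plus a smooth deterministic intensity texture (seeded
  smoothed noise, RMS 0.15 after blob normalization). The texture
  matters: soft tissue carries intensity structure nearly everywhere,
  and a deformation of a perfectly flat area is invisible to any
  intensity-driven registration — without texture, the effect's
  smoothing halo becomes spuriously class-discriminative across the
  whole frame. Seven landmarks sit at blob centers far (≈ 28 px) from
  the effect loci; a landmark inside an effect disc would let the
  rigid stage absorb class signal, the synthetic analogue of why real
  protocols annotate stable, pathology-free structures.
* **Nuisance deformation:** per subject, smoothed white noise
  (Gaussian σ = 8 px) rescaled to exactly 1 px RMS magnitude — the
  anatomy-wide individual variability both classes share.
* **Effects:** Gaussian-envelope displacements (σ = 5 px) at one or
  two blob-flank loci. Default two-locus conditions: disease subjects
  displaced 3 px and controls 2 px in directly opposing directions
  (180° implanted separation), directions aligned with the local
  intensity gradient. Three identifiability constraints shaped these
  defaults: the magnitude asymmetry (3 vs 2 px) carries the
  class-discriminative signal the screening stage detects; both
  amplitudes sit well above the background (an effect under ~2× the
  per-axis background SD leaves its uncentered principal direction
  statistically unidentifiable at n = 30); and a displacement
  orthogonal to the local gradient is unrecoverable in principle (the
  aperture problem). The single-locus conditions used for locus
  recovery are disease 3 px vs control 0.
* **Cohort:** 30 controls + 30 disease subjects; subject images are
  the reference backward-warped by −d_true (so features move by
  +d_true and registration should recover ≈ +d_true) plus Gaussian
  intensity noise (SD 0.02), clipped to [0, 1]. The first control is
  rendered undeformed and plays the clean reference individual: the
  landmark-PCA stage selects it, so recovered fields are each
  subject's own deformation rather than deformation relative to a
  deformed peer. Landmarks are transported by the exact true field
  (first-order transport; optional jitter available).
* **Null variant:** disease effects set equal to control effects —
  no class signal; used for calibration checks.
* **Seeds:** the cohort seed drives a `SeedSequence` spawned per
  subject; 1234 (generation/split) and 1235 (folds) are the fixed
  study seeds. Identical specs reproduce every output byte for byte.

What the generator does *not* emulate: acquisition physics (contrast,
bias fields, artifacts), anatomically realistic shapes, partial-volume
effects, annotation error in landmarks (unless enabled), or
multi-factor pathology. Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration under controlled
conditions, not clinical performance.

## Numerical and design choices

* AUC is the exact Mann–Whitney statistic via average ranks; a
  brute-force pairwise oracle confirms agreement to 1e-12.
* Train/test split: per-class round-half-up of 0.8 × class size;
  folds: stratified, shuffled under a fixed seed.
* Degenerate inputs: all-identical features score AUC 0.5; folds with
  a single-class validation set are skipped and the mean renormalized;
  a flat-gradient/zero-residual demons denominator is guarded; all-
  identical landmark configurations return the first subject flagged
  degenerate; an empty threshold result is an empty region list.
* The AUC-map maximum saturates into a plateau when an effect is
  strong (the locale extends every seed's reach by 4 px);
  `peak_location` therefore reports the centroid of the maximal pixel
  set, which is the plateau center and reduces to the argmax when the
  maximum is unique.
* Manifests contain the config echo and SHA-256 checksums of all
  numeric artifacts (NIfTI/JSON/CSV; PNG renders excluded) and are
  bit-identical across reruns; wall-clock timings live in a separate
  `timings.json`.
* Problem sizes: the shipped study conditions (128 × 128, 60
  subjects, ~14 400 screened seeds) keep a full pipeline run at a few
  minutes on one core, which is the intended scale for the package's
  tests and examples.

## Known limitations

* Registration recovery is attenuated for effects narrow relative to
  the demons regularization: the recovered class-mean amplitude on the
  default conditions ranges from ~0.75× at a high-contrast locus down
  to ~0.3× where local contrast is weak, and the surviving bias can
  push a recovered class direction 20–25° off the implanted one at the
  weaker locus. Sharper regularization did not resolve this without
  degrading noise robustness.
* Because region growth legitimately expands regions well beyond an
  effect's 2σ disc, the pooled first explained-variance ratio over the
  final regions is diluted by background variability: on the default
  two-locus conditions it reaches only ≈ 0.29 (ground-truth-field
  ceiling over the same regions ≈ 0.48). Concentration above 0.5 is
  observed only on the exact effect discs with ground-truth fields.
* The greedy refinement finds local optima; no invertibility or
  diffeomorphism guarantees are made for the demons field; everything
  is strictly 2D.
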