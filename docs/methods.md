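# Methods

This note documents the models, defaults and numerical choices behind
`dosederm`, and states precisely what the synthetic phantoms do and do not
establish.

## Geometry and dose-volume features

Grids are axis-aligned with identity orientation, indexed `[z, y, x]`;
world coordinates refer to voxel centers and volumes are
`count × voxel_volume / 1000` cc.  Oblique acquisitions are rejected at
load time — planning CTs for this treatment site are axial, and the
restriction keeps every geometric operation oracle-checkable.

Contours rasterize by the even-odd rule with voxel-center membership: a
voxel belongs to a structure iff its center falls inside an odd number of
that structure's polygons on the slice.  This matches common
treatment-planning-system behavior and admits an independent
point-in-polygon oracle.

The body mask is an HU threshold (default −300 HU) followed by the largest
26-connected component and per-slice hole filling, so lung is counted as
body interior.  The subcutaneous layer `skin5mm` is the inner Euclidean
margin of the body surface computed with anisotropic spacing via a
distance transform — not slice-wise 2-D erosion, which would be distorted
by 2.5 mm slices.  The dose-guided ROI is
`skin5mm ∧ (dose ≥ 0.10 × prescription)`, i.e. the skin actually receiving
≥ 5 Gy at the 50 Gy prescription.  All dose thresholds are inclusive;
ties at a threshold count as inside.  Dose is resampled to the CT grid by
trilinear interpolation (exact on affine fields), with 0 Gy outside the
dose extent.  `PTV100%`/`PTV105%` are the PTV sub-volumes receiving
≥ 100%/105% of prescription.

## Handcrafted features (105)

Shape (14), first-order (18) and five texture families (GLCM 22, GLRLM 16,
GLSZM 16, GLDM 14, NGTDM 5) follow the IBSI-style formulas.  Choices left
open by feature counts alone:

* **Discretization**: fixed bin width, default 25 HU, relative to the ROI
  minimum.  Consequence: all texture features are invariant to adding a
  constant to the image.
* **Aggregation**: GLCM and GLRLM are built in 3-D per direction over the
  13 unique distance-1 offsets and feature values averaged over
  directions; GLSZM/GLDM/NGTDM use 26-connected neighborhoods and are
  direction-free.  Direction-averaged features are invariant to 90°
  rotations about z (property-tested).
* **GLCM roster**: the standard 24-feature set minus the two commonly
  disabled redundant members (sum average ≡ 2 × joint average,
  dissimilarity ≡ difference average), giving the 22 that make
  14 + 18 + 73 = 105.  The exact names are frozen in
  `hcr.feature_manifest()`.
* **Degenerate inputs**: zero-variance denominators (constant ROI, one
  gray level) return 0 rather than NaN; ROIs under 8 voxels are rejected,
  mirroring the cohort's "insufficient skin ROI volume" exclusion.
* Shape diameters use voxel-center coordinates (convex hull accelerated);
  mesh volume and surface come from marching cubes on the padded mask.

## Deep features (4224)

The extractor is the 13-convolution stack of the 16-layer VGG topology
(3×3 kernels, stride 1, padding 1, ReLU, 2×2 max-pool after layers 2, 4,
7, 10, 13), with global average pooling applied to every post-activation
map; the pooled blocks concatenate to 64+64+128+128+3×256+6×512 = 4224
features per slice, averaged over eligible slices per patient.  Weights
are always frozen.

* `weights_mode="seeded-random"` (He-normal from a seed) is the default:
  it exercises and verifies the whole mechanical contract — shapes,
  masking, pooling, averaging, reproducibility — without downloads.
  Pretrained weights are a pluggable input (`set_weights`); whether they
  yield *better* features is a scientific claim about transfer learning,
  not a mechanical contract this package can test offline.
* Input preparation: HU clipped to [−1000, 1000], scaled to [0, 1],
  masked designs zero-fill outside their ROI, single channel replicated to
  3.  Channel normalization is identity (mean 0, std 1) in seeded-random
  mode so the masked background stays exactly 0 and contributes nothing
  through the ReLU stack; this also makes masked-design features exactly
  invariant to off-ROI image content (tested bit-exactly).
* Slice eligibility: masked designs need ≥ 16 ROI pixels on the slice;
  the unmasked design uses slices within the body's axial extent.
  Patients with no eligible slice raise a flagged error.
* The source description's 14-number channel list is read as a
  typographical duplication; 13 layers summing to 4224 are authoritative.
* The extractor implements its exact backward pass (GAP, ReLU, max-pool
  routing, transposed convolution), which Grad-CAM uses; gradients are
  validated against the analytic one-hot case and finite differences.

## Synthetic cohort — the stated world

Defaults are the reference cohort's stated conditions: n = 148, 33.1%
prevalence, 50 Gy prescription, covariate marginals from the published
clinical table (laterality P(left) = 0.473, breast-conserving surgery
0.804, supraclavicular irradiation 0.257, internal-mammary irradiation
0.223, chemotherapy 0.50, the five-level AJCC multinomial), age mean 56,
BMI mean 24.73.  Spreads the tables do not print (age SD 9, BMI SD 3.6)
are fixed once at values typical for such cohorts.

Phantoms are elliptical cylinders with a breast-like bulge on the treated
side, lung ellipsoids at ≈ −750 HU, soft tissue at 40 HU plus a stationary
Gaussian random field (spectral synthesis) whose correlation length is the
patient's latent `texture_scale` (lognormal around 6 mm) — a scalar latent
that texture features can detect.  Dose is
`prescription × hotspot × σ(−(d − d₀)/τ)` over the signed distance `d` to
the PTV surface, with per-patient `τ ∈ [3, 8] mm`, `d₀ ∈ [6, 16] mm`,
`hotspot ∈ [1.0, 1.08]`; dose is therefore non-negative and bounded by
1.15 × prescription everywhere.

Labels are generated from covariates, not pixels:
`P(RD) = σ(β₀ + 0.5·z(age) + 0.8·IMN + 1.0·z(V25Gy) + 0.5·z(texture))`,
with V25Gy computed through the real geometry stack and β₀ calibrated by
bisection (tolerance 0.005 on the mean risk).  The default effect sizes
encode the reference study's significant risk factors (age, IMN
irradiation, mid-dose skin volume) at magnitudes that make recovery
testable at n = 148.  `sample_population` is a covariate-level fast path
drawing DVH values from the published mean ± SD summaries (one latent
exposure factor correlates the V-levels) with the identical label link —
used for large-n statistical checks.

**What a green test establishes**: that the pipeline recovers a known
generative signal, keeps folds leak-free, and is deterministic.  **What it
does not**: phantom volumes are desk-scale (skin V-volumes an order of
magnitude below the clinical tables), there is no beam model, no CT
artifacts, no anatomical variability, and no claim that clinical AUCs
(0.76 for the best multimodal combination in the reference study) are
reproduced — the patient cohort is access-restricted, so patient-level
headline numbers are out of reach by construction.

## Selection, modeling, evaluation

* "One-way ANOVA" with a binary outcome is the two-group F test (the
  square of the pooled-t statistic; verified as an identity).
  Zero-variance features get p = 1.  Retained set at α = 0.01 is a subset
  of the α = 0.05 set (monotonicity property).
* Boruta: per iteration every retained column is independently permuted
  into shadow features, a depth-unlimited random forest (200 trees by
  default, seeded) is fit on [real | shadow], importance is mean |TreeSHAP
  value| (own numba implementation, validated against brute-force Shapley
  enumeration on small trees), and a feature scores a hit when it beats
  the best shadow.  Decisions use a two-sided Binomial(n_iter, ½) test at
  α = 0.05; *tentative* counts as rejected at the modeling boundary so
  feature sets are reproducible.  Clinical and DVH blocks pass through the
  same two stages by default (toggleable to pass-through), matching the
  reading that only age survived selection in the reference study.
  LASSO appears only in the source's figure-abbreviation list, not in the
  described procedure, and is excluded.
* SMOTE–ENN: SMOTE interpolates minority points toward one of their
  k = 5 nearest minority neighbors until class counts are equal, then ENN
  (k = 3) removes any sample whose neighbors vote against its label; if
  cleaning would empty a class it is skipped for that fold.  Rebalancing
  runs strictly inside training folds — inner-search validation rows and
  outer test rows are never resampled.
* Stacking: base learners LR / RF / GBDT; the logistic meta-learner trains
  on out-of-sample base probabilities via internal stratified CV (classic
  leak-safe stacking; the source describes the layers but not the meta
  protocol).  One-hot encodings keep all levels; regularization absorbs
  the collinearity.
* Nested CV: stratified 5×5; the randomized search (30 draws by default)
  scores candidate configurations by mean inner-fold AUC (the study's
  primary metric; it names no search scoring), while the sensitivity
  tables aggregate mean F1 by n_estimators / max_depth / learning_rate as
  described.  Fold plans, searches and resampling all derive from one
  seed; a full run is bit-reproducible, and selection reports carry their
  fold id so cross-fold feature reuse raises.
* Metrics follow the standard confusion-matrix formulas with PPV/NPV/F1
  defined as 0 on empty denominators; AUC is Mann–Whitney with half-credit
  ties; fold CIs use the t distribution with k−1 df; the cohort-table
  tests are Pearson chi-square without continuity correction and
  pooled-variance Student t from summaries — the two choices that
  reproduce the published p-values from the printed counts (the
  V30 row computes p ≈ 0.050 against a printed 0.049, a rounding artifact
  of unprinted precision, and is excluded from exact checks).
* Test/acceptance runs scale the search down (3 draws, 3 inner folds,
  25–80 trees) to fit a single-CPU budget; the protocol — selection inside
  folds, rebalancing inside folds, out-of-sample stacking — is identical
  at every scale.  The permutation-null criterion is read as: over 20
  seeds, the grand-mean outer AUC lies within 2 SD (of the seed-level
  means) of 0.5.

## Explainability

The stacked ensemble is not differentiable, so feature attributions use a
permutation-sampling Shapley estimator over the whole predictor whose
telescoping construction makes local additivity exact at any sample size
(linear models recover w·(x − E[background]) in closed form).  Grad-CAM
needs a differentiable scalar head: a logistic probe on (selected) GAP
features attached to the frozen extractor; channel weights are the spatial
mean of the logit gradient w.r.t. the chosen layer's activations and the
map is the ReLU-weighted activation sum normalized to [0, 1], bilinearly
upsampled.  An all-zero gradient yields an all-zero map with a degeneracy
flag.  Overlap against a reference mask is the Dice coefficient of the
map's top-quantile pixel set.

## Known limitations

* The DICOM codec covers exactly one transfer syntax (Explicit VR Little
  Endian) and the module subset this package writes; it is an exchange
  format for synthetic cohorts, not a clinical DICOM implementation.
* Shape diameters are voxel-center based, not mesh-vertex based; on
  coarse grids they can differ from mesh-based values by up to a voxel.
* The phantom dose model is geometric (distance fall-off), not a transport
  calculation; V-volume distributions match the published tables in shape
  and ordering, not absolute cc.
* Pretrained-weight extraction is supported but unexercised by the test
  suite (no weights are bundled); all deep-feature tests use seeded-random
  weights.
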