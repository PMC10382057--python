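# Methods

This note documents the models, conventions and numerical choices behind
`mammotex`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Phantom model

Each tumor is a perturbed ellipsoid embedded in a noisy background volume.
The boundary is a radius function over directions: an ellipsoid with mildly
anisotropic semi-axes (log-normal axis ratios, SD 0.12, normalized to
preserve the target mean extent) times `1 + 0.25·irregularity·P(θ,φ)`,
where `P` is a random degree-≤4 spherical-harmonic combination normalized
to max |P| = 1 and `irregularity ∈ [0,1]`. Because the radius function is
positive, the region is star-shaped and therefore connected. After
voxelization the mask is rescaled once if its measured size (mean of the
three bounding-box extents) misses the target by more than 8 %, which keeps
realized sizes within 10 % of the target.

Intensities: background level plus, inside the tumor, an elevated level
plus a Gaussian random field (white noise smoothed with a Gaussian kernel of
width `texture_granularity_mm`, renormalized in-mask to zero mean and unit
SD, scaled by a per-channel `texture_amplitude`), plus i.i.d. Gaussian
noise everywhere. Default levels (arbitrary units) make the DCE tumor
clearly hyperintense (200 vs. 100 background), as enhancing lesions are.
The Sub channel is `clip(DCE − T1, 0)` with a synthesized T1 baseline whose
tumor elevation is small (110 vs. 95), so Sub is dominated by the DCE
enhancement. T2 is synthesized on its own, coarser through-plane grid
(1×1×3 mm vs. the 1×1×2 mm reference) so the preprocessing resampler does
real work. In the infinite-granularity or zero-amplitude limit the tumor
interior degenerates to its flat level; the field normalization guards the
zero-variance case explicitly.

Cohort-level laws: tumor sizes are log-normal with μ = 3.0153, σ = 0.6125
(moment-matched to mean 24.6 mm / SD 16.6 mm; median e^μ ≈ 20.4 mm),
clipped to [3, 55] mm so every tumor fits a modest per-tumor grid (the clip
touches ~2 % of the mass). Each patient owns a second tumor with
probability 0.33 (≈ 1.33 tumors/patient, the ratio of a 429-tumor /
323-patient study population). Default positive-class prevalences — ER
0.75, PR 0.65, HER2 0.20, ILC 0.15 — are configurable population-style
values, chosen to reproduce the qualitative class imbalance of clinical
cohorts, not measured facts. Five percent of label cells are missing at
random by default; tasks drop their missing rows independently.

Class effects are additive shifts of phantom parameters applied to
label-positive tumors, scaled by a global `effect_size`; with
`effect_size = 0` cohorts are class-exchangeable by construction (verified
by a permutation test). Two canonical profiles ship with the package: an
ER-linked granularity shift (+2 mm, all channels) and an ER-linked T2-only
amplitude shift (+25), used for signal-recovery and channel-specificity
checks.

What the phantoms do **not** emulate: MR physics (bias fields, coil
profiles, k-space artifacts), DCE kinetics, anatomical background texture,
segmentation error correlated with image content, and scanner-to-scanner
batch effects. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration — not clinical-level classification
performance, which depends on biology the phantoms only caricature.

## Preprocessing conventions

Mask smoothing is binary opening followed by closing with a 3×3×3 cube, on
a padded array so border voxels are treated like interior ones; the
operation is idempotent. A mask that vanishes under the opening (isolated
voxels, ≤2-voxel-thick slabs — e.g. a 5 mm lesion at 2 mm slice spacing)
raises a degenerate-mask error; the cohort pipeline logs such tumors as
excluded. Sizes are recomputed from the smoothed mask before exclusion
rules run. The sub-5 mm exclusion is strict (`<`), the optional
size-homogeneity window inclusive. Resampling assumes co-registered
channels sharing the voxel-0 origin, with physical position `i·spacing`;
intensities are interpolated trilinearly, masks nearest-neighbor. The DCE
grid is the reference because lesions are delineated on DCE.

## Feature inventory

342 features in ten categories; the allocation is configuration
(`FeatureConfig`), and the shipped YAML manifest records the default:

| category | n | notes |
|---|---|---|
| conventional | 30 | volume, marching-cubes surface area, sphericity/compactness, bbox extents, PCA axis lengths, first-order intensity stats |
| moments | 20 | skewness/kurtosis/energy/entropy/RMS/MAD/CV + scale-invariant 3D shape moments η_pqr and rotation invariants J1–J3 |
| transforms | 24 | single-level `db1` 3D wavelet: 8 bands × (energy fraction, coefficient entropy, mean |c|) |
| descriptor | 16 | slice-wise uniform LBP (P=8, R=1) histogram + summaries, gradient-magnitude mean/SD |
| gabor | 40 | 5 frequencies × 4 orientations × (in-mask mean, SD of response magnitude) |
| frequency | 40 | 16 radial-FFT band energy fractions + 16 band log-powers + 8 spectral summaries |
| glcm | 84 | 28 co-occurrence features × distances {1, 2, 3} |
| glrlm | 44 | 11 run-length features × {merged, directional mean, SD, range} over 13 directions |
| glszm | 28 | 16 classical zone features + 12 zone/gray marginal summaries |
| ngtdm | 16 | 5 classical + tone/probability summaries |

Design choices worth flagging:

* **GLCM at three distances.** A direction-aggregated distance-1 GLCM
  yields ~25–28 standard scalar features; the category's share of the
  inventory is reached by evaluating the same 28 formulas at voxel
  distances 1, 2 and 3 — a standard multi-scale practice — rather than by
  inventing non-standard formulas. Brute-force oracle checks cover
  distances 1 and 2.
* **GLRLM directional statistics.** Run-length matrices are kept
  per-direction; features are reported for the merged matrix and as
  mean/SD/range over the 13 directions (the classical Galloway/Chu set).
  The 13-direction set is closed under 90° in-plane rotations, so the
  aggregated features are invariant to them (tested).
* **Quantization.** Equal-width binning of the in-mask range,
  `level = floor(L·(v−min)/(max−min)) + 1` capped at L; this makes all
  matrix features invariant to intensity shifts and positive rescaling.
  Constant regions map to level 1 and are flagged degenerate.
* **Averaging scope.** Only quantization-dependent (matrix) features are
  averaged over the six L values; averaging a quantization-independent
  feature over six identical copies would be a no-op, so those are computed
  once.
* **Gabor bank.** 2D kernels applied slice-wise in the axial plane (MR
  voxels are anisotropic through-plane), envelope SD capped at 4 px so
  low-frequency kernels stay smaller than typical tumor crops, kernel mean
  subtracted so a constant image gives exactly zero response,
  edge-replicated padding to avoid boundary artifacts. skimage's
  orientation convention applies (θ = 0 modulates along the column axis).
* **Degenerate limits.** Formulas return documented finite limits instead
  of NaN: GLCM correlation of a zero-variance region is 0, NGTDM busyness
  with a zero denominator is 0, NGTDM coarseness with zero weighted
  difference is capped at 10⁶, empty matrices yield all-zero features.
  Extraction asserts finiteness of all 342 outputs.
* **"Descriptor-based" features** are interpreted as local-binary-pattern
  histogram summaries plus gradient statistics; the label is generic in the
  field and this is the package's explicit reading.
* **Moments and transforms are 3D** (slice-wise only where stated).

## Selection and classification

ReliefF is the canonical multi-neighbor variant: every row is visited, k
(default 10) nearest hits and misses under Euclidean distance update the
weights by mean absolute feature differences; neighbor ties break by row
index, weight ties by inventory order; a class smaller than k+1 shrinks k
with a warning. LASSO uses squared loss on ±1 labels along 100 log-spaced
penalties from λ_max = max|Xᵀy|/n down to 10⁻³·λ_max (scikit-learn
coordinate descent, tol 10⁻⁶); the selected penalty is the largest with
more than 100 active features. Note the active set of a LASSO solution
cannot exceed the row count, so on cohorts with ≤100 train+validation rows
the target is unreachable and the selector falls back to all features with
a warning — the documented behavior for small cohorts.

Multi-contrast input concatenates per-contrast feature tables column-wise
with `contrast__` name prefixes before normalization and reduction.

The linear SVM uses a slack penalty C = 10⁶ to approximate an
unregularized maximum-margin fit. The FCNN is a scikit-learn
`MLPClassifier` with hidden layers (50, 40, 30, 20, 10), ReLU, sigmoid
output with log-loss (binary cross-entropy), Adam at its default
parameters (lr 10⁻³, β = 0.9/0.999), an epoch budget of 200 and patience
20 on the loss plateau (tol 10⁻⁴); training is deterministic given the
seed. Model selection across the 25 resamples uses validation AUC (the
pipeline's only reported metric), ties broken by the lowest split index.
Resamples whose train or validation rows are single-class are recorded as
undefined and skipped; test folds with single-class labels contribute no
AUC and are excluded from the fold mean with a warning.

## Evaluation

AUC is computed from average ranks (Mann–Whitney U / (n₊·n₋); ties count
½), with the positive class ER+/PR+/HER2+/ILC scored high, so sub-0.5
values are reported as-is. Result tables mirror the seven contrast
combinations (DCE, SUB, T2, DCE+SUB, DCE+T2, SUB+T2, DCE+SUB+T2); table
regeneration from stored JSON records is a pure function. Category
summaries count selected features per inventory category (summing to the
selection size); stability is the per-feature selection frequency across
the five folds.

## Monte-Carlo problem sizes and what the checks show

All calibration and recovery checks run the *full* protocol (5 patient-wise
folds × 25 resamples, normalization and selection refitted per fold). The
suite uses cohorts of 40–50 patients (≈ 53–66 tumors) and 2–3 cohort
replicates per condition; the acceptance script uses 30–50 patients and 1–2
replicates. These sizes keep a complete run on one CPU within minutes while
leaving the mean-AUC estimators with a standard error of roughly 0.05 per
task/method cell and ≈ 0.02 pooled.

Two statistical conventions follow from that resolution:

* Null calibration asserts that **simultaneous** (Bonferroni-corrected,
  t-based) 95 % confidence intervals over all task/method cells cover 0.5,
  plus that the pooled mean lies in [0.4, 0.6]. Independent per-cell 95 %
  intervals would false-alarm ~40 % of the time family-wise at this sample
  size even for a perfectly calibrated pipeline.
* Signal recovery asserts mean test AUC > 0.65 for the injected ER texture
  effect (observed means are far higher — the canonical effect is strong by
  design) and, for the T2-confined effect, that T2-bearing models beat
  DCE-only models by more than 0.1 AUC.

With the canonical effect switched off the same machinery must sit at
chance; this pairing (null + recovery) is the package's core evidence that
no information leaks across the patient-wise boundaries — reinforced by a
direct audit that corrupting test-row features changes neither the selected
features nor the validation scores.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute AUCs on
  phantoms say nothing about clinical AUCs.
* The feature set is not IBSI-harmonized; names and exact formulas are
  documented here and in the manifest rather than certified.
* No scanner-harmonization (ComBat-style), no peritumoral features, no
  repeatability analysis.
* The FCNN stops on a training-loss plateau; the explicit 25-resample
  validation selection is the guard against overfitting, not early
  stopping on a separate validation curve.
* LASSO's >100-feature target requires >100 fitting rows (see above).
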