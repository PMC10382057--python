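# mammotex

Multi-contrast breast-MRI radiomics: phantom cohorts, 342-feature texture
extraction with six-level gray quantization averaging, ReliefF/LASSO
dimension reduction, and SVM/FCNN classification of tumor molecular markers
under a patient-wise 5-fold × 25-resample protocol with AUROC reporting.

## The problem

Immunohistochemical markers (estrogen receptor ER, progesterone receptor PR,
HER2) and the histological subtype (invasive ductal vs. invasive lobular
carcinoma, IDC/ILC) guide breast-cancer treatment but require a biopsy.
Radiomics asks whether these signatures can be predicted non-invasively from
the quantitative appearance of the tumor on MRI. `mammotex` implements a
complete, tested pipeline for this question on three co-registered contrast
channels per tumor — dynamic contrast-enhanced T1 (DCE), the contrast
subtraction image (Sub = DCE − T1, clipped at 0), and T2-weighted imaging —
with a binary tumor segmentation mask.

Because patient imaging of this kind is not openly shareable, the package
ships a first-class **synthetic cohort generator**: seeded NIfTI phantoms
(perturbed-ellipsoid tumors with a Gaussian-random-field interior texture,
log-normal size law with mean ≈ 24.6 mm / median ≈ 20.3 mm, ~1.33 tumors per
patient, imbalanced and partially missing labels) whose class-linked texture
effects can be switched on, scaled, or confined to a single contrast
channel. Every downstream stage is validated on these phantoms.

## The method

1. **Preprocessing** — masks are smoothed by morphological opening + closing
   with a 3×3×3 cube; all channels are resampled to the DCE grid (trilinear
   for intensities, nearest-neighbor for masks); tumor size is the mean of
   the three bounding-box extents in mm; tumors < 5 mm, tumors missing a
   channel, and (optionally) tumors outside a size-homogeneity window are
   excluded with a logged reason.
2. **Feature extraction** — 342 named features per image–mask pair, across
   conventional size/shape, moments, wavelet transforms, descriptor (LBP /
   gradient), Gabor responses, radial-FFT frequency summaries, and the four
   gray-level texture matrices (GLCM, GLRLM, GLSZM, NGTDM). Texture-matrix
   features are computed at six quantizations L ∈ {8, 16, 24, 32, 48, 64} of
   the in-mask intensity range and averaged.
3. **Dimension reduction** — ReliefF (k = 10 neighbors, top 32 features by
   weight) or LASSO on ±1 labels at the largest penalty on a 100-step path
   whose active set exceeds 100 features. Fitted on train+validation rows
   only, after z-scoring with parameters estimated on the same rows, and
   frozen for the test fold.
4. **Classification** — a linear SVM with C = 10⁶ (effectively
   unregularized) or a fully connected net with hidden layers
   50-40-30-20-10 (ReLU, sigmoid/BCE, Adam). Patients are split into 5
   folds; for each test fold, 25 random 75/25 train/validation resamples of
   the remaining patients each train one model; the model with the best
   validation AUC is evaluated once on the test fold; test AUCs are averaged
   over the 5 folds. Patient-wise disjointness is asserted at run time.
5. **Evaluation** — AUROC as the Mann–Whitney statistic (positive class
   ER+/PR+/HER2+/ILC scored high, ties ½), result tables over the seven
   mono/multi-contrast combinations, per-category summaries of selected
   features, and selection-stability frequencies across folds.

## Worked example

```bash
cat > run.yaml <<'YAML'
seed: 7
cohort:
  n_patients: 30
  effect_size: 1.0     # inject the ER-linked texture effect
experiments:
  tasks: [er]
  contrasts: [[dce], [t2], [dce, sub, t2]]
  reductions: [relieff]
  classifiers: [svm]
YAML

mammotex synth-cohort --config run.yaml --out cohort/
# wrote 38 tumors from 30 patients to cohort/
mammotex extract --cohort cohort/ --out features.csv
# extracted 37 tumors (1 excluded) -> features.csv
mammotex experiment --config run.yaml --cohort cohort/ --out results/
# 3 experiments -> results/
cat results/test_auc_table.csv
# task,method,DCE,T2,DCE+SUB+T2
# er,relieff+svm,1.0000,1.0000,1.0000
```

The cohort directory holds one `*_dce/sub/t2.nii.gz` volume triplet plus a
mask per tumor and a `cohort.csv` label table. One tumor was excluded
because the 3×3×3 smoothing destroyed its (2-voxel-thick) mask — the
exclusion log records why. With the injected class effect
(`effect_size: 1.0` makes ER+ tumors' interior texture coarser by 2 mm of
correlation length) the mean test AUC reaches 1.0 on every channel; with
`effect_size: 0.0` the same pipeline stays at chance (≈ 0.5), which is
exactly what the acceptance checks verify at larger Monte-Carlo sizes.

The same stages are callable as a library (`mammotex.synth`,
`mammotex.preprocess`, `mammotex.features`, `mammotex.reduction`,
`mammotex.classify`, `mammotex.evaluate`, `mammotex.pipeline`).

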