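# Methods

This note records the models, parameter choices and numerical conventions
behind `lnrad`, and what the synthetic phantom does and does not show.

## The prediction problem

Each observation is one lymph node on contrast-enhanced CT with a binary
histology label (metastatic / benign).  Nodes are small (mean volume
~0.15 cm³, short diameter ~6–7 mm), several nodes may come from one
patient, and the training and testing cohorts come from different scanners.
The pipeline builds node-level classifiers from quantitative image features
and evaluates them on a held-out cohort.

## Synthetic phantom cohort

Real imaging of this kind cannot be shipped, so `lnrad.phantom` generates a
cohort with the statistical structure the analysis rests on.  Defaults are
the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| cohorts | 47 / 33 patients, 1–3 nodes each | train (one in-house scanner) / test (three external scanners) |
| prevalence | 0.74 | per-node probability of metastasis |
| lesion volume | lognormal, median 0.13 cm³, clipped to 0.05–0.5 cm³ | ellipsoid with smooth random surface modulation |
| volume effect | ×1.4 for metastatic nodes | makes diameter/volume weakly informative |
| base intensity | 45 ± 8 HU between nodes | contrast-enhanced soft tissue |
| intensity shift | +5 HU for metastatic nodes | small first-order effect |
| texture | structured sd 15 (metastatic) vs 7 (benign) HU, ×lognormal(0, 0.18) per node | band-limited Gaussian field, 1.5 mm correlation length |
| white noise | 12 HU | acquisition noise |
| variance equalization | on | white noise refilled so total in-mask variance is comparable across labels |
| scanners | offsets 0/+8/−6/+12 HU, gains 1.0/1.05/0.95/1.08 | additive/multiplicative batch effects |
| voxel spacing | (1.5, 0.8, 0.8) mm | typical axial CT grid |
| rater-2 displacement | 0.7 mm smooth surface field | calibrated so median Dice ≈ 0.89 |

The central design choice is *where the label signal lives*.  Metastatic
nodes differ mainly in **spatially structured** texture, while total
histogram variance is equalized between labels.  Plain intensity statistics
therefore separate the classes only weakly (through the 5 HU shift and
variance-floor leakage), whereas neighborhood-aware features — texture
matrices and the LBP maps — see the smooth-versus-white contrast directly.
This reproduces the qualitative finding the pipeline is built to detect
(combined ≥ LBP-only ≥ intensity-only, with the diameter baseline behind),
without borrowing any measured effect size: the intensity distributions of
metastatic versus benign nodes on CT are not published, so these amplitudes
are free parameters of the phantom, chosen once and documented here.

What the phantom does **not** emulate: anatomy (no surrounding organs,
vessels or fat planes), partial-volume effects at node boundaries, contrast
timing variation, beam hardening, or inter-patient correlation of texture
beyond the shared scanner.  A green test suite on the phantom therefore
shows the *machinery* is correct and the pipeline can recover structure it
is pointed at — not that the same AUCs would be reached on patients.

The rater-2 perturbation displaces the mask boundary by a smooth zero-mean
Gaussian field added to the signed distance.  Its default magnitude
(0.7 mm) was calibrated by Monte-Carlo on the default lesion size so the
median Dice between raters sits in the published 0.85–0.93 agreement band;
Dice decreases monotonically in the magnitude.

## Preprocessing conventions

* Resampling target 1 mm isotropic; image via cubic B-spline.
* **Mask resampling** interpolates the signed Euclidean distance field and
  thresholds at zero.  The more common "interpolate the binary mask,
  threshold at 0.5" rule was implemented first and rejected: on a
  2 mm-slice grid it loses up to 16% of a small node's volume, because
  occupancy sampled at coarse slice positions cannot represent the bulge of
  a convex lesion between slices, while the distance field can.
* Discretization: fixed bin width 5 HU anchored at absolute multiples of
  the width (`floor(x/w)` convention), so bin edges are scanner-independent
  and adding k·5 HU to all intensities leaves every bin index — and hence
  every discretization-based feature — unchanged.
* Axis order is (z, y, x); world coordinates are `origin + index·spacing`;
  all shape quantities are in mm.

## Feature panel (156)

18 first-order + 10 shape + 74 texture + 54 LBP.  The exact list ships as a
versioned manifest (`feature_manifest.json`); it is a reconstruction of a
panel of this size, assembled from the standard feature families:

* First-order: the 18 usual statistics; entropy/uniformity on the 5-HU
  bins; variance/skewness population moments; kurtosis **non-excess**
  (Gaussian → 3).  Constant VOIs return 0 for skewness/kurtosis.
* Shape: mesh volume and surface area from marching cubes of a Gaussian
  anti-aliased (σ = 0.6 mm) level set whose iso-level is chosen to enclose
  exactly the mask's voxel count.  Raw binary meshing was rejected: the
  staircase inflates a digital ball's area by ~9% (sphericity 0.91 instead
  of ≥0.95); anti-aliasing alone shrinks small lesions; the
  volume-preserving level fixes both.  Axis lengths are 4√λ of the
  coordinate-covariance eigenvalues; Elongation = √(λ₂/λ₁) and
  Flatness = √(λ₃/λ₁) lie in (0, 1] with 1 = isotropic (so a 2×1×1 box has
  *lower* elongation than a cube — the value measures compactness, not
  stretch).  Single-voxel masks fall back to the raw 0.5-level mesh and
  report Elongation/Flatness 1.
* Texture: GLCM (distance 1, 13 unique directions, symmetrized), GLRLM
  (same directions), GLSZM/GLDM with 26-connectivity (GLDM α = 0,
  dependence size includes the center voxel), NGTDM with 26-neighborhood.
  Directional families aggregate by averaging per-direction features,
  which makes the averages exactly invariant under 90° grid rotations.
  Degenerate single-bin VOIs return the documented fallbacks (contrast 0,
  correlation and MCC 1, NGTDM coarseness capped at 10⁶).
* LBP: neighbors sampled by trilinear interpolation at 42 icosphere
  directions, radius 1 mm, mirror padding at volume borders; binary pattern
  `neighbor − center > 10⁻⁶` (the tolerance absorbs interpolation round-off
  on flat regions, and ties count 0).  "Level 1" and "level 2" maps are the
  energies of the degree-1/degree-2 real spherical-harmonic components of
  the pattern — approximately rotation-invariant by construction.  The
  third map is the excess kurtosis of the **raw** neighbor differences
  (binarized samples would have trivial kurtosis); zero-variance
  neighborhoods map to 0.  Radius, sampling density and the kurtosis
  construction are configuration, not fixed facts.

Extraction crops to the mask bounding box plus a margin larger than the LBP
radius, which changes no feature value.

## Robustness, harmonization, modeling

* **ICC(3,1)**: two-way mixed, single-measure, *consistency* form — blind
  to fixed rater offsets.  Computed on raw feature values.  Features below
  0.8, or with no between-subject variance, are excluded; exclusion
  fractions are reported per class.  On the default phantom, shape features
  are excluded at the highest rate and LBP at the lowest, matching the
  expectation that boundary-derived quantities suffer most from contour
  disagreement.
* **ComBat**: parametric empirical-Bayes location/scale correction per
  scanner, label-blind (no biological covariates in the design — a caveat
  when batch and outcome are confounded).  Fit jointly on train+test by
  default, since every batch must be seen at fit time and the test scanners
  do not appear in training; a train-only mode exists for settings where
  they do.  EB iterations stop at relative change < 10⁻⁶ or 100 rounds.
  The implementation matches R's `sva::ComBat` to ~10⁻⁴ on shared inputs.
* **LASSO**: λ grid geometric from λ_max = max|Xᵀ(y−ȳ)|/n over 30 points;
  λ chosen at minimum mean CV binomial deviance ("λ-min"; the 1-SE rule is
  an option).  CV folds are stratified and, by default, patient-grouped:
  multiple nodes per patient are correlated, and splitting a patient across
  folds would leak.  The solver behind each fit is scikit-learn's liblinear
  L1 logistic regression with unpenalized intercept; near-separation at
  tiny λ is handled by the iteration cap rather than divergence.
* **Conventional models**: maximum-likelihood logistic fits on standardized
  covariates; quasi-separation is detected from exploding coefficients or
  standard errors (|β| > 10 or SE > 10 on the standardized scale) and the
  Wald interval is then reported as (0, ∞) with an instability flag —
  expert-rating-style covariates that perfectly order a small test set do
  exactly this.
* **Maxstat cutpoint**: candidate splits are midpoints of consecutive
  distinct scores with split proportion in [0.10, 0.90]; the statistic is
  the absolute standardized two-sample linear rank statistic with Wilcoxon
  (midrank) scores; ties in the statistic resolve to the first (lowest)
  maximizing split.

## Evaluation

AUC is the tie-corrected Mann–Whitney concordance (ties ½), hence invariant
under monotone transforms.  Bootstrap CIs resample within each class
(stratified; B = 1000 by default, seed-deterministic) — with only ~13
negative test nodes, unstratified resampling would produce single-class
replicates.  The paired model comparison is a stratified paired bootstrap
of the AUC difference (two-sided sign p-value); the rank-correlation-based
paired U-statistic test it stands in for is version-dependent in its
reference implementation, and the bootstrap form is exact about what it
resamples.  Decision curves are node-level: net benefit
`TP/n − FP/n · p_t/(1−p_t)` against treat-all and treat-none references.
Calibration uses 10 equal-width bins, empty bins omitted.

## Train/test hygiene

Feature standardization, the ICC filter, λ selection and the maxstat
cutpoint are all computed on the training cohort and frozen before the test
cohort is touched.  The one deliberate exception is joint-fit ComBat
(above), which is label-blind.

## Problem sizes

The default study is 80 patients / ~140–150 nodes, which the pipeline
processes end to end in well under two minutes on one CPU (feature
extraction ~0.04 s per node after bounding-box cropping).  Tests and
examples use reduced cohorts (8–28 patients) that exercise every stage; the
acceptance script runs the full default study.

## Known limitations

* The 156-feature manifest is a reconstruction; other panels of the same
  size and family structure exist.
* The phantom's effect sizes are assumptions, not measurements; only
  orderings and calibration bands derived from its own configuration are
  asserted.
* ComBat here has no reference-batch or non-parametric variants, and no
  outcome-protecting covariates.
* The paired AUC comparison is a bootstrap, not the asymptotic U-statistic
  test; p-values on tiny cohorts are granular (resolution ~1/B).
* No DICOM reading, no PET volume synthesis, no 2D extraction mode, no
  wavelet/LoG filtered features.
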