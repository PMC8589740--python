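# Methods

## Overview

`ctnq` estimates three clinical neuroimaging grades from a head CT volume:
medial temporal lobe atrophy (MTA, Scheltens scale, 0–4 per hemisphere),
global cortical atrophy (GCA, Pasquier scale, 0–3, whole brain and per lobe)
and white-matter-lesion load (Fazekas scale, 0–3).  The pipeline is:

1. **Skull stripping** — five-step EM brain extraction.
2. **Spatial normalization** — 9-parameter affine of the subject skull mask
   to a mean CT template, optional nonrigid refinement.
3. **Segmentation** — an ensemble of K = 10 independently trained voxelwise
   networks segments CSF and white-matter lesions from the z-scored,
   template-space CT; the ensemble is merged with a correlation-weighted
   fusion rule.
4. **Measures** — the fused maps and template masks are transported back to
   native space; unitless volume fractions are computed there.
5. **Calibration** — a two-step regression (linear + piecewise-linear median
   matching) maps each fraction to its grade scale.

Because no clinical cohort ships with the package, a synthetic head-phantom
generator provides paired CT-like volumes, voxel-level ground truth and
known severities.  All quantitative claims in the test suite refer to this
synthetic population.

## Phantom generator

The phantom is an analytic head model evaluated on the voxel grid (default
64³ at 1 mm isotropic; anisotropic spacing supported): an ellipsoidal skull
shell with two solid protrusions (occipital and nasofrontal — these make the
shape chiral, so mask-based registration has a unique optimum, as it does on
real heads), brain parenchyma with a GM rim and WM core, two lateral
ventricles, and CT-like pseudo-Hounsfield class intensities (air −1000, bone
900, WM 30, GM 38, CSF 8, WML 20) plus additive Gaussian noise (default SD
10 HU, a typical parenchymal noise level for clinical head CT).

Severities map **linearly** to structure volumes so calibration recovery is
well-posed:

- **MTA (per hemisphere)** — a medial-temporal CSF pocket of volume
  30 + 90·severity mm³.
- **GCA** — two components: a uniform sulcal rim (parenchyma shrinks by 1.5%
  of cavity volume per grade) and eight fixed radial sulcal grooves whose
  depth grows by 1.5 mm per grade (1 mm at grade 0).  The grooves matter:
  real cortical atrophy widens discrete sulci by millimetres, and a purely
  uniform rim would move every boundary by well under a voxel over the whole
  scale — a signal that vanishes under interpolation and registration
  residuals.  Grooves avoid the medial-temporal region so the two atrophy
  scales stay independently controllable.
- **Fazekas** — five periventricular lesion blobs with total volume
  180·severity mm³, carved only from WM.

Cohorts draw severities uniformly over the full scales, rigid pose
perturbations (±3 voxels, ±8°) and an isotropic head-size factor
(0.97–1.03), which gives the 9-parameter registration its scale degrees of
freedom.

What the phantom does **not** model: partial-volume averaging beyond what
grid sampling produces, beam hardening, gantry tilt, scanner-specific noise
spectra, cortical folding topology, or anatomical covariance between scales
(severities are sampled independently).  Passing tests therefore demonstrate
that the method recovers the structural signal it targets under controlled
conditions, not clinical-grade performance.

## Skull stripping

Steps: nonlocal-means denoising (patch radius 1, search radius 3, strength
0.8× the estimated noise sigma); percentile clipping of in-field intensities
(defaults 0.1/99.9); two-class Gaussian EM over the field of view (voxels
above −200 HU) with **fixed priors** (default 0.5/0.5) — only means and SDs
are updated, and the log-likelihood trace is kept and asserted
nondecreasing; the skull threshold is the equal-posterior crossing of the
two fitted Gaussians (root of the posterior-equality quadratic between the
class means), with a fixed 200 HU fallback if the classes are inseparable;
morphological fine-tuning is opening → largest connected component →
closing → hole fill with a ball of radius 2 voxels, followed by re-exclusion
of any supra-threshold voxel the closing re-introduced.  EM initialization
is the 25th/75th intensity percentiles.  Total brain volume — the
normalizer for every measure — is the voxel volume times the mask count.

## Registration

The affine stage has exactly 9 parameters (3 translations mm, 3 rotations
degrees, 3 scales) about a fixed center (template skull-mask centroid), and
maps template world coordinates to subject world coordinates.  Both binary
skull masks are Gaussian-smoothed (σ = 1 voxel, scaled per pyramid level) so
the SSD objective is differentiable in the parameters; optimization is a
deterministic Powell search over a 3-level pyramid (levels 4, 2, then a
short subsampled full-resolution polish).  Scales are parametrized as
1 + u/50 so a unit step in any coordinate is comparable.  On 50 random
transforms (|t| ≤ 5 voxels, |θ| ≤ 10°, scales 0.9–1.1) recovery is
sub-voxel and sub-degree in the median (asserted in the acceptance suite).

Nonrigid refinement is an order-1 B-spline free-form deformation (default
3³ control points) maximizing a 32-bin Parzen-smoothed normalized mutual
information, with a second-difference bending penalty (weight 1e-4 — NMI
changes are O(1e-3), so the penalty must stay subdominant).  Outer
iterations that do not improve the objective are rejected, which enforces
the NMI-nondecreasing contract.  The desk preset **disables** nonrigid
transport: the synthetic cohort's inter-subject variation is rigid + scale
by construction, so affine transport is already exact; the stage is
implemented and tested and can be enabled in `RunConfig(use_nonrigid=True)`.

Transport conventions: world-mm coordinates, voxel centers; nearest-neighbor
for labels/masks, trilinear for intensities and probabilities; the
template→native direction inverts the affine exactly and inverts a
deformation by fixed-point iteration (5 steps).

## Template bundle

Built from an aligned low-severity reference cohort: voxelwise-mean CT,
skull and brain masks from the canonical geometry, spherical MTL (left and
right) and deep-WM masks covering the maximal extent of their structures
(clipped to the intracranial cavity), a 4-lobe label map extended into CSF
by nearest-labelled-voxel assignment (Euclidean distance in world mm, so
anisotropic grids remain correct), and a voxelwise 99th-percentile CSF map
(linear interpolation between order statistics; permutation-invariant).

## Segmentation and fusion

The segmenter is a voxelwise residual network over a fixed multi-scale
convolutional filter bank: the z-scored CT, Gaussian smoothings (σ = 1, 2,
4), Laplacians of Gaussian at the same scales and a gradient magnitude — 8
channels — feed a residual MLP (input projection, 2 residual blocks of
width 16, softmax head over background/CSF/WML), trained with Adam on
cross-entropy over a stratified voxel subsample (3000 per volume; lesion and
CSF voxels oversampled).  Backprop and Adam are implemented in numpy;
training is deterministic given the seed.  Class weighting defaults to
**calibrated** importance weights that undo the stratified oversampling, so
softmax outputs stay calibrated to in-brain prevalence; this matters because
the fusion threshold is fixed at 0.5, and pure inverse-frequency weighting
(available as `class_weight="inverse_frequency"`) over-calls the rare WML
class by an order of magnitude at that threshold.

Ensemble variability comes from K independently seeded trainings (the
repetition count defaults to 10).  Fusion, per class and over the brain
domain:

1. Pearson correlation c_ij between every pair of member probability maps.
2. n_i = #{ j : c_ij > min(0.8, 0.9·max c_ij) }, where the max runs over
   **distinct** pairs (the diagonal c_ii = 1 would otherwise pin the
   threshold at 0.8 and make the 0.9·max branch unreachable) and j = i is
   counted (c_ii passes any threshold below 1).
3. w_i = n_i / Σ n_i.
4. Fused probability Σ w_i·p_i, thresholded at 0.5 (≥) for the binary map.

Members with (numerically) zero variance have undefined correlations and
are excluded with a warning.  The implementation is tested for exact
agreement with an explicit loop-level oracle on randomized ensembles, and
for the reduction to the unweighted mean when all pairwise correlations
exceed 0.8.

The GCA measure consumes the **un-thresholded** fused CSF probability.

## Percentile-map calibration

`train_pipeline` rebuilds the bundle's CSF p99 map from the trained
ensemble's own fused probabilities on a pose-randomized reference cohort
pushed through the regular spatial stage.  Two reasons: (i) a percentile map
built from label concentrations is exactly zero deep in parenchyma while a
softmax emits small positive probabilities there, so a strict `>` would
flag most of the brain at every severity; (ii) the reference band must
include the pipeline's own registration-residual spread, as a reference
population processed by the same registration naturally would.  With both in
place, ~1% of normal-range probability values exceed the map by
construction.

## Measures and calibration

All fractions are computed in native space, normalized by total brain
volume: CSF within each transported MTL hemisphere mask (MTA); brain volume
where fused CSF probability **strictly** exceeds the transported p99 map
(GCA; restricted per transported lobe label for the lobe variants); lesion
volume within the transported deep-WM mask (Fazekas).

Calibration per scale: OLS of grade on measure, then a monotone
piecewise-linear correction with one knot per observed rounded grade,
mapping the per-grade median step-1 estimate to the per-grade median
ground-truth grade; non-monotone medians are repaired isotonic with a
warning; beyond the end knots the correction extrapolates linearly with the
adjacent segment's slope.  Continuous grades are clamped to the scale range
and rounded (half away from zero) only at categorization; the normality
dichotomy is grades 0–1 vs > 1.  MTA left and right are calibrated
separately and the combined MTA is their mean — the combination rule is a
package choice.  Per-lobe GCA uses lobe-specific calibration models against
the global atrophy grade.

## Agreement battery

Pearson r on continuous (pre-clamping) grades; % identical categorical
grades; % within one grade; % identical normality dichotomy; quadratically
weighted Cohen's kappa (weights ((i−j)/G)², any positive scaling cancels;
cross-checked against scikit-learn); Bland–Altman mean difference and
mean ± 1.96 SD limits.  Confusion matrices are rows = reference source,
columns = test source.  Kappa is undefined (error) when a rater is constant.

## Study conditions and problem sizes

The standing validation study trains on 30 phantoms and grades 20 held-out
phantoms with the 10-member ensemble, a 14-subject reference cohort for the
percentile map, 30 training epochs and 3000 sampled voxels per volume; the
phantom grid is 64³ at 1 mm with noise SD 10 HU.  These sizes give stable
correlation estimates from a complete train-and-evaluate cycle in minutes on
one CPU.  The network-scale knobs (`n_residual_blocks`, `base_channels`,
`epochs`) can be raised for larger grids.

## Numerical choices and degenerate inputs

- EM stops on relative log-likelihood change < 1e-6 or 50 iterations;
  degenerate (zero-variance) input raises.
- Zero-variance fusion members are detected with a relative tolerance
  (1e-12 of the data magnitude), not exact zero.
- Rounding ties go away from zero (2.5 → 3); documented because the
  convention changes ~1 in 100 random categorizations.
- Strict inequality against the percentile map (a tie is not abnormal).
- `transport` with nearest-neighbor interpolation and an identity transform
  is bit-exact; label alphabets are never expanded.
- Empty field of view, empty masks, constant images and mismatched grids
  raise typed errors at the offending stage.

## Known limitations

- The phantom's geometric simplicity means segmentation is much easier than
  on clinical CT; absolute Dice and correlation values here do not transfer.
- Per-lobe GCA on phantoms shares one global severity, so lobe-specific
  recovery is weaker (temporal and occipital lobes are small and partially
  occupied by MTL pockets / few grooves).
- The affine stage assumes the skull mask determines pose and scale; heads
  with large focal defects would violate this.
- Nonrigid refinement uses a coarse control grid; it is a refinement for
  mask transport, not a diffeomorphic morphometry tool.
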