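# Methods

`wavetex` quantifies the heterogeneity of multispectral whole-slide
pathology images across four colorectal tissue grades — stroma (ST), benign
hyperplasia (BH), intraepithelial neoplasia (IN), carcinoma (CA) — with
multiscale texture features from a single-level 3D wavelet decomposition.
This note records the model, its assumptions, the tunable parameters, the
numerical conventions, and what the bundled synthetic data can and cannot
show.

## Data model

A sample is a volume `V[x, y, z]` whose first two axes are spatial pixels
and whose third axis indexes 16 narrow spectral bands spanning 500–650 nm
(9.375 nm band spacing, emulating a liquid-crystal tunable filter).  A
region of interest (ROI) is a 2D binary mask over the spatial frame,
either supplied (ground truth) or detected by the segmentation stage.
Before feature extraction every volume is normalized by dividing all voxel
intensities by the standard deviation of the whole volume, making features
invariant to global gain.

## Segmentation

ROI detection is region-based: the mean image across spectral bands is
block-mean down-sampled ×8 per axis (default, configurable), a
morphological Chan–Vese two-phase active contour evolves from a full-frame
rectangular initial contour, and the converged coarse mask is up-sampled
(nearest neighbour) and closed with a 3×3 structuring element.  Connected
components below 50 full-resolution pixels are dropped as speckle.  Region
energies carry no object/background semantics, so the foreground phase is
chosen as the one whose mean intensity differs more from the frame-border
mean (the border is assumed to be background).  Iteration stops when the
fraction of pixels changing per iteration falls below 1e-3, when the
discrete contour enters a period-2 oscillation (treated as converged), or
at 500 iterations.  A zero-variance image yields zero regions rather than
an error.  Agreement with a reference mask is reported as Jaccard (JSC),
Dice (DSC), false-positive rate `|B\A|/|Ā|` and false-negative rate
`|A\B|/|A|`, all as pixel-count fractions.

## Wavelet decomposition

The volume is decomposed by a separable single-level 3D discrete wavelet
transform using the orthonormal Daubechies-2 (db2) pair, applied with
dyadic decimation along x, then y, then z (the 2D + 1D scheme).  This
yields eight octant sub-bands LLL, HLL, LHL, HHL, LLH, HLH, LHH, HHH,
where letter *i* is the low/high-pass filter applied on axis *i* in
(x, y, z) order; each octant has half the input extent per axis.

Boundaries are periodized: this is the only mode in which the analysis
operator is exactly orthogonal, so sub-band lengths are exactly N/2,
energy is conserved (Parseval) and the inverse transform (the adjoint)
reconstructs to machine precision — properties the test suite asserts at
1e-10/1e-8 tolerances.  The filter is stored in the classical Daubechies
order with analysis `a[n] = Σ_k g[k]·x[(2n−1+k) mod N]`; this convention
coincides coefficient-for-coefficient with PyWavelets' `periodization`
mode, which the tests use as an independent reference.

ROI handling: the volume is cropped to the ROI bounding box, voxels
outside the ROI are zeroed, odd axis extents are edge-padded by one voxel
(recorded in provenance), and the transform runs on the regular cropped
grid.  Quantifiers are then restricted to sub-band voxels whose 2×2×2
parent cell intersects the ROI (any-parent rule), so lesion texture is
measured without contamination from the surrounding frame.

## Texture quantifiers

Each octant is summarized inside the decimated ROI support by three
quantifiers, giving 3 × 8 = 24 named features per sample
(`variance_LLL` … `energy_HHH`):

* **Variance** — population (1/N) mean squared deviation from the mean of
  the sub-band values.  The raw-sum variant (no 1/N) is available behind a
  flag but is not the default, since the mean-based form matches the
  quantifier's purpose of measuring spread about the texture average.
* **Entropy** — Shannon entropy of the value histogram with 256
  equal-width bins spanning the ROI min–max, in bits (log base 2), with
  0·log 0 := 0; range [0, 8] bits.  A degenerate range (constant sub-band)
  collapses to a single occupied bin and entropy 0.
* **Energy** — sum of squared bin probabilities of the same histogram
  (uniformity); range (0, 1], equal to 1 exactly when entropy is 0.

Min–max binning makes entropy and energy invariant to affine maps of the
sub-band values; the volume-level SD normalization makes variance
gain-invariant.  Feature tables are z-scored per column (population SD)
before classification; constant columns are zeroed with a warning.

## Univariate statistics

Each feature is tested with a one-way fixed-effects ANOVA across the four
grades; the 24 p-values are adjusted by the Holm–Bonferroni step-down
procedure and flagged at familywise α = 0.01.  Because the F statistic is
invariant to per-column affine maps, testing before or after z-scoring is
equivalent (asserted by a test).  Degenerate inputs follow an explicit
policy: zero within-group variance with distinct means gives p = 0; zero
variance everywhere gives F = 0, p = 1.  The report keeps raw and adjusted
p-values plus −log10 transforms for heatmap rendering.

## Classification

A 100-tree random forest (√p features per split, unlimited depth, seeded)
is evaluated by stratified 5-fold cross-validation.  The fold assigner is
in-package: per class, shuffled indices are dealt round-robin with a
rotating fold offset, so per-class counts differ by at most one across
folds and classes smaller than k simply occupy fewer folds (scikit-learn's
splitter rejects that case).  Per fold, per-class one-vs-rest confusion
counts give accuracy/sensitivity/specificity; these are macro-averaged
across classes and then summarized as mean ± SD over folds.  Plain
multiclass accuracy is reported alongside, since the one-vs-rest
macro-average counts true negatives and therefore runs higher on a 4-class
problem.  AUC is computed per fold from held-out class-probability scores
as the Mann–Whitney pairwise-concordance probability (ties one half) —
identical to trapezoidal ROC integration, an equivalence asserted to
1e-12 — then averaged over folds.  Feature subsets (one octant's 3
features, one quantifier's 8 features, or all 24) reproduce the per-band
and per-quantifier experiment grids.

## Synthetic multispectral generator

Real multispectral histology cohorts of this kind are not publicly
deposited, so the package ships a generator whose defaults define the
study conditions for all Monte-Carlo tests: 39-sample cohorts composed
ST=9, BH=10, IN=9, CA=11, 16 bands over 500–650 nm.

A sample is built from (1) an irregular star-convex lesion mask (12
control radii, smoothed; 20–60 % of the frame) — the ground-truth ROI; (2)
inside the lesion, a correlated Gaussian background field (class-specific
correlation length) plus dark elliptical "nuclei" blobs with
class-specific density, radius and contrast on a tissue level of 0.55
against a bright background of 0.95; (3) a per-class spectral profile
(monotone attenuation slope plus a small sinusoidal ripple) multiplying
the spatial field across bands; and (4) additive white Gaussian noise
(SD 0.02 by default).  Malignancy is modelled as progressively denser,
smaller, higher-contrast nuclei on a shorter-range stroma field with a
steeper, more rippled spectral profile; no quantitative description of
per-class texture exists for the real tissue, so these parameters are
invented and were frozen after a single calibration pass of the planted
separability checks.  `effect_scale` interpolates every class parameter
between the across-class mean (0 — the null generator, under which all
four classes are a single texture distribution and, for a fixed seed, give
bitwise-identical volumes) and the full class-distinct values (1, the
default).  All randomness flows through one integer seed; cohorts derive
per-sample seeds as `seed + index`.

What passing tests show: the pipeline detects planted spatial- and
spectral-frequency texture differences of realistic effect size, controls
the familywise error under the null, and its segmentation recovers
smooth star-convex lesions with strong intensity contrast.  What they do
not show: performance on real stained tissue, whose optics (H&E
absorption, LCTF transmission), nuclear morphology, spatial
nonstationarity and annotation noise the generator does not emulate.

## Problem sizes and runtime choices

Desk-scale defaults keep the full suite and the acceptance script
comfortably inside interactive runtimes: frames are 128 × 128 × 16 for the
planted-effect suites (the full 512 × 512 × 16 geometry is available via
`SimParams`), 48 × 48 × 16 for the 200-cohort null Monte-Carlo, and 10
cohort seeds for the classification grid.  These sizes are the package's
own reproducibility choices and are fixed in the tests and
`scripts/acceptance.py`.

## Known limitations

* Single decomposition level and db2 only by default; other orthonormal
  banks plug in but are untested extensions.
* The active contour assumes the lesion/background intensity contrast
  dominates; faint or multi-modal lesions may segment poorly.
* One-vs-rest macro-averaging is one of several defensible multiclass
  reductions; plain multiclass accuracy is reported alongside for
  comparison.
* At n = 39, fold-level metrics are coarse (test folds of 7–8 samples);
  SDs over folds understate sampling variability across cohorts.
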