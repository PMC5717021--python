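# Methods

## DOP from Stokes volumes

Each Stokes component (I, Q, U, V) is smoothed laterally — along adjacent
A-lines within a frame, never axially or across frames — with a Gaussian
kernel parameterized by its FWHM in A-lines (default 12; σ =
FWHM/(2√(2 ln 2))), truncated at 3σ and renormalized to unit sum at the
volume edges (zero-padding followed by division by the in-support kernel
weight, which is exactly edge renormalization and introduces no padding
bias). The DOP per voxel is √(Q̄²+Ū²+V̄²)/Ī, evaluated independently for
every spectral bin and input state and averaged with equal weight
1/(P·N). For physical inputs (per-voxel |QUV| ≤ I, enforced by the
`StokesVolume` constructor with a 1e−9 float guard) the averaged DOP
cannot exceed 1: smoothing is a convex combination, so the triangle
inequality bounds the smoothed polarized norm by the smoothed intensity.
Overshoot beyond 1e−9 therefore indicates unphysical input and raises;
smaller float overshoot is clipped to 1.

**Cylinder ROI.** A voxel belongs to the cylinder when its lateral center
lies within diameter/2 (inclusive) of the axis and its depth within
[z_top, z_bottom] (inclusive); indices are 0-based with physical
coordinate = index × spacing. The default diameter is 1 mm. Depth levels
whose lateral mask is empty are dropped from the profile rather than
zero-filled. The axial extent is an explicit input (no automatic layer
segmentation); the depth-profile line fit uses the full retained profile.

**DOPSlope sign convention.** The reported slope is the *negated* OLS
slope of mean DOP vs depth (mm), so a downward DOP trend — the typical
behaviour as light depolarizes with depth — yields a positive DOPSlope,
matching how the feature is tabulated.

## Birefringence homogeneity

Quantization uses L equal-width bins (default 12) on [lo, hi) = [0, 1)
deg/μm; out-of-range values clip into the end bins and the right edge
closes into level L. Out-of-ROI voxels carry a missing code and never
pair. The co-occurrence matrix counts directed (source → target) pairs at
a (Δz, Δx) pixel offset, default (5, 0) — five pixels along the axial
grid axis, not micrometres. For 3-D ROIs all frames accumulate into one
matrix, giving a single Hom per lesion. Homogeneity is
Σ P(i,j)/(1+|i−j|), the co-occurrence summary that is 1 exactly when all
mass is diagonal. It depends only on |i−j|, so directed vs symmetrized
counting cannot change it (asserted in tests); directed counting is kept
as the primitive. The formula is a design choice — the common toolbox
definition — since alternatives (e.g. 1/(1+(i−j)²)) would change values.

## Cohort and models

The cohort CSV has one row per wound-month with columns wound_id,
animal_id, treatment, month, scar_area_mm2, hom, dop_slope; months
1, 2, 3, 6 are required, month 5 is carried but never modeled. Features
are z-scored per column with the sample (n−1) standard deviation
(``ddof=0`` switches to population) using moments fitted on the whole
cohort before cross-validation; a strict per-fold mode exists, and a test
documents that for unregularized OLS with intercept the two modes give
*identical* held-out predictions (least squares is equivariant under
affine column maps, so the pooled-moments "leak" is vacuous for this
model class — it would matter only for regularized or non-affine models).
The target, month-6 scar area in mm², is never transformed.

Models are fitted by least squares with intercept; a rank-deficient
design raises rather than being silently regularized. LOOCV refits the
model explicitly for each held-out wound. The permutation control
permutes only the target vector (features and fold structure untouched),
B = 1000 by default, and reports the one-sided empirical p-value
(1 + #{null ≥ observed})/(B + 1), which can never be 0; the analytic
correlation p-values are reported alongside and neither is privileged.
Because OLS predictions are linear in the target, the control precomputes
each fold's prediction weights once and applies them to every shuffle —
algebraically identical to refitting per fold (asserted against the
explicit-refit path to 1e−10). The model-comparison table covers the
seven variants K ∈ {1},{2},{3},{1,2},{1,3},{2,3},{1,2,3} in that fixed
order, with no multiple-testing correction across variants. RMSE uses
1/n, not 1/(n−k). Spearman uses average ranks on ties (the features are
continuous, so ties have measure zero).

## Synthetic data

**Cohort generator.** Defaults emulate the study conditions: 9 animals ×
4 wounds, months {1, 2, 3, 5, 6}, and per-(feature, month) means and
standard deviations set to the published summary-table values. Dependence
is a single latent severity factor u per wound (standard normal, with an
animal-shared variance component of 0.2): each feature is
μ + σ(w·u + √(1−w²)·ε) with independent standard-normal ε, so the
population correlation between any feature and the outcome is the product
of their loadings. Default loadings are 0.2 for month-1 features and 0.5
for later months — month 1 weakly predictive, months 2–3 informative —
and the month-6 outcome loading defaults to 0.8 (the signal dial; 0 gives
a null cohort). The true inter-feature correlation structure of the real
data is unpublished, so this single-factor structure is a modeling
choice: tests validate the pipeline against the generator's own ground
truth, not against the original animals. Bounds (scar_area > 0,
hom ∈ [0,1], dop_slope ≥ 0) are enforced by truncation; at the default
moments the strongest clip (month-3 hom, 2.2σ from its upper bound)
biases the mean by ≈0.001, well inside the 3-standard-error moment
fidelity asserted at n = 10,000.

**Tomograms.** The polarized fraction decays linearly, f(z) = f₀ − s·z
(defaults f₀ = 0.95, s = 0.25/mm over a 400 × 2048 × 1 grid spanning
1 mm × 10 mm, five spectral bins, two input states; these sizes mirror a
realistic single-frame acquisition). The polarized Stokes component lies
along a unit direction rotating with depth (period 0.5 mm, emulating
birefringence); the unpolarized remainder is zero-mean isotropic noise on
(Q, U, V) with per-component σ = noise_scale·(1−f)/√3 (noise_scale
default 0.5), which keeps |QUV| ≤ I essentially surely — the rare
violators are rescaled onto the sphere. After lateral averaging the
expected DOP converges to f(z) with a positive bias of order
σ̄²/f ≈ 5·10⁻⁴ at the deepest, noisiest voxels, two orders below the
±0.02 recovery tolerance. What the generator does *not* emulate: OCT
speckle statistics, depth-dependent intensity decay, focus and
birefringence-artifact effects — so slope-recovery tests demonstrate the
estimator's correctness, not robustness to real acquisition artifacts.

**Birefringence maps.** Base level (0.3 deg/μm) plus Poisson-placed
Gaussian spots (density 50/mm², radius 30 μm, amplitude 0.4 deg/μm),
clipped at 0. Amplitude 0 is the uniform scar-like limit (Hom = 1);
rising amplitude monotonically lowers Hom. Spots are all-positive bumps,
a simplification of the true mesh-like pattern.

## Numerical choices and degenerate inputs

* Gaussian kernel radius caps at the lateral extent (larger offsets never
  overlap the support, so this is exact, and lets a very large FWHM
  realize an equal-weight average).
* A delta kernel (FWHM → 0) reduces the DOP to the per-voxel ratio,
  checked against a direct loop oracle.
* Non-positive smoothed intensity, empty ROIs, all-missing quantization,
  zero valid GLCM pairs, zero-variance columns, rank-deficient designs,
  and sub-minimal profile/vector lengths all raise with the offending
  voxel/column/fold named.
* Problem sizes in tests were chosen to keep the full suite and the
  acceptance script comfortably re-runnable on a laptop-class single
  core: 50 cohorts for the hat-matrix identity, 20 tomogram seeds for
  slope recovery, 50 null cohorts × 200 shuffles for the calibration
  check, 100 seeds per coupling level for signal recovery.

## Known limitations

* The regression coefficients fitted on synthetic cohorts have no
  biological meaning; only the pipeline's statistical behaviour is
  validated.
* Raw fringe reconstruction (spectral binning, axial-offset
  birefringence estimation) is upstream of this package: it consumes
  Stokes volumes and birefringence maps as inputs.
* Scar areas are inputs, not derived from masks or photographs.
* One volume per lesion is assumed (no multi-acquisition averaging).
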