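# Methods

`vesselmink` quantifies the three-dimensional architecture of capillary
networks imaged by confocal fluorescence microscopy. The analysis has two
stages: (1) conversion of a noisy intensity z-stack into a binary tubular
vessel model, and (2) morphometric quantification of that model by the four
3D Minkowski functionals evaluated across a family of uniform dilations,
condensed into a fixed 40-feature summary and analysed at cohort level.
This note records the model, its conventions, the tunable parameters, and the
choices made where the design was genuinely open.

## Digital geometry conventions

A `BinaryVolume` is interpreted as the union of closed unit voxels, which
realizes the (26-connected foreground, 6-connected background) digital
topology; the complementary (6, 26) pair is available behind a flag. Arrays
are indexed `(z, y, x)` with TIFF pages mapping to optical sections; spacing
is `(dx, dy, dz)` in µm. Before any counting, volumes are padded with one
layer of background, so structure clipped at the field-of-view border is
counted as boundary (each field is treated as a closed sample; minus-sampling
edge correction would be an extension).

## The four Minkowski functionals

For a body X the package reports:

* **Volume** V(X): foreground voxel count (× voxel volume in physical mode).
* **Surface area** S(X): Crofton-type estimate from foreground/background
  intercept counts along the 13 lattice directions (3 axes, 6 face diagonals,
  4 body diagonals). Direction weights are the spherical-Voronoi solid-angle
  fractions of the 26 signed direction vectors, computed at run time (and
  adapted to anisotropic spacing by weighting the physical direction vectors).
  For a line direction ω with one sampling line per perpendicular area
  `a_d = v_vox / ℓ_d`, the intercept count estimates `∫_∂X |⟨n,ω⟩| dA / a_d`;
  since the spherical average of `|⟨n,ω⟩|` is 1/2,
  `S ≈ 2 Σ_d w_d n_d v_vox / ℓ_d`. This estimator converges for smooth bodies
  (digitized ball of radius 24: 0.6% error). The exact digital boundary-face
  count is also reported as a diagnostic; it is bias-free for digital
  geometry but overestimates smooth areas by the classical 3/2 factor.
* **Mean breadth** b̄(X): Crofton plane sweep — the sum over grid slices of
  the 2D Euler characteristic (8-connected squares, consistent with the 3D
  pair), averaged over the three axes. For convex bodies this integral equals
  the breadth in the sweep direction, so the ball-diameter normalization holds
  by construction: a digitized ball of radius r gives ≈ 2r + 1 (2% high at
  r = 24); axis-aligned boxes are exact. The raw integral of mean curvature,
  `M = 2π b̄`, is also emitted since the constant in "surface integral of mean
  curvature" is convention-dependent.
* **Euler number** χ(X): exact integer, from a 256-entry lookup table over
  2×2×2 voxel configurations. The table is derived programmatically from the
  closed cubical complex: each configuration window owns one lattice vertex,
  the three edges and three faces leaving it in positive directions, and one
  voxel; a cell is present when any incident voxel is foreground, and the
  window contributes its alternating cell count. For vessel networks with k
  connected components, L independent loops and no cavities, χ = k − L: loops
  (collaterals) lower the Euler number.

An independent oracle path — global vertex/edge/face/cube counts of the
complex, plus Betti numbers `(b0, b1, b2)` from exhaustive component labelling
on small grids — never touches the lookup table and is used to verify
`χ = b0 − b1 + b2` on random volumes.

### Additivity

Minkowski functionals satisfy `V(A∪B) = V(A) + V(B) − V(A∩B)`. For *voxel*
set operations this identity cannot hold exactly for any non-trivial
configuration-count functional: a valuation on the Boolean lattice of
configurations that is modular for all pairs is necessarily linear in the
bits, i.e. can only measure volume (concrete failure: two face-adjacent
voxels, where the voxel-wise A∩B is empty but the polyhedral intersection is
the shared face). The identity is a statement about the *bodies*: A∩B must
retain shared lower-dimensional faces. `mf_additivity_check` therefore forms
union and intersection on the cubical cell complexes and evaluates the four
functionals as per-cell-type valuations (the exact intrinsic volumes of the
polyhedron, with surface = boundary-face area and V₁-based mean breadth).
In that setting euler and volume residuals are integer identities (exactly 0)
and surface/mean-breadth residuals are exact rational valuations evaluated in
floats (< 1e-9). The smooth-convergent Crofton estimators inherit additivity
only approximately; this is a property of all such estimators, not of this
implementation.

## Segmentation: the adaptive structure filter

Vessels are bright tubes. At scale σ (µm), the Hessian of the
Gaussian-smoothed intensity is computed with per-axis σ/spacing so that
anisotropic stacks (e.g. 1 µm sections vs 0.44 µm pixels) are not smeared in
z, normalized by σ², and corrected for the small nonzero DC gain of truncated
second-derivative kernels (so a constant image has an exactly zero Hessian
and the operator is exactly linear in the intensity — this is what makes the
whole pipeline equivariant to affine intensity rescaling). Eigenvalues
ordered |λ1| ≤ |λ2| ≤ |λ3| feed a Frangi-type vesselness

    V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2γ²)),

zero where λ2 > 0 or λ3 > 0, with R_A = |λ2|/|λ3|, R_B = |λ1|/√|λ2λ3| and S
the Frobenius norm. Defaults α = β = 0.5; γ defaults to half the maximum of S
over the stack.

The *adaptive* filter runs several calibres and keeps, at each voxel, the
maximum of log(ε + V) across scales (ε = 1e−6), rescaled to [0, 1]. The scale
ladder defaults to five log-spaced σ from 0.5× to 2× the mean vessel radius,
which is bootstrapped from the data: a provisional intensity segmentation
(Otsu on the lightly smoothed stack) is fed to the local-thickness analysis
and its mean calibre sets the ladder centre.

Binarisation is Otsu's criterion on the nonzero combined scores (after
clipping the 0.5/99.9 percentile tails), or a fixed threshold. Cleaning then
performs outlier elimination in voxel values and in cluster sizes: voxels
whose smoothed raw intensity falls below the midpoint of two robust levels —
the median intensity of the top-scoring 5% of the mask (the vessel plateau)
and the median intensity outside the mask (background) — are removed; for a
symmetric point-spread function that midpoint isophote is where the true
boundary lies. Finally, 26-connected components smaller than
`min_cluster_voxels` (default 64) are dropped.

## Local thickness

Each foreground voxel receives the diameter of the largest inscribed sphere
containing it (the maximal-sphere definition used in trabecular-bone
morphometry): exact Euclidean distance transform, removal of spheres strictly
enclosed by a neighbour's sphere (`|y−z| ≤ ρ_z − ρ_y`, an exact pruning), and
max-painting of the survivors. Digital conventions: sphere radius = EDT value
(distance to the nearest background voxel centre), a sphere covers voxels
strictly closer than its radius, and the recorded diameter is 2ρ − 1 so an
isolated voxel has thickness 1. Anisotropic volumes are first resampled
(nearest neighbour) to an isotropic grid at the finest spacing, since
inscribed spheres are ill-defined on anisotropic lattices; this is recorded
in the map metadata. Thickness statistics (mean, SD over foreground voxels)
summarize the calibre distribution and drive the segmentation scale ladder.

## Dilation signatures and features

The vessel set is inflated by thresholding its exact Euclidean distance
transform at radii r = 0, 1, …, R (voxel units of the x–y plane; R defaults
to ⌈3 × mean vessel radius⌉ capped at 25). The four functionals evaluated on
each dilate give four signature curves. Ten features summarize each curve
(population variance and SD, mean, median, max and its abscissa, min and its
abscissa, maximum forward difference Δy/Δr and the left abscissa of that
interval; ties break toward the smallest abscissa), named
`{vol, surf_area, mean_breadth, euler3D}_{var, std, mean, median, max,
maxScale, min, minScale, dmax, dmaxScale}` — 40 features per sample. When a
sample comprises several fields of view, the per-volume feature vectors are
averaged (additivity of the functionals makes such averages well defined);
SD is re-derived from the averaged variance so std² = var holds. For joint
reporting, volume/surface/mean-breadth curves are normalized by the global
maximum across the collection and Euler curves are affinely mapped by the
global range onto [0, 1]; both maps are exactly invertible.

## Synthetic phantoms

The generator provides ground truth for every stage. Networks are built from
tubes (open, sinusoidally perturbed centrelines; the tortuosity parameter is
the perturbation amplitude in voxels) and welded ring chains: a component
with ℓ loops is a chain of ℓ rings whose consecutive circles cross at exactly
one point (centres 2R apart, alternating normal axes, the tortuosity sinusoid
phased to vanish at the weld points), so the tubes merge in one contractible
blob with overlap ≥ 2 voxels and χ = 1 − ℓ independently of the connectivity
convention. Disjoint components are separated by at least 2·max radius + 3
voxels, so dilation merge radii are predictable. All randomness flows from a
single integer seed through `numpy` seed-sequence spawning.

Rendering emulates confocal degradation: anisotropic Gaussian blur
(default PSF σ = (1, 1, 2) voxels, mimicking ~1 µm optical sections),
additive Gaussian noise, impulse speckle, and a constant-plus-z-gradient
background standing in for tissue autofluorescence (which rises with specimen
age in real material). The *standard recovery phantom* is a 2-component,
1-loop network of radius-4 tubes (≈ 8 µm capillary calibre at ~1 µm
sampling) in an 80³ grid, rendered at SNR 5 (signal 100, noise SD 20). The
segmentation pipeline achieves Dice ≈ 0.93 against ground truth there and
≈ 0.997 on degradation-free renderings. What the phantoms do *not* emulate:
realistic PSF side lobes, depth-dependent attenuation, staining
heterogeneity, vessel calibre tapering, or true angiogenic branching
topology — so passing recovery tests bounds algorithmic error, not
biological fidelity.

The cohort generator maps age to network parameters; the default effect model
encodes loop density and tortuosity rising after ~60 years and calibre
dipping mid-life, the qualitative pattern the morphometry is meant to
detect. Problem sizes in the test suite (80³ volumes, cohorts of 12–30,
signatures to r ≈ 6–25) are chosen so the whole suite completes on a single
CPU in minutes while every stage still runs end to end.

## Cohort statistics

Features are z-scored with sample SD (n−1). PCA is an eigen-decomposition of
the z-scored feature covariance (full SVD), with the sign convention that
each component's largest-magnitude loading is positive. Ages are binned into
six half-open groups [5,45), [45,55), [55,70), [70,75), [75,80), [80,85).
Pairwise one-way ANOVA is computed per feature per group pair with Bonferroni
correction over the whole family of feature × pair tests in one call (the
correction family is a declared choice).

Stepwise regression of age on the 40 features is the classical
forward–backward procedure on partial-F p-values (p-enter 0.05, p-remove
0.1), capped at 2 × n_features iterations, with cycle detection that keeps
the better-fitting of the cycling models. Regression analyses restrict to
samples aged ≥ 40 by default (the near-linear range); configurable. The
bootstrap wrapper draws subjects with replacement (default 3000 resamples,
repeated 6 times with counter-split seeds), runs stepwise on each resample,
and tallies selection frequencies over the "conservative" models with 2–4
selected features; it reports per-feature frequency mean ± SD across repeats,
model-size quartiles over all resamples, r² mean ± SE and median F over the
filtered models, and each feature's median partial p-value where selected.
Degenerate resamples (constant response or all-constant design) are skipped
and counted. The OLS core is a direct numpy/scipy implementation (needed for
~10⁵ fits per analysis); its final-model statistics are verified against
`statsmodels` in the test suite.

Two behaviours of classical stepwise selection worth knowing: under a pure
null (independent features), the expected number of selected features is
close to p_enter × n_features (≈ 2 of 40), and with a very strong planted
signal the procedure reliably enters the true features first but often admits
one additional spurious term — exact-set recovery is not a property of the
classical procedure at n ≈ 52.

## Numerical choices and degenerate inputs

* Otsu binarisation refuses all-equal score fields (suggesting a fixed
  threshold); empty cleaning results are allowed with a warning.
* The empty volume has functionals (0, 0, 0, 0); the empty-foreground EDT is
  +∞ everywhere with a warning; thickness of an empty mask is an error.
* Feature extraction requires signatures of length ≥ 2 (the derivative is
  undefined on shorter ones); ties in extrema and derivative maxima break
  toward the smallest abscissa.
* All statistics are deterministic given (data, seed); per-repeat and
  per-sample seeds are split with `numpy.random.SeedSequence` spawning, so
  results are independent of execution order.

## Known limitations

* The Crofton surface estimator is biased low by ~1% at capillary-scale
  digitization; the face-count diagnostic brackets it from above.
* The 3-direction plane-sweep mean breadth is exact for boxes and ~2% high
  for balls but can be several percent low for strongly curved bodies
  (e.g. tori); adding diagonal sweep planes would reduce this at cost.
* Local thickness is computed on isotropically resampled grids; diameters are
  reported in units of the resampled voxel.
* The segmentation value-outlier rule assumes one dominant vessel plateau;
  stacks with strong depth-dependent attenuation would need per-slab levels.
* Per-sample feature averaging across fields of view is an unweighted mean;
  the features themselves are nonlinear in the functionals, so averaging
  features is not identical to features of stitched volumes (both modes are
  supported).
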