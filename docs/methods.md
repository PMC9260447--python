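# Methods

This note records the model, the defaults, and the choices made where the
design was genuinely open, in enough detail to reproduce or audit any
number the package computes.

## Reconstruction

**Smoothing.** Gaussian, with one physical `sigma_nm` converted to
per-axis voxel sigmas `(σ/dz, σ/dy, σ/dx)` so the kernel is isotropic in
nm despite anisotropic voxels. Default σ = one in-plane voxel (7 nm at
7×7×30). Boundaries are reflective, so total intensity is conserved away
from the border.

**Signal isolation.** Intensities are first reoriented so that high
always means more chromatin (dark-is-signal stacks are inverted as
`v' = max_scale − v`; 16-bit by default, 8-bit input upcast without
rescaling because the 24000/30000 exceedance thresholds are absolute).
The default threshold is a **3-class Otsu whose lowest cut must clear a
robust background ceiling** (median + 5·1.4826·MAD of the smoothed,
reoriented stack). The rationale: the downstream model posits two
chromatin populations, so a stack may legitimately contain background
plus one *or* two foreground intensity modes. A plain 2-class Otsu on a
two-population stack can place its cut *between* the dim and the bright
population and silently discard every dim (open) domain; a 3-class Otsu
on a single-population stack wastes its extra class splitting the
background noise, and its lowest cut then sits inside the background.
Requiring the cut to clear the background ceiling handles both regimes
with no tuning. A forced 2-class `otsu` and a `fixed` threshold remain
available; a uniform image is rejected as degenerate.

**Interpolation.** The z-axis is resampled by linear interpolation to
approximately the in-plane spacing *before* re-binarization, and the mask
is re-cut at the same threshold; interpolating intensities rather than a
binary mask avoids stair-step artifacts that would bias surface area and
sphericity. Output slice count is `round((nz−1)·dz/dx) + 1` over the same
physical extent, so the realized z-spacing deviates from `dx` by at most
`dx / (2(nz_out−1))`. Square in-plane pixels with `dz ≥ dx` are required.

**Segmentation.** 26-connected components of the foreground mask,
minimum size 30 interpolated voxels, ordered by decreasing voxel count
with ties broken by the lexicographically smallest (z, y, x) voxel, ids
1…K. An optional distance-transform watershed (seeds = local maxima at
min separation 3 voxels) is available for dense fields where many domains
touch; it is off by default because probe-based stacks contain few,
well-separated domains. Domain intensities are carried on the **original
(un-inverted) scale** — the inverted copy exists only for thresholding —
because the intensity metrics are interpreted on the raw scale of each
technology.

## Features

19 candidate metrics per domain: 8 shape, 11 intensity; the two
exceedance percentages are omitted for bright-is-signal data (17).

* **SPEI-3D (white EI, black EI, SP).** White = domain voxel count. The
  domain's voxel centers are enclosed in their *exact* minimum enclosing
  sphere (Welzl's algorithm on the convex-hull vertices; deterministic),
  and the sphere in its axis-aligned circumscribing cube of side 2R. The
  cube is rasterized symmetrically about the sphere center with
  `2·ceil(R/s)` voxels per axis — the side is rounded up to whole voxels,
  i.e. padded by at most half a voxel per side — and black = cube count −
  white, SP = white/(white+black). A single voxel degenerates to region =
  1, SP = 1. Under this discretization a digital ball approaches π/6 ≈
  0.524 and a solid cube 1/(3√3) ≈ 0.192, matching the continuous
  definition. SP is exactly scale-invariant (computed in voxel units).
* **Eigenvalues.** Descending eigenvalues of the unweighted covariance of
  voxel centers in nm (population covariance), reported in nm². They are
  axis-length *proxies*: for a uniform ellipsoid they scale as a²/5, so
  semi-axes (40, 20, 10) give ratios 16:4:1. < 2 voxels → (0, 0, 0).
* **Surface area.** Area of the 0.5-level marching-cubes surface of the
  zero-padded binary mask, scaled by s². The mask is pre-filtered with a
  Gaussian of σ = 0.6 voxels before triangulation: the raw binary level
  set is blocky and overestimates a smooth solid's area by ~9%, while the
  filtered surface is within ~1% for a digital ball and −5% for a cube.
  Thin objects whose filtered maximum falls below 0.5 fall back to the
  unfiltered mask so the surface always exists.
* **Sphericity.** Wadell's Ψ = π^⅓(6V)^⅔/A with V = voxel count · s³ and
  A as above. 1 for a sphere; (π/6)^⅓ ≈ 0.806 for a cube in the
  continuum. Discretization note: small cubes read high (side 15 → ~0.86)
  because corner rounding shrinks A faster than V; the bias decays with
  size (side 30 → 0.83).
* **Intensity statistics.** Computed on the domain's own (original-scale)
  voxels only — background never enters. Quartiles use linear
  interpolation between order statistics (the common "type 7" rule); SD
  is the sample (n−1) estimator; skewness is Fisher–Pearson g₁ and
  kurtosis excess g₂ (both biased-moment versions, both defined as 0 for
  constant or single-voxel domains); exceedance percentages use strict
  `>` against 24000 and 30000 on the 16-bit scale, in [0, 100].

## State assignment

Per feature and batch, z-scores with the sample SD; features with zero
variance in any batch are dropped identically across batches with a
warning (their z-score is undefined). k-means (k = 2, k-means++
initialization, 10 restarts, seeded) runs independently per batch on the
normalized features; clusters are renumbered by first occurrence so the
labels do not depend on initialization. With m₁, m₂ the means of the
Mean-intensity metric (original units) over clusters 1 and 2:
bright-is-signal → the higher-mean cluster is closed; dark-is-signal →
the lower-mean cluster is closed; in either convention an exact tie sends
cluster 1 to open. This makes the final A/B labels
initialization-invariant and enforces, by construction, that closed
domains carry more material on each technology's own scale.

## Penalized selection and the final model

The training split is stratified by state (70/30 by default, seeded;
per-state counts preserved to within one domain; a singleton state goes
to training). The L1 logistic path uses 100 λ values log-spaced from
λ_max = max|Xᵀ(y − ȳ)|/n (the smallest penalty that zeroes every
coefficient on the standardized predictors) down to 10⁻⁴ λ_max. Features
are standardized internally for the penalty only; coefficients are mapped
back to original units. Per-λ fits use liblinear coordinate descent with
a large intercept scaling so the intercept is effectively unpenalized.
K-fold CV (stratified, seeded; folds capped at the minority-class count
with a warning) scores held-out binomial deviance; λ_1se is the largest λ
whose mean deviance is within one standard error of the minimum. An empty
selection at the chosen λ warns and falls back to λ_min. A `fixed` λ
policy reuses a supplied value, e.g. to carry one dataset's choice over
to another; λ = 0 is accepted as the unpenalized limit.

The final model is an unpenalized maximum-likelihood logistic regression
(closed = 1) on the selected features in original units, giving
coefficients, standard errors and Wald z. Perfect separation is
tolerated: the fit is iteration-capped (100 Newton steps); if it fails or
does not converge, coefficients come from a near-unpenalized fit and
standard errors from the ridge-stabilized (1e−8) Fisher information, and
`z_reliable` is flagged False — coefficients are reported, importance is
then qualitative. Variable importance is |z|, relative VI divides by the
maximum (degenerate all-zero z reports relative VI 1 everywhere).
Accuracy uses the 0.5 probability cutoff with an exact Clopper–Pearson
95% CI (the binomial-beta identity; the CI method is a package choice).

**Bootstrap stability.** Each resample (with replacement) is reclustered
per batch with k = 2; labels are matched to the reference per batch over
both pairings (exhaustive for k = 2); Jaccard index (per-cluster IoU
averaged over the two clusters), accuracy and balanced accuracy are
pooled over the resampled rows. Degenerate resamples (a batch reduced to
one distinct row) count as trivially stable.

## Synthetic data

The generator plants the contrasts the two states are defined by, in
physical units so the same population can be imaged at different batch
resolutions. Blobs are randomly rotated prolate ellipsoids (volume-
preserving axes r·e^⅔, r/e^⅓, r/e^⅓); "open" sparsity is Bernoulli
thinning of the interior (the center voxel always survives). Defaults:
closed r = 28–48 nm, elongation 1.8–2.4, fill 1.0, material intensity
32000 ± 4000; open r = 22–42 nm, elongation 1.0–1.2, fill 0.6,
18000 ± 4000; background 2000; additive Gaussian noise with SD 2% of the
16-bit range, clipped. Two batches mimic the two probe-based acquisition
rounds (voxels 30×7×7 and 30×5×5 nm) and batch 2 additionally receives a
gain 0.9 / offset 3000 distortion of the written intensities; for
dark-is-signal output the material image is inverted at write time.
Stacks are 14×64×64 with two blobs each, centers at least 8 voxels of
clearance beyond the sum of bounding radii (at the background-level
threshold, smoothing halos of blobs only 4 voxels apart can bridge into
one component); unplaceable draws are retried with fresh blobs before
the spec is declared overcrowded.

What the generator does *not* emulate: optics (no PSF, no depth-dependent
blur), chromatin polymer structure, intensity inhomogeneity within a
domain beyond iid noise, touching domains, or partial-volume effects.
Passing the recovery checks therefore shows the chain is correct and
batch-robust under its own assumptions, not that it meets any particular
accuracy on real microscope data. Two consequences worth knowing: the
24000/30000 exceedance metrics are near-constant under the default
intensity populations and are dropped by the zero-variance rule during
normalization (the mechanism, not the metrics, is what is being
exercised); and separation of the final logistic fit is common because
the planted clusters are cleanly separable, which is exactly the regime
the separation handling exists for.

## Reported experiments

`scripts/acceptance.py` (and the heavier tests) use: a 10-seed (tests) or
5-seed (script) recovery experiment at the default conditions — 200 open
+ 200 closed domains per seed, two batches — scoring the validation split
against both the unsupervised states and the planted kinds; a 20-seed
(tests) or 10-seed (script) selection study with 2 informative features
(2 SD effect) among 17 noise columns at n = 400; analytic solids (digital
ball r = 10, cubes of side 15–30, an ellipsoid with 40/20/10 nm
semi-axes); and 50 bootstrap resamples for stability. These sizes keep
the whole suite around seven minutes on one CPU while leaving the
acceptance margins visible.

## Known limitations

* The exceedance thresholds (24000/30000) presuppose a 16-bit intensity
  calibration; their provenance on other instruments is unknown.
* Only the z-axis is interpolated; in-plane anisotropy (dy ≠ dx) is
  rejected rather than resampled.
* Connected components cannot split touching domains; the watershed
  option exists but is unvalidated against dense real fields.
* Eigenvalues are covariance eigenvalues (nm²), not fitted-ellipsoid
  axis lengths; only relative comparisons are meaningful across sizes.
* The bootstrap stability statistic treats a resample's duplicated rows
  as independent, as bootstrap reclustering conventionally does.
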