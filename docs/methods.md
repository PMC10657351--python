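# Methods

This note documents the models, estimators, numerical choices and known
limitations of `winggrad`, and what the synthetic-data generator does and
does not emulate.

## Morphometry

A wing scan is consumed as a bare vertex list (faces and normals are
ignored). Alignment is rigid only: the principal axes of the spatial
covariance are mapped to (X, Y, Z) in decreasing-variance order, with two
sign conventions resolved from the geometry — the wing tip (the spanwise
half with the smaller chordwise spread) points to +X, and the camber arch
opens downward in Z (mid-chord surface above the chord edges). The third
axis follows from right-handedness; leading vs trailing edge cannot be
resolved from geometry alone and is not needed by any measurement. Clouds
whose second principal variance vanishes (collinear points) are rejected.

The wrist position is a required per-scan annotation, not auto-detected:
wing thickness tapers monotonically through the wrist, so there is no
robust landmark-free detector.

Slices are half-open spanwise bins [x, x+w), proximal edge inclusive, of
width w = (X_max − wrist_x)/25. Twenty-five handwing bins tile wrist to
tip (the tip point itself is kept in the last bin); armwing bins tile
wrist to base, keeping only bins that fit entirely; the single bin
adjacent to the joint is labelled WRIST (width configurable). The
standardized analysis grid is 10 AW + 25 HW slices with the wrist
excluded; wrist-inclusion policies (`to_HW`, `to_AW`) reassign that one
column and change the module sizes to (26, 10) or (25, 11).

Per-slice traits, on the slice's Y/Z projection:

* chord = Y_max − Y_min, camber = (Z_max − Z_min)/chord, from slice-global
  extremes;
* XST (maximum thickness) and XSA (section area) from chordwise *station
  envelopes*: points are binned into up to 100 Y-stations (at least ~8
  points per station; the count adapts downward for sparse slices). A
  station whose z values split around a dominant gap (> 0.35 of the
  station extent) is treated as a thin shell and its surface positions are
  the two cluster means — this cancels the extent inflation caused by
  spanwise taper and camber sweep *within* the slice. Stations without
  such a gap (solid sections) fall back to the raw extremes, debiased by
  the uniform-range factor (k+1)/(k−1) when at least 8 points make the
  classification reliable. Stations that sampled only one surface by
  chance (extent collapsing far below both neighbours) are repaired by
  interpolation. XST is the maximum of the extent profile after a
  15-station moving average (suppressing the upward bias of a max over
  per-station noise); XSA is the trapezoidal integral of the extent over
  the sampled chord. A shapely `concave_hull` area estimator is available
  (`xsa_method="hull"`) but the station perimeter is the default: concave
  hulls collapse or bridge the camber arch on thin shell-like sections.

Because traits are slice-aggregated functionals, the generator's ground
truth is defined the same way: chord/camber as extremes over the slice's
spanwise extent, XST/XSA from the mean surfaces across the slice,
evaluated on dense grids of the exact parametric surface. At ≥ 500 points
per slice the estimators recover chord, camber and XST within 2% and XSA
within 5% of that truth; accuracy degrades roughly with 1/√(points per
station) below that.

Mass scaling is isometric: lengths ÷ M_b^(1/3), areas ÷ M_b^(2/3), camber
dimensionless; scaling round-trips exactly. Species summaries are medians
over specimens per slice. Missing body mass can be filled from a
two-column species-mean table.

## Evolutionary models

All fits are maximum likelihood with the rate divisor n (a `ddof=1`
switch gives n−1). For tip values x on a tree with unit-rate structure
matrix V₀(θ), the root state and rate are profiled analytically,

  ẑ₀ = (1ᵀV₀⁻¹1)⁻¹1ᵀV₀⁻¹x,  σ̂² = (x−ẑ₀)ᵀV₀⁻¹(x−ẑ₀)/n,

and the remaining shape parameter is optimized on the profile likelihood:
OU pull α on [0, 50/depth], EB decay r on [−10/depth, 0], via a coarse
candidate scan (multi-starts {1e−4, 1e−2, 1, 10}/depth plus the bounds)
followed by bounded Brent (xatol 1e−8 relative). The OU covariance is the
fixed-root nonstationary form; both OU and EB collapse to BM as α, |r| → 0
(verified to 1e−6). Likelihoods go through Cholesky factorizations;
constant data trigger a documented σ² floor (1e−300) with a `degenerate`
flag rather than an infinite likelihood. Polytomies are resolved to
zero-length branches before covariance construction. AICc uses
−2ℓ + 2k + 2k(k+1)/(n−k−1) with k = 2 (BM) or 3 (OU, EB); ties below 1e−6
go to the model with fewer parameters.

Pagel's λ scales the off-diagonal of C; the ML search first evaluates a
41-point grid on [0, λ_max] — the profile can fall off a cliff where
C(λ) approaches singularity, which traps a bare bounded search — then
refines with Brent inside the bracketing interval. λ_max is
max(diag C)/max(offdiag C), shrunk finely (×0.9995) if that matrix is not
positive definite. Blomberg's K uses the GLS-mean-centred variance ratio
against its Brownian expectation and equals 1 exactly on star trees.

Per-slice σ² profiles fit all three models per slice and report the rate
under the AICc-best one (`model_policy="best-aicc"`, default) or under a
forced common model. Note that σ² is not comparable across slices whose
best models differ in α; with the study-like designs used here the best
model is stable across slices.

Known limitation: the ML shape parameters carry finite-sample bias — at
128 tips, α is overestimated by ~12% and |r| underestimated by ~11% on
average (shrinking to ~4% at 384 tips); σ̂² itself is accurate to a few
percent. The likelihood surface, not the optimizer, is responsible: the
implementation matches brute-force density evaluation and independent
reference implementations to numerical precision.

## Modularity and disparity

The covariance ratio uses the unbiased sample covariance of species
values, Frobenius norms, and within-module blocks with zeroed diagonals;
no phylogenetic correction is applied (the test addresses morphological,
not evolutionary, modularity). The permutation null reassigns variables
to modules of the same sizes; p = (1 + #{CR_perm ≤ CR_obs})/(1 + n_perm),
the add-one convention avoiding p = 0. Because the four traits differ
strongly in mean between regions, the test defaults to log10-transformed
data; CR is scale-invariant but not invariant to the log transform
precisely when module means differ, which is the motivation for it.

Disparity per slice is the sample variance of species values (default) or
the median absolute deviation from the mean (`median_dist_centroid`);
both are reported by name since published disparity profiles do not pin
the metric.

All spanwise statistics (σ², disparity, K, λ) default to
log10-transformed traits. The traits are positive and vary
multiplicatively — chord spans an order of magnitude across species and
thickness decays several-fold along the span — and the magnitudes of
published per-slice disparity and rate values for such data are
unit-consistent only on the log scale. `analysis_log10=False` restores
raw-scale fits.

## Regression discontinuity

The RDA is the sharp-design global linear model
y = β₀ + β₁(x−c) + δD + β₂D(x−c), D = 1[x ≥ c], fitted by OLS
(statsmodels); δ is the intercept step at the wrist cutoff (slice index
10.5 on the 1..35 grid, the wrist bin itself excluded) and the reported
effect p is its two-sided t-test. β₂ (slope change) is reported alongside.
A bandwidth argument restricts the fit to a window around the cutoff
(local-linear variant). On exactly piecewise-linear data the fit is exact
and residual variance vanishes; the degenerate t-statistic is resolved to
p = 0 for a nonzero step and p = 1 otherwise. No multiple-testing
correction is applied across traits or statistics.

Calibration, measured over 500 replicates at 35 slices: type-I error
0.03–0.06 at α = 0.05 under linear or rate-profile-shaped smooth
gradients; power 1.0 with an unambiguous step (5× the residual SD) and a
mean estimate within 2% of truth. Two caveats are inherent to the design:
power at a step of exactly 2× the residual SD is ~0.75 (the intercept
extrapolation at the cutoff costs efficiency), and strong curvature
relative to noise inflates the false-step rate, since a linear fit cannot
absorb it — profiles analysed here are smooth at the relevant scale.

Robustness scans rerun the σ²/disparity profiles over clade subsets,
random taxon removals (each removal count drawn without replacement,
pool restored between draws; floor of 3 retained species, 6 in practice),
and tree samples (median ± MAD per slice). Disparity is tree-free and
therefore exempt from the tree scan.

## Mechanical sensitivity

The blade-element strip model: section force ∝ c(r)·r²·dr and section
inertial moment ∝ m(r)·r²·dr, so the per-area force and moment go as r²
— chord taper cancels from the per-area law (asserted symbolically on
discrete grids). The exponent is exposed for sensitivity analysis. The
module emits the two qualitative rate templates (smooth gradient;
two-level step at the wrist) for overlay against fitted profiles; no
amplitude link is claimed.

## Synthetic data

The generator emulates the study design end to end: a seeded pure-birth
tree rescaled to unit depth (~178 tips; dendropy's birth–death simulator
was avoided because it leaves the final cherry with zero-length branches
and a singular covariance), four traits over 10 AW + 25 HW slices,
~6 specimens per species, armwing fraction 0.45 of span (empirically
30–60%).

Species values evolve on the log10 scale: per slice, tips are
MVN(μ(s)·1, σ²(s)·C_model) with a smoothstep spanwise mean trend (camber
0.14 → 0.09, chord 20 → 13 mm·g^(−1/3), XST 2.0 → 0.7 mm·g^(−1/3), XSA
17 → 3 mm²·g^(−2/3)) and a quadratic base-to-tip rate ramp (per-trait
log10-σ² of ~0.015–0.04 at the base rising to ~0.05–0.12 at the tip,
sized so the OU stationary variance σ²/(2α) at α = 2 matches realistic
among-species spreads). Across slices the standardized innovations share
an AR(1) correlation (length 5 slices) so profiles are spanwise-smooth
without changing any slice's marginal; the innovation correlation is
attenuated once (×0.5) across the wrist, giving the two regions genuinely
modular covariance. An optional multiplicative rate step at the wrist
turns the smooth-gradient world into the modular-rates world. Specimen
noise is Gaussian with sd 2% of the trait value (median-of-6 standard
error ≈ 1%, in line with careful scan-derived morphometrics); species
medians are taken before analysis. Trait tables are written on the raw
(exponentiated) scale.

The parametric wing surface is a shell of vertical thickness t(x) around
a parabolic camber arc z = 4h(x)(y/c)(1−y/c), with linear chord and
thickness taper; points sample the planform uniformly and land on either
surface. Ground-truth functionals are computed from the surface as
described under Morphometry.

What the generator does **not** emulate: scan artefacts (holes,
registration error, feather-level texture), non-Gaussian specimen
variation, correlated measurement error across slices, empirical
mass–span allometry, and clade-specific rate regimes beyond the optional
two-clade scalar used in tests. Passing tests therefore certify the
estimators and the pipeline plumbing under the stated statistical
conditions, not robustness to raw-scan pathology.

## Determinism

Every stochastic component takes a seed; study generation is
byte-reproducible, permutation tests and scans reproduce exactly under a
fixed seed, and the pipeline writes a manifest recording config, seeds and
library versions. Per-slice fits are independent, so any parallel
execution must aggregate in slice order to preserve identical output.
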