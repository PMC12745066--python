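# Methods

This note documents the models and procedures implemented in `paleogm`,
the numerical choices behind them, what the synthetic data generator does
and does not emulate, and the package's known limitations.

## Superimposition

Shape analysis begins by removing position, size and orientation.
Centroid size (CS) is the square root of the summed squared distances of
the landmarks from their centroid; it is the size proxy throughout (e.g.
for the tooth- and talus-size box plots, and for scaling outlines to unit
CS before analysis).

**Ordinary Procrustes (OPA)** superimposes one configuration on another:
both are centred and scaled to unit CS, then the rotation minimizing the
residual Frobenius norm is obtained from the SVD of the cross-product
matrix (Kabsch), with the determinant constrained to +1 unless a
reflection is explicitly allowed. The Procrustes distance reported is the
residual norm of this *partial* fit, 2·sin(ρ/2) in terms of the
Procrustes angle ρ; no post-hoc rescaling by cos ρ is applied. The choice
of partial over full Procrustes is a convention; at the small shape
distances typical of congeneric comparisons the two are nearly
indistinguishable, and the partial fit keeps "translated, scaled, rotated"
literally true of the output.

**Generalized Procrustes (GPA)** alternates two exact minimization steps —
rotate every configuration onto the current mean, recompute the mean —
so the least-squares criterion Σᵢ‖xᵢ − x̄‖² is non-increasing by
construction; iteration stops when it changes by less than `tol`
(default 1e−10, `max_iter` 100). Because the consensus of a GPA is only
defined up to rotation, the fitted consensus is afterwards rotated into
its principal-axes frame with a deterministic sign rule (largest-magnitude
coordinate of each axis positive, determinant forced to +1 by flipping the
last axis if needed). This makes results reproducible and rigid-motion
invariant to ~1e−8 across platforms, which the test suite checks
explicitly. Reflections are never applied inside GPA; right-side
specimens are mirrored to left antimeres beforehand by negating the x
coordinate (an involution that also flips the side label).

Query specimens (e.g. a fossil completed on a reference mean) are *not*
refitted into the sample: `GPA.transform` centres, rescales and
OPA-rotates them onto the frozen consensus, and `ShapePCA.transform`
projects them onto the frozen axes. This mirrors how single fossils are
placed into an existing comparative shape space without perturbing it.

## Thin-plate splines and sliding

The TPS is the minimum-bending-energy interpolant between paired landmark
sets. Kernels are U(r) = r²·log r² in 2D and −r in 3D; both are
conditionally positive definite of the required order, so the bending
energy quadratic form tr(YᵀBY) (B = upper-left block of the inverted
Bookstein system) is non-negative and vanishes exactly on affine maps.
Coincident source landmarks (within 1e−12) and collinear/coplanar source
configurations are rejected as degenerate.

Semilandmark sliding minimizes, per specimen, the bending energy of the
deformation from the consensus, with displacements constrained to the
estimated tangent (curve points: central difference of the template's
neighbour indices) or tangent plane (surface points: top two local-PCA
axes of the 6 nearest neighbours). The constrained minimization is a
single linear solve, so the per-pass objective can only decrease — a
property the tests assert on every tested pass. Three passes are run by
default, re-superimposing and updating the consensus between passes
(recursive updating). There is no projection back onto a mesh: meshes are
outside the package's scope, and for the dense templates this scheme
emulates, tangent-space sliding is the standard approximation.

## Crown outlines

For the 2D molar analysis the cervical curve receives a total
least-squares plane (smallest singular vector of the centred points); the
crown is rigidly moved so this plane is the xy-plane and a user-supplied
lingual direction is parallel to the x-axis, leaving the buccal side
towards +y. There is no operational rule for deriving the lingual
direction from geometry alone, so it is digitized metadata. The outline —
supplied as an explicit closed polygon; silhouette extraction from meshes
is out of scope — is centred on its *area* centroid (shoelace/Green's
theorem, via shapely) and sampled by 24 rays at 15° steps starting from
the buccal +y ray, sweeping clockwise for a left tooth so that the mesial
side follows the buccal ray. Rays must cross the boundary exactly once
(star-shaped polygon); violations raise an error naming the offending
ray. The resulting pseudolandmarks are centred and scaled to unit CS.
MD and BL crown diameters are the x- and y-extents of the oriented
outline's bounding box.

## Missing-landmark estimation

A damaged configuration is completed against a complete reference mean:
the reference is OPA-superimposed (with scaling) on the present landmarks,
a TPS is fitted from the aligned reference's present landmarks to the
specimen's, and the missing positions are the warp's values at the aligned
reference's missing-landmark positions. TPS estimation (rather than a
regression variant) is the geometric default and works with a single
reference mean; present landmarks are never modified. The estimate is
exact for affine deformations of the reference, and under isotropic noise
of sd σ the recovery RMS stays below 3σ (verified over 100 seeds).

The multi-reference sensitivity table completes a specimen against each
candidate reference (group means and the overall mean), projects every
completion into a fixed shape space, and reports pairwise PC1–3
distances. An important caveat the synthetic benchmark makes explicit:
when missing landmarks lie *on* the feature that separates the groups,
each reference pulls the reconstruction towards its own group, and the
spread across references grows to roughly 8–17% of the between-group mean
distance under the default study conditions (two groups separated by 6×
the landmark noise, n = 30/group, the 4-facet-points-plus-1-crack-point
knockout). With missing points away from the discriminating feature (the
2-point facet-style benchmark) the spread stays below ~5%. Robustness to
reference choice is therefore a property of *where* the damage sits, not
of the estimator alone — which is exactly why the sensitivity table is a
first-class output of the pipeline rather than an internal check.

## Shape spaces

`ShapePCA` is a covariance PCA (divisor n−1) of the vectorized Procrustes
coordinates, computed by SVD of the centred data matrix, with each axis
oriented so its largest-magnitude loading is positive (plots and scores
reproduce across runs and BLAS implementations). The scree "inflection
point" used to pick the number of PCs for the permutation and correlation
tests is operationalized as the interior position maximizing the discrete
second difference f(j−1) − 2f(j) + f(j+1) of the (descending) variance
fractions, smallest position on ties. Any elbow rule is a heuristic; this
one is deterministic, matches the intuitive elbow on well-behaved scree
plots, and degenerates gracefully (length-3 input returns the only
interior point).

`BetweenGroupPCA` runs the PCA on the g group mean vectors, equally
weighted regardless of group size, yielding at most g−1 axes (exactly 3
for four groups) onto which all specimens and queries are projected. Its
purpose is dimension reduction when the smallest group has fewer members
than the PCs a discriminant analysis would need.

## Inference

* **Permutation tests** on the first three PC scores: the statistic is the
  Euclidean distance between group mean score vectors (the permutation
  routine's statistic is configurable; this is the conventional default),
  labels are permuted within each pooled pair, N = 10,000 by default, and
  p = (#{permuted ≥ observed} + 1)/(N + 1), which bounds p below by
  1/(N+1). Holm's step-down correction (via statsmodels) adjusts across
  pairs. Permutations are vectorized and seeded.
* **Normality gate:** Shapiro–Wilk on each of the first three PCs within
  each group; any p < 0.05 routes the analysis to QDA, otherwise LDA —
  reproducing the convention of switching to the quadratic model exactly
  when the linear model's normality assumption fails.
* **Discriminant analysis:** sklearn's LDA/QDA with priors proportional
  to training group sizes (configurable), leave-one-out cross-validation
  for the reported accuracy and confusion matrix, and full-data refit for
  query posteriors (P_post, summing to 1). The PC count is the smallest k
  achieving the maximum LOO accuracy among those whose cumulative variance
  lies in [70%, 90%] (if the cumulative variance jumps over the window,
  the first k past 70% is used). For QDA the window is truncated to
  k ≤ min group n − 2 so every LOO training fold keeps a full-rank
  within-group covariance; candidates that are still singular are skipped.
* **Geography and chronology:** Pearson r (two-sided p) of each of the
  first three PCs against latitude and longitude separately within the
  Neanderthal sample, and per-PC one-way ANOVA across the two Marine
  Isotope Stage groups ("early" vs "classic") when Shapiro–Wilk accepts
  normality in both groups, Kruskal–Wallis otherwise. α = 0.05 throughout.

## Radiocarbon

Collagen screening: yield = 100·(collagen mg)/(sample mg), QC threshold
~1%; atomic C:N = (%C/%N)·(14.007/12.011), accepted in [2.9, 3.6] after
the standard collagen-quality literature. δ¹³C/δ¹⁵N are carried as
metadata without thresholds.

Calibration evaluates, on a 1-yr calendar grid spanning the curve, the
normal likelihood of the measured age with combined variance
σ² + σ_curve(θ)², normalizes under a uniform calendar prior, and extracts
highest-posterior-density sets at 68.2% and 95.4% by descending-density
accumulation (density ties at the cutoff are included, keeping symmetric
posteriors symmetric). Multi-modal posteriors report a union of
intervals; the printed-style rendering uses the overall min/max bounds,
as published ranges are single spans. cal BC = cal BP − 1950 (for ages
older than 1950 cal BP), cal AD = 1950 − cal BP otherwise. No reservoir
correction, no outlier model, single determinations only. Curve files
follow the IntCal `.14c` layout (`#` headers; columns cal BP, ¹⁴C age,
error; linear interpolation between knots). The public IntCal20 file is
not redistributed; tests and the acceptance script use it only if the
user places it at `data/intcal20.14c`, and otherwise exercise the engine
with synthetic curves whose Gaussian limits and coverage have closed-form
expectations.

## Synthetic data

The generator emulates the *structure* of comparative landmark samples:
per-group mean shapes (a unit-CS base plus named deformation vectors),
isotropic Gaussian landmark noise, size variation, random rigid motions,
group labels, and geographic/chronological metadata. Effect vectors are
projected into the shape tangent space at the base (orthogonal to
translation, scaling and rotation) and normalized, so the `effect_scale`
parameter *is* the realized Procrustes separation between group means —
without this, part of a nominal effect would be absorbed by the
superimposition and effect sizes would be systematically understated.

Two fixture templates ship as CSV: a 24-point molar-like crown outline (a
superellipse, half-axes 6.8 × 6.45 mm, exponent 3.5, whose disto-lingual
quadrant can bulge — echoing the protruding-hypocone contrast that
separates the real groups) and a 30-point talus-like 3D block (6 fixed
extremal points, a 12-point equatorial sliding curve, 12 surface points
on an ellipsoid, 28 × 22 × 16 mm half-axes). Defaults for the study
conditions: two to four groups, n = 8–30 per group, landmark noise sd
0.01 in shape units (≈1% of size, a realistic digitizing error), group
separation 0.06 (6× noise, which places groups at the edge of perfect
LOO separability — the interesting regime), sizes ~N(12, 1) mm.

What the generator does **not** emulate: anatomically realistic mean
shapes, spatially correlated digitizing error, allometry, asymmetry, or
observer effects. Passing tests therefore demonstrate the correctness and
calibration of the *procedures* (superimposition, estimation, inference)
under their stated assumptions, not the discriminability of real
Neanderthal vs *H. sapiens* samples, which depends on real covariance
structure the generator deliberately omits.

Simulated radiocarbon measurements draw age ~ N(μ(θ), √(σ_meas² + σ_curve²))
from a curve, enabling round-trip coverage checks (the 95.4% HPD covers
the true calendar age in 95% ± 2% of 1,000 replicates).

## Problem sizes and determinism

Test and acceptance runs use 24×2 and 30×3 templates, 16–60 specimens per
analysis (1,000 for the consensus-recovery and coverage checks), N = 1,000
permutations for the 200-replicate null-uniformity calibration and
N = 10,000 elsewhere — sizes chosen so the whole battery is a desk check
on one CPU while keeping every statistical assertion well-powered. All
stochastic steps take explicit seeds; identical seeds give bitwise
identical datasets and reports.

## Known limitations

* No mesh handling: outlines and landmarks must already be extracted;
  sliding has no surface re-projection step.
* Partial (not full) Procrustes; no weighted or robust GPA.
* TPS-based missing-data estimation only (no regression/mean-substitution
  variants yet).
* Single-determination calibration: no Bayesian sequence/phase models,
  marine or mixed curves, or F¹⁴C handling.
* The scree elbow and the 70–90% PC-selection window are deterministic
  operationalizations of visual conventions; near-flat spectra make any
  such rule arbitrary, and the window can legitimately be empty for QDA
  with very small groups (reported as an error with diagnostics).
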