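# Methods

`morphohead` implements a complete 3D soft-tissue craniofacial morphometrics
pipeline: dense, geometrically homologous landmark sets are produced by
thin-plate-spline (TPS) multi-point warping with sliding surface
semi-landmarks, superimposed by generalized Procrustes analysis (GPA), and
analysed with the standard shape-statistical battery (Procrustes ANOVA with
a digitization-error stratum, relative-warp PCA with parallel-analysis
retention, EDMA distance tables, allometric regression, MANOVA on allometric
trajectories, CVA and cross-validated discriminant classification).  Because
head-scan collections of this kind are license-restricted, the package ships
a synthetic head generator that reproduces the *structure* of such a study —
demographic cells, smooth group effects, individual variation, allometry,
re-digitization error — so every stage is exercised end-to-end at desk scale.

## Thin-plate splines in 3D

The warp `h: R^3 -> R^3` interpolating control points `P_i -> Q_i` minimizes
the integral of squared second derivatives (the bending energy) and
decomposes into a radial and an affine part:

    h(p) = Psi(p) K + [p, 1] Gamma,        Psi_w(p) = ||p - P_w||.

In 3D the biharmonic radial kernel is the plain Euclidean distance `U(r) = r`
(not the 2D `r^2 log r`).  Coefficients solve the bordered system with the
homogeneous control matrix `P` (M x 4):

    [ Psi - beta*I   P ] [ K     ]   [ Q ]
    [ P^T            0 ] [ Gamma ] = [ 0 ].

* At `beta = 0` (the default) the map interpolates exactly; the interpolation
  residual is at machine precision and tested at `1e-8` relative.
* The distance kernel is conditionally *negative* definite, so two sign
  conventions follow.  The bending energy is the negated quadratic form
  `-trace(K_xyz^T Psi K_xyz)` (non-negative on the subspace `P^T K = 0` the
  system enforces; zero exactly for affine maps), and the smoothing term
  enters as `-beta*I` — with `+beta*I` the energy is not monotone along the
  regularization path, which we verified numerically.
* Degenerate inputs are rejected, never repaired: duplicate controls within
  `1e-9` mm, fewer than 5 points, or a coplanar configuration (rank-deficient
  affine part) raise errors.

The energy of a full configuration `Y` relative to a fixed control
configuration `X` uses the bending-energy matrix `B`, the negated upper-left
block of the inverse bordered matrix of `X`: `E = sum_d Y_d^T B Y_d`.  `B`
annihilates affine configurations, so `E` is zero when `Y` is an affine image
of `X`.  Everything is closed-form; no quadrature.

## Template and sliding semi-landmarks

The template carries 20 anatomical anchor landmarks (standard facial points:
canthi, nasion, pronasale, cheilions, tragions, opisthocranion, vertex, …)
and by default 480 surface semi-landmarks.  Semi-landmarks are spread from
the pronasale — the most robust, expression-invariant facial point — by
drawing random surface candidates, growing the set by farthest-point
selection starting at the nose tip, and relaxing with a few tangent-plane
repulsion sweeps (re-projected onto the surface each sweep).  The result is
deterministic per seed, lies on the surface to `1e-6` mm, and keeps pairwise
spacing at least half the configured spacing radius (default 1.5 mm).  With
more than one semi-landmark the seed point is nudged one minimum spacing
along the surface so the combined 500-point configuration has no duplicate
(the anchor stays where it is); with exactly one it coincides with the
pronasale.

Transfer to a target head fits the TPS on the 20 anchor pairs only (the
anchors define the warping field), pushes the semi-landmarks through it, and
projects each onto the nearest point of the target triangulation
(point-to-triangle with barycentric clamping; a KD-tree over triangle
centroids prefilters candidates and a widened second pass guarantees
exactness, which tests verify against an independent brute-force oracle).
Points landing farther than 10x the spacing radius from the surface are
flagged in the log rather than silently accepted.

Sliding then minimizes the bending energy relative to the template over
tangent-plane displacements: per cycle, two orthonormal tangent vectors are
computed at each semi-landmark (from barycentrically interpolated
area-weighted vertex normals), and one dense symmetric solve yields the
energy-minimizing tangent coefficients — the classic minimum-bending-energy
semi-landmark formulation, linear because sliding happens along tangents
rather than on the curved surface itself.  Displacements are scaled by a
geometrically decaying step fraction (100% down to 5% over six cycles by
default; the endpoints are the method's convention, the geometric shape of
the decay is this package's choice) and the points are re-projected onto the
surface.  Because re-projection can raise the energy after a small tangent
step, each cycle backtracks (halving the step up to four times, keeping the
previous configuration as a last resort) so the energy trace is non-
increasing by construction.  Anchors never slide.  Convergence is by fixed
cycle count (six), matching the method's convention; sliding and transfer
are fully deterministic — only template generation consumes randomness.

Rigid motions are recovered exactly: on a rotated + translated copy of the
template, transfer is exact (affine maps lie in the TPS null space) and the
slid landmarks coincide with the rotated template to machine precision.

## Superimposition and shape space

GPA centers every configuration, scales it to unit centroid size
(`CS = sqrt(sum ||x_i - centroid||^2)`, the size measure used throughout),
and iteratively rotates to the consensus until the mean changes by less than
`1e-10` (at most 100 iterations), with a final pass that leaves each
specimen optimally rotated to the converged mean.  Rotations only — no
reflections, so anatomical left/right cannot flip.  The consensus is
initialized from the raw mean of the centered, scaled configurations (with a
fallback to the first specimen when random orientations cancel it out),
which makes GPA an exact fixed point on already-aligned input.  Full
Procrustes distance (unit size, optimal rotation) is the shape metric;
group-difference tests permute group labels and use the add-one p-value
`(b + 1)/(n_perm + 1)`, which can never be exactly zero.

Linear statistics operate on tangent-space coordinates: the orthogonal
projection of each aligned configuration's flattened coordinates onto the
complement of the consensus direction.  The shape-space dimension after
superimposition of K landmarks in 3D is `3K - 7` (3 translations, 3
rotations, 1 scale).

## The statistical battery

**Procrustes ANOVA.**  Sums of squared Procrustes deviations are partitioned
sequentially in the fixed hierarchical order ethnicity, sex, age, individual,
digitization error (replicate digitizations of the same head).  Main-effect
degrees of freedom are `(levels - 1) * (3K - 7)` — 53 for a two-level factor
on the 20 anchors, 212 for the five age classes, 1433 on the 480
semi-landmarks, 1493 on all 500 points.  F ratios follow the
measurement-error ladder: factor MS over individual MS, individual MS over
error MS.  Individual DF is `(n_individuals - 1 - sum(levels - 1)) * (3K-7)`
and error DF `(n_observations - n_individuals) * (3K - 7)`; conventions for
these two strata differ between morphometrics packages, so ours is stated
explicitly here.  The three
landmark partitions (anchors / semi-landmarks / all) are each superimposed
on their own before decomposition.

**PCA and retention.**  Relative warps are the principal components of the
tangent coordinates (SVD; component signs fixed so the largest-magnitude
loading is positive).  Retention uses parallel analysis: every coordinate
column is independently permuted across specimens (100 draws by default) and
components are kept while their eigenvalues exceed the 95th percentile of
the permuted eigenvalues of the same rank (leading-run convention).  A fixed
`retained_count` override exists for workflows that fix retention a priori
(note the rank bound N - 1 caps what is computable).  Note
that on GPA-aligned data parallel analysis legitimately retains a few
components even without biological signal — superimposition induces
correlations that column permutation destroys; the pure-noise calibration in
the tests therefore bypasses alignment.

**EDMA.**  Inter-anchor Euclidean distances on group mean *forms*: the
aligned group mean shape rescaled by the group's mean centroid size, so
distances are in mm and base-10 logs land near the conventional magnitudes
(log10 of a ~200 mm cranial length is ~2.3).  The named 12-distance
anthropometric battery (cranial, face, eye, nose, mouth, chin regions) and
the full 190-pair set are both available.

**Allometry.**  Multivariate regression of tangent coordinates on centroid
size (not log-transformed, following the source convention); percent
predicted is predicted SS over total SS, significance by permuting sizes
against shapes (vectorized, 10,000 permutations by default).  Pooled
within-group regression estimates a common slope on group-centered data and
returns size-corrected shapes (residuals plus group means).

**MANOVA on trajectories.**  On retained PC scores: the full model
group + CS + group x CS tests slope differences via Wilks' lambda of the
interaction; the reduced model without the interaction tests intercepts via
the group effect.  Wilks is converted to F with Rao's approximation (exact
for <= 2 groups or <= 2 variables).  The score count defaults to the 99.98%
cumulative-variance cutoff, capped so residual degrees of freedom stay
positive.

**CVA / DA.**  CVA solves the generalized eigenproblem of between- versus
pooled within-group scatter (at most groups - 1 axes), reducing by PCA to
the within-scatter rank when singular.  Classification is a pooled-covariance
linear discriminant on retained PC scores with leave-one-out
cross-validation (deterministic, the convention of the classic morphometrics
tools);
confusion matrices are row-percent by true group, and discriminant-function
significance is Wilks' lambda of the canonical eigenvalues with Rao's F.
Mahalanobis distances exist inside the eigenproblem but are not reported.
Specimens are classified individually — averaging into group means first
would make cross-validation meaningless.

## The synthetic study population

`make_head_mesh` builds a star-shaped head: an icosphere (default
subdivision 4, 2562 vertices — a deliberate desk-scale stand-in for
180k-vertex scans) radially displaced by an ellipsoid base (semi-axes
95/75/110 mm) plus Gaussian-on-sphere bumps for nose, mouth, chin and brow.
The 20 anchors sit on fixed outward directions and are snapped to mesh
vertices, so they lie exactly on the surface by construction.  Radial
construction cannot self-intersect; a collapsed radius field (< 5 mm)
raises a generation error.

`sample_population` emulates the emulated study's design: 2 ethnicities x 2
sexes x 5 age classes with cell counts mirroring the demographic
margins of the emulated 292-specimen study sample (largest-remainder
rescaling; default total 120 for fast runs).  Per specimen it adds:

* **Group effects** as fixed smooth radial fields — ethnicity: lateral
  cranial widening/roundness; sex: nose + mouth scale; age: chin + forehead
  protrusion — with peak amplitudes in mm (defaults 2 / 6 / 3 mm).
* **Individual variation** as a random low-frequency field (10 Gaussian
  bumps, normalized to a per-surface-point SD of 1 mm by default).  Smooth,
  spatially correlated variation is essential: per-landmark white noise
  would make sliding trivial and violate the correlation structure GPA/PCA
  assume.
* **Allometry**: a fixed smooth field scaled by log centroid size (default
  peak 12 mm per unit log-CS, chosen so the injected allometry is roughly
  4–5% of shape variance, inside the 2–13% range reported for comparable
  craniofacial samples).  Age classes also shift mean log size (children
  smaller), so age and size interact — as in real growth data.
* **A random rigid pose** (rotation + translation) per specimen, and
  **digitization noise** (white, SD 0.1 mm) on the landmark coordinates
  only.  Thirty specimens are re-digitized: duplicated with fresh landmark
  noise on the same posed head, populating the error stratum.

All randomness flows through one numpy PCG64 generator seeded from the
population spec, so populations are bit-reproducible per seed.

`ground_truth` reports the constructive keys for recovery tests.  Its
`allometry_percent_expected` is the percent of shape variance predicted by
centroid size in the *noise-free, un-posed* configurations — the quantity a
shape-on-size regression targets.  It deliberately includes every
size-coupled mechanism the generator builds in (the explicit allometric
field, the age size-trajectory interacting with age shape effects, and the
coupling of individual deformation into centroid size), because a regression
on data cannot distinguish them; the isolated explicit term is reported
separately as `allometric_component_percent`.

**What passing recovery tests do and do not show.**  The generator
reproduces the ordinal structure of such a study (digitization error ≪
factor effects ≪ individual variation; localized sex dimorphism in nose and
mouth; size–age coupling), not the spectral richness of real scan data:
meshes are smooth and star-shaped, effect fields are low-frequency, and
there are no latex-cap artifacts, holes or texture.  Passing therefore
demonstrates correctness of the algorithms and calibration of the tests, not
that real-data effect sizes or classification rates would be attained.

## Problem sizes, numerical choices, limitations

* Default analysis scale: 120 specimens + 30 re-digitizations, 20 anchors +
  480 semi-landmarks, 2562-vertex meshes; the full pipeline runs in about a
  minute on one CPU.  Statistical calibration suites use 200 null
  replicates with 499 permutations.
* Tolerances: TPS interpolation `1e-8` relative; affine bending energy
  `1e-10`; surface containment `1e-6` mm; GPA convergence `1e-10` with
  machine-precision fixed-point behavior; permutation p-values add-one.
* Tie-breaks and determinism: PCA signs fixed by largest loading; farthest-
  point template growth breaks ties by candidate order; LOO cross-validation
  is deterministic; all stochastic steps take explicit seeds.
* The bilateral-symmetry decomposition sometimes applied to such data is not
  implemented: full shapes are analysed (the symmetric-component protocol is
  not specified well enough to reproduce, and the pipeline is complete
  without it).
* Curve semi-landmarks are not modeled separately: all 480 sliding points
  are surface semi-landmarks, and sliding is along surface tangent planes
  with re-projection.
* Anchor landmarks are taken as given (the generator places them by
  construction); automatic anchor detection on raw scans is out of scope.
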