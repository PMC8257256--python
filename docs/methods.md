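# Methods

This note documents the models, numerical choices and experiment designs
behind `discmorph`, in the spirit of a package methods appendix: what each
stage assumes, which parameters matter, and what the synthetic benchmarks
do and do not demonstrate.

## Boundary geometry

Masks are cleaned deterministically: keep the largest connected component,
fill interior holes, and pad 5 background pixels when the foreground
touches the image border (the pad offset is propagated to anchors).
Contours are the 0.5-level set of the mask (marching squares), oriented so
the shoelace area in (x, y) = (col, row) coordinates is positive.

The hinge is removed by the straight chord between the contour points
nearest to the two user-supplied anchors (humeral break, alula notch);
the longer of the two arcs is retained by default. Anchors more than 3 px
from the contour are rejected. Re-clipping with the same anchors is
idempotent up to one contour point.

Curvature is estimated after a fixed 5-point moving-average smoothing as
the circumscribed-circle (Menger) curvature of point triples spaced
`window` = 7 points apart, in units of 1/px. Polygon vertices are placed
at equal increments of the cumulative weight `w(s) = eps + |kappa(s)|`
with `eps = 0.1 * mean|kappa|`. Placing vertices *densely* where
curvature is high minimizes the polygon-to-contour deviation at fixed N;
the additive floor keeps straight runs (notably the hinge chord) from
being starved of vertices entirely. With constant curvature the rule
reduces exactly to equal-arclength placement. Default N = 100 vertices;
the desk-scale test configuration uses 32 (see "Problem sizes").

## The conformal map

The Riemann map of the polygon interior onto the unit disc is represented
in Schwarz–Christoffel form (disc version): with prevertices `z_j` on the
circle and interior angles `alpha_j`,

    f(w) = A + C * ∫₀ʷ ∏ⱼ (1 − ω/z_j)^(alpha_j/π − 1) dω ,

mapping the disc onto the polygon; the published pipeline direction
(image → disc) is its inverse.

*Parameter problem.* The n prevertex gaps are parameterized by n − 1
unconstrained logits through a softmax (removing rotation), and we solve
the over-determined but consistent system of all n − 1 side-length
log-ratios plus the two real components of the base-point condition
f(0) = z₀ with Levenberg–Marquardt. A square subsystem (n − 3 ratios)
would suffice in exact arithmetic — closure makes the remaining ratios
redundant — but it admits numerically spurious roots in which the two
unconstrained sides collapse into a crowded prevertex cluster; the full
system eliminates them. Initial gaps are proportional to side lengths
(equal spacing as fallback). Convergence demands max residual < 1e−6;
typical solutions reach 1e−13.

*Quadrature.* Integrals with a prevertex endpoint use Gauss–Jacobi rules
with the matching exponent (so the endpoint singularity is exact); all
paths obey a half-distance rule — each integration piece is no longer
than half the distance to the nearest other singularity — subdividing
geometrically toward the far end. 10 nodes/piece during the solve, 14 in
the final map. The integrand's log is evaluated in real arithmetic
(log-modulus + arctan2), which is several times faster than complex log
and identical for principal branches.

*Normalization.* The base point ("I-point") defaults to the vertex
centroid, projected inside for non-convex polygons. The rotational gauge
makes C real positive, i.e. the derivative of the image→disc direction at
the base point is real positive; two independent solves agree to 1e−6.
Prevertex gaps below 1e−8 rad raise a crowding error.

*Evaluation.* `inverse` (disc→polygon) integrates from the disc center or
the nearest prevertex, whichever is closer. `forward` (polygon→disc) uses
fixed-step RK4 continuation of dw/ds = (z − A)/f′(w) followed by damped
Newton, to 1e−12 of the polygon scale. Bulk pixel pushforward uses a
cached polar grid of f (96 radii with sin-clustering toward the rim × 256
angles, cumulative 2-point Gauss integration of f′), nearest-grid-sample
initialization and up to 3 Newton steps with Simpson updates of the
running f value, converging to 0.05 source px; an independent
finite-difference harmonic-map oracle in the test suite (Shortley–Weller
Laplace solve plus Cauchy–Riemann path integration) agrees with the
solver to better than 1e−3 on random polygons.

*Disc raster.* The common domain is a D×D grid (default D = 200) whose
pixel centers sit at half-integer offsets from the grid center; a pixel is
valid iff its center is strictly inside radius D/2 (no center can fall on
the circle for even D). D = 200 gives 31,428 valid pixels, within 0.04%
of π·100². Pushforward averages all source pixels landing in a disc pixel
(arithmetic mean, so constants are preserved exactly); valid pixels that
receive none — possible near the center, where the map is one-to-many in
pixel terms — are filled by bilinear sampling of the source at the
inverse image of the pixel center.

## Möbius registration

The residual freedom after disc mapping is the automorphism group
g(z) = e^{iθ}(z − α)/(1 − ᾱz). Registration maximizes Pearson correlation
over the shared valid mask. The coarse stage sweeps θ in 2° steps jointly
with α on a polar grid (radius step 0.05 up to 0.30, 24 directions); for
each α all rotations are scored at once by an FFT cross-correlation over
the angular coordinate of a fixed polar resampling. Refinement halves all
three steps 4 times (default; 3 at desk scale), hill-climbing on the true
pixel-domain correlation and keeping the best candidate, so the attained
score is monotone in grid refinement. Final resolution 0.125° in θ and
0.003 in |α| at default settings. Bilinear resampling pads invalid rim
pixels with their nearest valid neighbor so interpolation never bleeds in
zeros. θ and α are swept jointly rather than independently: the
correlation surface has shallow diagonal ridges and an independent sweep
can lock onto a secondary ridge; an `joint=False` option preserves the
independent variant. One reference image per experiment (seeded uniform
draw unless named); left wings are mirrored before conformal mapping.

## Radon domain

All ensemble statistics operate on sinograms of the aligned discs: line
patterns (veins) become localized, angle-sensitive peaks. The transform
is warp-and-sum: rotate about the raster center (D − 1)/2 — matching the
half-integer disc convention — with bilinear interpolation and sum along
rows, one column per angle (default grid 0°–179° in 1° steps; 2° at desk
scale). Column sums agree with total image mass to < 0.5%. The inverse,
used only for visualizing signed Radon-domain vectors such as centroid
differences, is filtered back-projection with a Ram–Lak (ramp) kernel
built in real space. Intensity transforms `log(1 + I)` and
`log(1 + 255 − I)` are available ahead of the transform for
representation-robustness checks; identity is the analysis default.

## Nonparametric estimators

Differential entropy uses the k-NN estimator (natural log; k = 3 by
default)

    H_k = log c_d + log(N − 1) − ψ(k) + (d/N) Σᵢ log ρ_k(i),

with c_d the unit-ball volume and ρ_k(i) the distance to the k-th nearest
neighbor excluding self. The `log(N − 1)` sample-size term follows the
formula as printed in the morphometrics context; the digamma variant
ψ(N) (the more common form in the estimator literature; the two differ by
O(1/N)) is available via `n_term='psi'`. The two-sample KL estimator
(k = 2) is

    D = (d/N) Σᵢ log(ν_k(i)/ρ_k(i)) + log(M/(N − 1)).

8-bit data is dequantized with seeded Uniform(−1/2, 1/2) jitter before
either estimator; ties would give ρ = 0. Per-pixel maps use d = 1 with a
sort-based vectorized path (cross-checked against the KD-tree path);
a window-d variant is not provided — per-pixel maps are marginal by
design. Identical input ensembles are rejected for the KL map: the
estimator assumes independent samples, and self-matches bias it by
O(log N). Known bias: with strong scale mismatch (e.g. N(0,4) vs N(0,1))
the estimate converges slowly from below; tests bound rather than pin
that direction.

PCA is centered and unscaled, computed through the Gram matrix (n ≪ d),
with sign fixed by making each component's largest-magnitude coordinate
positive. Eigenvalue significance uses marginal resampling: every column
permuted independently across rows, 95th percentile per rank, count of
observed eigenvalues above their rank's threshold (the method itself does
not fix a cutoff; 0.95 rank-matched gives ~5% per-rank false positives on
independent noise by construction).

Centroid geometry: Δ = centroid(B) − centroid(A) in Radon space,
R = ‖Δ‖, n = Δ/R, and cos θ = |⟨n, PC_k⟩| (absolute value — the sign of a
component is conventional). The identity √(1 − cos²θ)·R = ‖Δ − ⟨Δ,
PC₁⟩PC₁‖ is exact and asserted to 1e−8. Bootstrap: 50% within-group
subsampling without replacement (with-replacement flag available),
recomputing centroids and the reference PCA per replicate. Shuffle tests
permute group labels within strata and recompute the full statistic;
p = (1 + #{null ≥ observed})/(n_shuffles + 1). The manifold fit is
ordinary least squares of log √(1 − cos²θ) on log R, α = −slope, with the
constant-σ (α = 1) line anchored at the geometric mean of the observed
σ values for comparison.

## Procrustes baseline

Generalized Procrustes analysis: center, scale to unit centroid size,
iteratively rotate onto the running mean (SVD with determinant-sign
correction — reflections never allowed) until the mean shape changes by
< 1e−8. An area-matching scale variant (`scaling='match'`) is provided.
The Procrustes distance is the root-sum-of-squares over all 2L
coordinates. Landmark PCA shares the conventions of the pixel-domain PCA.

## Synthetic wings: what is emulated, and the benchmark designs

The generator renders an elliptical, AP-asymmetric blade (background 212,
blade ~150, 8-bit) with five longitudinal veins and two cross-veins as
Gaussian-profile dark ridges (width 1.8 px, depth 80) and stationary
Gaussian-filtered intervein texture (amplitude 2 intensity levels,
correlation length 3 px). The latent score t (standard normal across an
ensemble) shifts veins L2–L4 anteriorly by 0.022·t in blade-normalized
units (≈ 3.1 px per unit t at the default raster) and slides the
cross-veins distally — one coherent "dominant mode". Independent per-vein
jitter of scale σ_orth = 0.001 (≈ 0.14 px) provides orthogonal nuisance
variation; 12 ground-truth landmarks, hinge anchors, chirality mirroring
and per-specimen truth records make every downstream claim checkable.

Not emulated: hair/trichome polarity, campaniform sensilla, illumination
gradients, segmentation errors (masks are exact), or correlated
biological covariance beyond the single latent mode. Passing benchmarks
therefore demonstrate that the *pipeline* recovers planted structure
through its own distortions (boundary discretization, conformal
distortion, registration, Radon projection) — not that real wings have
this structure.

Two designs deserve explanation:

* **Quasi-linear window.** The map from vein displacement to intensity
  phenotype is only locally linear: once a vein moves by much more than
  its own width (~2 px, i.e. |t| ≳ 1), difference vectors for different
  displacements decorrelate, and group displacements bend away from the
  local tangent direction that PC1 estimates. The generator's noise
  scales are therefore calibrated so that the whole controlled-distance
  ladder below stays inside this window, and the ground-truth mode vector
  is estimated from nuisance-free pairs at t = ±1 (averaged over three
  texture seeds to suppress registration noise).

* **Controlled-distance (cylinder) ladder.** Probe groups are displaced
  along the mode by {2, 5, 10, 20}·σ_orth — offsets are specified in
  units of the orthogonal noise scale so σ/R is controlled by
  construction — and their *own* within-group latent spread is suppressed
  (`latent_sigma_scale = 0.1`), because at desk-scale group sizes the
  sampling noise of a group's mean latent score would otherwise exceed
  the smaller offsets and R would be set by noise rather than by design.
  With this design the off-axis residual of bootstrap replicates is
  constant across the ladder while R grows, and the fitted decay exponent
  lands at α ≈ 1 (the ±0.2 band absorbs errors-in-variables attenuation
  from the finite bootstrap).

Robustness perturbations follow the reference protocol: origin jitter
uniform ±3 px per axis on the conformal base point, anchor jitter ±3 px,
boundary jitter ±1 px per contour point (lightly re-smoothed so the
contour stays simple), everything downstream recomputed.

## Problem sizes

Library defaults follow the reference analysis (diameter-200 disc,
100-vertex polygon, 1° Radon grid, 4 refinement halvings). The test suite
and the acceptance script run desk-scale configurations chosen as the
package's own benchmark sizes: 320×240 rendered wings, 32-vertex
polygons, diameter-100 discs, 2° Radon grid (9,000-dimensional phenotype
vectors), 3 refinement halvings; ensembles of n = 100 (reference group)
plus 4 × 24 probe wings for the end-to-end suites and n = 48 + 4 × 24 in
the acceptance script. At these sizes one wing takes about a second to
process end to end. Statistics at full scale differ only through the
sharper rasters, not through any algorithmic switch.

## Known limitations

* The SC solver targets simple polygons with moderate crowding; extremely
  elongated shapes (aspect ≫ 5) would need crowding-robust
  parameterizations and currently abort with a crowding error.
* The per-pixel KL/entropy maps are marginal (d = 1) and ignore
  inter-pixel dependence; they localize variation but do not measure
  joint structure.
* The k-NN KL estimator underestimates strongly scale-mismatched
  divergences at realistic n.
* Registration absorbs any phenotype component expressible as a disc
  automorphism; coherent pattern shifts are measured only net of the
  best-fitting Möbius map. This mirrors the alignment convention of the
  underlying method.
* The 31,428-pixel disc count is a property of the stated half-integer
  pixel-center convention; alternative conventions give counts within a
  fraction of a percent but none equals round(π·100²) exactly.
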