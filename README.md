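# discmorph

Landmark-free morphometrics for segmented 2D organ images, built around the
*Drosophila* wing as the model system.

Classic geometric morphometrics reduces a complex organ to a handful of
homologous landmarks (for the fly wing, 12 vein intersections, a
24-dimensional shape space). `discmorph` instead treats **every pixel as a
trait**: each segmented wing is mapped conformally onto a common unit disc,
residual orientation/centering freedom is removed by optimizing over disc
automorphisms, and the aligned ensemble is analyzed at single-pixel
resolution — entropy and divergence maps, PCA, centroid geometry and
nonparametric inference — by default in the Radon (sinogram) domain, where
vein-like linear features are most separable.

## The method in brief

1. **Boundary.** A binary mask is cleaned (largest component, hole filling,
   border padding), its contour traced at sub-pixel resolution, and the
   hinge removed by the chord between two user-supplied anchors (humeral
   break, alula notch). The contour is approximated by an N-vertex polygon
   (default N = 100) with vertices placed equidistantly along the
   cumulative curvature weight, so high-curvature regions are sampled
   densely.
2. **Conformal disc map.** The Riemann map of the polygon interior onto the
   unit disc is computed in Schwarz–Christoffel form

   `f(w) = A + C ∫₀ʷ ∏ⱼ (1 − ω/zⱼ)^(αⱼ/π − 1) dω`,

   with prevertices zⱼ solved from the side-length parameter problem
   (Gauss–Jacobi compound quadrature, Levenberg–Marquardt on gap logits).
   The interior base point maps to the disc origin; intensities are pushed
   forward onto a fixed D×D raster (default D = 200) by many-to-one
   averaging with inverse-bilinear fill.
3. **Möbius registration.** Remaining freedom is the disc automorphism
   `g(z) = e^{iθ}(z − α)/(1 − ᾱz)`; each disc image is registered to one
   reference per experiment by maximizing Pearson correlation over a
   coarse-to-fine (θ, α) search. Left wings are mirrored beforehand.
4. **Radon-domain statistics.** Aligned discs become flattened sinograms
   ("phenotype vectors"). Within-group variation: per-pixel k-NN
   (Kozachenko–Leonenko) entropy, `Ĥ_k = log c_d + log(N−1) − ψ(k) +
   (d/N)Σᵢ log ρ_k(i)`, and PCA with marginal-resampling eigenvalue
   significance. Between groups: per-pixel symmetrized k-NN KL divergence,
   and centroid geometry — Δ, R = ‖Δ‖, n = Δ/R, and cos θ = |⟨n, PC_k⟩|
   against a reference group's components — with bootstrap subsampling and
   label-shuffle null distributions. The cylinder diagnostic
   `σ/R = √(1 − cos²θ) ∝ R^(−α)` tests whether phenotypes occupy a 1D
   manifold (α = 1: constant orthogonal noise).
5. **Baselines & synthetic data.** A generalized-Procrustes landmark
   pipeline provides the classical comparison, and a procedural wing
   generator (blade, five longitudinal veins, two cross-veins, textured
   intervein tissue, a single latent variation axis plus orthogonal
   nuisance noise, full ground truth) makes every stage testable without
   any image downloads.

## Worked example

```bash
python examples/03_group_comparison.py
```

prints (numbers from this exact script and seed):

```
centroid distance R = 9595.9 (Radon-domain units)
|cos(n, PC1)| = 0.887
|cos(n, PC2)| = 0.144
|cos(n, PC3)| = 0.134
shuffle test: observed |cos| = 0.887, p = 0.070
```

The `mut` group was generated displaced purely along the latent vein-shift
mode; after the full pipeline its centroid direction aligns predominantly
with the reference group's own dominant axis (|cos θ| = 0.89 against PC1
versus ≈ 0.14 against the next components). The shuffle p at this very
small n (10 wings per group) is conservative — random splits of groups
sharing the latent axis also partly align with PC1 — and tightens with
ensemble size. The other examples cover the generator
(`01`), the conformal map and its area distortion (`02`), entropy/KL maps
(`04`), the Procrustes baseline (`05`) and the manifold-decay exponent
(`06`).

A thin CLI mirrors the library for shell use:
`discmorph synth|align|stats|run|baseline-procrustes --help`.

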