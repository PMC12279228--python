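# Methods

## Physical model

Every voxel of the object volume is a uniaxial linear retarder. Its index
ellipsoid is parameterized by the c-axis director
`c = (sinϕ cosψ, sinϕ sinψ, cosϕ)` (polar ϕ ∈ [0, π], azimuth
ψ ∈ [0, 2π)), the extraordinary index n_e, and the globally fixed ordinary
index n_o of the index-matching liquid (default 1.48). The director is
headless: (ϕ, ψ) and (π−ϕ, ψ+π) describe the same voxel, and every
function in the package is invariant under that flip (tested to machine
precision).

The tomographic pose maps object vectors into the lab frame (k, j, p) by
`R_s = R_k(β) R_j(α)`, right-handed rotations about the lab tilt axis
k = (1,0,0) and rotation axis j = (0,1,0); the beam runs along
p = (0,0,1). For each sample of a ray:

- incidence angle: `cos φ = p · R_s c`;
- e-wave index: `n_E = n_o n_e / sqrt(n_o² sin²φ + n_e² cos²φ)`
  (n_E = n_o along the c-axis, n_e perpendicular to it, and always between
  the two);
- retardance: `δ = 2π d (n_E − n_o)/λ` with d the voxel pitch and λ the
  vacuum wavelength (defaults 23.44 µm and 0.625 µm);
- fast axis: θ = azimuth of the transverse projection of R_s c, measured
  from k. The printed projection formula needs an explicit normalization of
  the projected vector; we instead take a two-argument arctangent of the
  (j, k) components, which normalizes implicitly and fixes the quadrant,
  then fold θ modulo π (only 2θ enters the matrix). When c is parallel to
  the beam the projection vanishes; θ is then set to 0 and flagged, which
  is harmless because δ = 0 there and the voxel matrix degenerates to
  t·I regardless of θ;
- Müller matrix: `M = t · R(−θ) LR₀(δ) R(θ)`, implemented in closed form
  and verified against the explicit rotator/retarder triple product. The
  scalar transmission follows Beer–Lambert, `t = exp(−A)`, with A the
  per-voxel-traversal absorption coefficient (dimensionless; a path of L
  voxel lengths transmits `exp(−A·L)`).

### Polarization states and intensity convention

Generator and analyzer each use the four states RCP, LCP, LP 0°, LP 45°
(two Poincaré poles, two equator points), giving 16 polarization sets.
An ideal polarizer for the unit Stokes direction s is
`M = ½·outer(v, v)`, `v = (1, s)`. With the unpolarized unit source
`S = (1,0,0,0)ᵀ` the co-polarized maximum through matched
generator/analyzer and an identity sample is 0.5: the first polarizer
halves the unpolarized intensity, the matched second one is lossless.
All intensities are reported on this scale (relative to the co-polarized
maximum); the absolute factor cancels in the loss, in the Müller synthesis
and in the noise model, which normalizes to the global image maximum.

## Ray discretization

The forward model is ballistic: one straight ray per detector pixel, no
refraction, diffraction or scattering (valid for index-matched samples with
|n_e − n_o| ≲ 10⁻², which the `VoxelGrid` container enforces). The detector
raster equals the (nx, ny) grid footprint with the rotation axis along y.
Each ray is sampled at uniform steps of one voxel pitch; every sample takes
the parameters of the nearest voxel of the rotated grid and contributes one
retarder matrix with a constant path length d. The step count is
parity-matched to nz so that at α = β = 0 the samples coincide exactly with
voxel centers and the chain reduces to the grid column. For oblique rays
the unit-pitch visited sequence is an ordered subset of a finely marched
ray path (tested against a d/10 marching oracle). This one-matrix-per-step
convention keeps the loss piecewise smooth in the parameters, which the
analytical gradient requires; the alternative of exact chord lengths per
crossed voxel would change per-voxel weights by at most a factor ~√2 and is
absorbed by the reconstructed n_e scale at oblique incidence.

Matrices compose left-multiplicatively along propagation (last voxel hit is
leftmost), matching the prefix/suffix split used by the gradient.

## Inverse problem

Minimized objective (internal, scale-normalized form):

    F = ε^I / N_data + w_o · ε^reg,o / N_pairs + w_n · (ε^reg,n / Δn_max²) / N_pairs

with `ε^I = Σ (Î − I)²` over all projections, polarization sets and pixels;
`ε^reg,o = Σ_pairs (1 − (c_v·c_w)²)` (director-symmetric, zero iff
neighboring axes are parallel or antiparallel) and
`ε^reg,n = Σ_pairs (n_e,v − n_e,w)²` over 6-neighbor pairs. The exact
functional forms of the smoothing penalties are this package's choice of
the simplest quadratic neighbor couplings with the required symmetries.
The per-datapoint / per-pair normalization makes the learning rates
transferable across problem sizes; recorded traces keep the raw ε^I sum.
Loss and both regularizer traces are stored every iteration, plus
orientation-proximity and index-error traces when a ground truth is
supplied.

The data-term gradient is analytical. With per-ray prefix products L_p
(voxels before sample p) and suffix products O_p (after), the derivative of
one intensity w.r.t. the sample's matrix is the outer product of
`Q = Sᵀ M^PSA O_p` and `V = L_p M^PSG S`, so

    ∂ε^I/∂u = Σ 2(Î − I) · ⟨O_pᵀ W L_pᵀ, ∂M/∂θ·∂θ/∂u + ∂M/∂δ·∂δ/∂u⟩

for u ∈ {ϕ, ψ, n_e}, where W sums the residual-weighted state outer
products and ⟨·,·⟩ is the Frobenius inner product. The element-wise
derivatives of the retarder matrix and the chain factors ∂δ/∂u
(through n_E and cos φ, written in cos²φ so no arccos singularity appears)
and ∂θ/∂u (through the transverse components, zeroed at the degenerate
c ∥ p configuration) are all closed-form. The complete gradient matches
central finite differences at relative error < 10⁻⁴ on random volumes over
dual-axis geometries (tested, and recomputed by the acceptance script).

### Optimizer

Nesterov-accelerated descent: `v ← μv − lr·∇F(x + μv)`, `x ← x + v`, with
momentum μ = 0.9; μ = 0 reduces exactly to plain gradient descent. A
stage-wise schedule alternates blocks of 10 iterations on (ϕ, ψ) with 10 on
n_e, which decouples the two very differently scaled parameter groups.
After each step ϕ is folded into [0, π] (flipping ψ by π when needed),
ψ wrapped modulo 2π, and n_e clipped to the configured Δn bounds. If the
objective fails to improve over 8 consecutive iterations, learning rates
are halved and momentum reset; a non-finite loss or gradient aborts.
Optional mini-batching over projections (`batch_projections`) gives the
stochastic variant; the default full batch is deterministic under the
initialization seed.

Defaults (fixed by a one-time line search on the spiral phantom and not
re-tuned per run): lr 8000 for angles and 3·10⁻² for n_e on the normalized
objective, w_o = 3·10⁻³, w_n = 10⁻³, 250 iterations, uniform random
initialization of ϕ ∈ [0, π], ψ ∈ [0, 2π), Δn ∈ [0, 0.002].

Two structural choices matter for convergence:

- **Positive-birefringence bound.** The retarder matrix is invariant under
  (δ, θ) → (−δ, θ + π/2), so allowing Δn < 0 admits a conjugate solution
  branch with perpendicular axes that traps gradient descent. The optimized
  Δn is therefore bounded to [0, 0.01] by default (the samples of interest
  — collagenous tissue — have positive birefringence); the bounds are
  configurable for negatively birefringent materials.
- **Gimbal degeneracy.** At ϕ ≈ 0 the azimuth ψ is unidentifiable (the
  chart of the sphere is singular); the director regularizer and the
  stage-wise alternation keep such voxels from stalling, and the
  orientation metric |c_est · c_true| is insensitive to the chart.

`reconstruct_multistart` restarts from k seeds and keeps the lowest final
objective; useful for small dense volumes, where a single random start can
land in a local minimum. The spiral-phantom validation uses single starts.

### Absorption

The absorption tomogram is solved separately and first: the per-pixel
transmission is element (0,0) of the synthesized Müller matrix (exactly the
product of per-voxel transmissions), and `Σ_path A = −log T` is a linear
system solved with damped LSMR and clipped at zero. The decoupling is exact
because t_LR is a scalar factor of the retarder matrix. The reconstructed A
is then held fixed while (ϕ, ψ, n_e) are optimized.

## Polarimetric data reduction

With invertible 4×4 generator/analyzer state matrices, the per-pixel Müller
matrix is `M = A⁻¹ I₁₆ G⁻¹`; this inverts the intensity simulation exactly
for noiseless data (machine-precision roundtrip, tested). Cumulative
retardance and fast axis are read off the retarder element pattern:
transmission = M₀₀, `δ = atan2(√(m₃₁² + m₃₂²), m₃₃) ∈ [0, π]` (principal
branch; δ > π aliases to 2π − δ with θ shifted by π/2),
`θ = ½·atan2(m₃₁, −m₃₂) mod π`. A thick heterogeneous sample is generally
not a pure retarder; pixels whose normalized 3×3 block deviates from
orthogonality beyond tolerance are flagged rather than silently decomposed.
Cross-pixel phase unwrapping is out of scope.

## Synthetic data

The validation object is a helical tube (default grid 15×25×15 voxels, one
pitch of 22 voxels, tube radius 3; reduced 9×15×9 / pitch 13 / radius 2 for
desk-scale runs). Foreground voxels lie within the tube radius of the
continuous centerline; their c-axis is the helix tangent at the nearest
centerline point, and Δn ∈ [0.001, 0.002] and A ∈ [0.1, 0.3] ramp linearly
with the centerline parameter (the simplest smooth profile consistent with
"gradual variation" over the stated ranges, which are typical of biological
tissue). The helix radius defaults to the largest value that keeps the tube
inside the grid, so no projection of the default scan clips it. Shot noise
scales the stack so its global maximum maps to 4095 counts (12-bit
full well), Poisson-samples, and rescales.

What the phantom does *not* emulate: refraction and lensing at sample
boundaries, depolarization and diattenuation, misalignment of the
goniometer, camera read noise and gain nonuniformity. Passing the recovery
tests therefore demonstrates the correctness of the forward model,
gradients and optimizer under the model's own assumptions — not robustness
to the systematic errors of a physical instrument.

## Problem sizes and tolerances

Tests and the acceptance script use the reduced spiral (9×15×9, 78
projections, ≈170 k datapoints for 3 645 unknowns) and 3×3×3 volumes for
finite-difference checks; full-scale geometries (16×35×16, ≈700 k
datapoints) are exercised for the counting identities only. Finite
differences use step 10⁻⁶ against a 10⁻⁴ relative-error bound; exact
algebraic identities are asserted at 10⁻¹⁰–10⁻¹³ absolute. The absorption
solver uses LSMR damping 0.1 and a transmission floor of 10⁻⁶.

## Known limitations

- Nearest-neighbor unit-pitch ray sampling introduces discretization error
  at oblique angles (bounded by the fine-marching oracle tests).
- The reconstruction assumes uniaxial, non-depolarizing,
  non-diattenuating voxels; biaxial anisotropy and depolarization are out
  of scope.
- δ is only recovered modulo the principal branch per voxel chain; very
  thick or strongly birefringent samples would alias.
- n_o is never optimized; a wrong immersion-liquid index biases n_e but not
  the orientations (only Δn enters the matrices to first order).
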