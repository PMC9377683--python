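# Methods

## Model

A cryo-EM density map is treated as a nonnegative mass distribution on its
voxel lattice. After normalizing two maps to unit mass, their similarity is
the entropy-regularized squared 2-Wasserstein distance: the minimum over
transport plans π (joint distributions with the two maps as marginals) of
the quadratic transport cost Σ d²(x,y) π(x,y) minus γ times the plan entropy
H(π) = −Σ π ln π. The regularization makes the problem strictly convex and
solvable by alternating kernel scalings (Sinkhorn iterations): with the
Gibbs kernel K = exp(−d²/γ), the optimal plan is diag(v) K diag(w), and the
converged cost equals the dual value γ·(Σ μ₀ ln v + Σ μ₁ ln w).

The intermediate map V_t minimizes (1−t)·W²₂,γ(V₀,V) + t·W²₂,γ(V,V₁). It is
computed by the iterated-Bregman barycenter scheme: per input measure a pair
of scaling fields (vᵢ, wᵢ) is maintained; each pass updates
wᵢ ← μᵢ ⊘ K(vᵢ), forms dᵢ = vᵢ ⊙ K(wᵢ), sets the barycenter estimate to the
weighted geometric mean μ = Π dᵢ^{αᵢ} (accumulated in log space for
underflow resistance), and rescales vᵢ ← vᵢ ⊙ μ ⊘ dᵢ. At weights (1−t, t)
this is the displacement interpolant.

Assumptions worth stating explicitly: maps are nonnegative measures
(negative intensities from sharpening are clamped before transport); the
two maps are normalized to equal mass, so composition differences are
interpolated in scale, not transported; the cost is plain squared Euclidean
distance, unaware of molecular topology — mass may fragment and travel in
straight lines even when the underlying motion is a rotation.

## The kernel as an exact separable operator

On a regular grid the Gibbs kernel factorizes per axis. `apply_kernel`
multiplies the field by an n×n banded 1D kernel matrix along each axis, so
the result equals the dense m×m kernel–vector product exactly (up to the
band truncation) while never forming the m×m matrix. The band half-width is
`truncation_radius`·σ, never less than `truncation_radius` voxels, with
default 40σ.

The wide default is deliberate. The Gaussian tail exp(−d²/(2σ²)) underflows
float64 near 38σ, so a 40σ band reproduces the untruncated kernel to machine
precision. A narrow band (the conventional 3–4σ of image filtering) is
*wrong* for transport: voxels separated by more than the band have exactly
zero coupling, the plan between distant regions becomes infeasible, and
barycenters with asymmetric weights collapse toward the midpoint — measured
on the two-translated-blob benchmark, a 4σ band put the t = 0.25 barycenter
centroid at x = 15.4 instead of 13.0, while the 40σ band is exact to 1e-8
voxels and converges an order of magnitude faster. Tails as small as 1e-79
are still meaningful in the scaling iteration, because only ratios of tails
enter the fixed point.

Two kernel conventions are exposed, because "Gaussian of width σ² = γ" and
"kernel exp(−d²/γ)" differ by a factor 2 in variance:

* `standard`: σ² = γ/2, i.e. exactly exp(−d²/γ) — the Gibbs kernel of the
  objective. Used for every quantitative check against the dense oracle.
* `paper` (default for morphing): σ² = γ, i.e. exp(−d²/(2γ)) — the
  convention of the published morphing tool, equivalent to `standard` at
  doubled γ. Keeping it default means γ values quoted for that tool (γ = 1
  at 60³, γ = 3 at 240³) carry over unchanged.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| γ | 1 | voxel² | entropic regularization; larger = smoother, faster-converging, blurrier; tie γ to the grid (≈1 at 60³, ≈3 at 240³); `gamma_from_angstrom2` converts physical values |
| max_iter | 1500 | — | iteration cap; hitting it is a warning, not an error (non-converged maps are still displayable) |
| tol | 1e-9 | — | unnormalized L2 change of the sum-1 barycenter estimate between consecutive passes (for distances: of the concatenated scaling fields) |
| kernel_convention | paper | — | see above |
| floor | 1e-300 | — | divisions use max(denominator, floor). The floor must sit *below* every meaningful kernel tail: masses 3 voxels apart at γ = 0.05 couple at exp(−180) ≈ 1.5e-79, and a larger floor (e.g. 1e-30) clamps that tail and biases the distance (measured: 6.91 instead of the correct 9.0 on the point-mass benchmark). 1e-300 guards exact zeros only. |
| truncation_radius | 40 | σ multiples | see above |
| threshold_fraction | 0.01 | of map max | binarization cutoff for Δ_Vol / Δ_Voxel, strict `>` per-map maximum |

γ and all distances are in voxel units: the regularization is a property of
the lattice geometry, and published per-grid-size values are voxel-level.

## Numerical choices

* **Initialization** is always the all-ones scaling field; there is no
  randomness anywhere in the solver, so every run is bitwise reproducible.
* **Stabilization**: far outside the inputs' support the ratio of two
  Gaussian tails can grow by hundreds of orders of magnitude per pass, so
  barycenter scaling fields are clipped to [1e-150, 1e150]. The clip can
  only activate at voxels whose barycenter mass is negligible (tail
  products ≲ 1e-100); within the support the scalings stay O(1).
* **Convergence metric**: root of summed squared differences of the
  normalized barycenter field between consecutive passes; one pass over all
  input measures counts as one iteration. Applying the criterion to the
  normalized field keeps it comparable across grids and mass scales.
* **Degenerate inputs**: all-zero (or all-negative) maps are rejected at
  normalization; a zero-mass map is still valid to read and write.
  Barycenter weights exactly (1, 0) are accepted: the result is the
  weight-1 input blurred by the kernel (entropic bias), which is why
  trajectory endpoints return the input maps verbatim instead of solving a
  degenerate barycenter.
* **Ties** in best-match assignment resolve to the smallest frame index.
* **Resampling** is trilinear over the fixed physical box with the total
  intensity renormalized to the input's exactly — the transport stage
  assumes mass conservation, so interpolation error in the total is scaled
  out. Axis order is normalized to (x,y,z) on read whatever the file's
  MAPC/MAPR/MAPS permutation; anisotropic voxel edges are stored but
  trigger a warning, and the mean edge is used as the physical length
  scale.
* **RMSD / Δ_Voxel** divide by the full grid voxel count; maps are
  normalized to unit total intensity before L2/RMSD matching (barycenters
  and deposited maps live on different intensity scales), with raw-intensity
  comparison available via a flag.

## Synthetic data

The generators provide ground truth that deposited maps cannot: Gaussian
blobs with known centroids and masses; atom-coordinate rasterization (one
unit-mass isotropic Gaussian per atom, default σ = 1.5 Å, a typical width
for intermediate-resolution simulated maps — atoms are not Z-weighted since
all comparisons are scale-normalized); and a two-state fixture. The fixture
caricatures a group II chaperonin barrel: a 16-blob ring carrying 8 arms as
thick as the ring wall (about half the structure's mass), arm length ≈ 0.3
of the box, on the 60³ grid to which γ = 1 is matched; `opening` ∈ [0,1]
swings the arms 0–65° outward, giving a parametric ground-truth displacement
trajectory with exactly conserved mass. Arm mass fraction matters: with
thin arms the entropic blur halo of near-endpoint barycenters dominates the
binarized comparison and the displacement-vs-cross-fade ordering degrades at
the outermost interior frames.

What the generators do **not** emulate: experimental noise, CTF/point-spread
delocalization, map anisotropy, solvent background, or rotational (rather
than chord-line) motion of real domains. Passing tests therefore demonstrate
the solver's mathematical contracts and the qualitative displacement
behaviour, not resolution-dependent performance on deposited maps.

## Problem sizes

Unit and property tests run on 6³–12³ grids (where the dense oracle is
exact) and 32³ blob pairs; the end-to-end checks run the full 25-frame
trajectory on a 60³ pair and the 9-frame ground-truth comparison on the 60³
fixture — the working scale the default γ is tied to. The acceptance script
repeats these at the same sizes in about a minute on one CPU.

## Known limitations

* Balanced transport only: maps with genuinely different composition are
  force-normalized; unbalanced OT is out of scope.
* No GPU backend; the kernel operator is a pure function and could be
  swapped, but none ships.
* No log-domain Sinkhorn: γ ≪ 0.1 (voxel²) is ill-conditioned and warned
  about rather than supported.
* The dense oracle is capped at 12³ voxels by its m×m matrices.
* Straight-line mass transport can transiently fragment connected density;
  topology- or rigidity-aware costs are not implemented.
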