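# Methods

## Anatomy representation

An anatomy couples class-posterior probability images with boundary
surfaces on one physical frame.  Voxel index i maps to the physical point
`origin + i * spacing` (0-based, world units everywhere); anisotropic
spacing is supported throughout.  Posterior channels lie in [0, 1] with a
per-voxel channel sum of at most 1 — the remainder is implied background.
The MAP label of a voxel is `1 + argmax_c p_c` when the winner beats that
implied background probability, else 0; ties break toward the lowest
channel index.  Neonatal anatomies with split white-matter classes
(myelinated / nonmyelinated) are made comparable to mature ones by
`merge_channels`, which sums the two posteriors voxel-wise — total
probability mass is preserved exactly — yielding a single white-matter
surface.

Surfaces come from marching cubes at iso-level 0.5 on the label
indicator.  The indicator is pre-smoothed by 1 voxel (configurable; 0
disables): the isosurface of a raw binary mask carries a staircase area
inflation of roughly 9 % that does not vanish with resolution, while the
smoothed indicator recovers a sphere's analytic area to about 2 %.  Faces
are ordered so area-weighted normals point out of the labeled region —
the currents norm is sign-sensitive, so this orientation is normative.
The optional decimation is a deterministic vertex-clustering pass (the
quadric route would need an extra dependency); it targets a face-count
fraction and guarantees no degenerate output faces.

## Currents norms and gradients

A triangulated surface is the current Σ_f η(f) δ_{c(f)} with centroid
c(f) = (x_r+x_s+x_t)/3 and area-weighted normal
η(f) = ½(x_s−x_r)×(x_t−x_r).  Kernels are normalized to k(x,x) = 1 with
the Gaussian argument |x−y|²/σ² (no 2σ²; no volume prefactor) — the
registration weights absorb overall scale, and σ is directly a physical
length.  Dissimilarity is the squared norm of the union with the second
shape's measure negated, which equals ‖a‖² + ‖b‖² − 2⟨a,b⟩ by
bilinearity.  Degenerate faces contribute a zero normal and are kept so
face indices stay stable.

The vertex gradient of the dissimilarity has two terms per incident
face: a normal-variation term — ∂η/∂x_v is a cross product with the
opposite edge, giving G(c_f) × (x_prev(v) − x_next(v)) with
G(c) = Σ_u s_u k(c, c_u) η(u) — and a centroid term (2/3) Σ_u s_u
∇k(c_f, c_u) ⟨η(f), η(u)⟩ from ∂c_f/∂x_v = I/3.  Both terms carry the
symmetry factor 2 of the quadratic form; correctness is pinned by a
central finite-difference oracle (componentwise agreement at 1e-4 and
better in the tests).

The exact computation is O(N²), vectorized in row blocks, and intended
for up to a few thousand faces; it is the ground-truth oracle for the
particle-mesh path, which handles larger inputs.

## Particle-mesh approximation

All-pairs kernel sums are approximated in four steps: build a grid, splat
the signed face momenta η(f)·s_f at the centroids, convolve with the
kernel on the grid by FFT, and interpolate back at the centroids.  When
posteriors exist the computational grid *is* their lattice, adding no
quantization beyond the images' own; bare geometry gets a bounding-box
grid padded by a caller-chosen border so every deposit stays in bounds.

Splatting uses standard trilinear (cloud-in-cell) weights — 1−{x} toward
the floor node and {x} toward the ceiling node per axis — making it the
exact adjoint of trilinear interpolation: total deposited mass equals
total input mass, deposits are order-independent to rounding, and
interpolation of a splatted node-aligned impulse reproduces it exactly.
Accumulation is a deterministic sequential reduction; concurrent
implementations (atomics, sort-and-scan) are equivalent realizations of
the same contract.

The FFT convolution is linear (zero-padded to grid + kernel support),
never circular.  The kernel is sampled at node offsets out to the radius
where it falls below 1e-6 of its peak, additionally capped at the grid's
physical extent — exact for a convolution restricted to the grid, and
essential for the heavy-tailed Cauchy kernel whose 1e-6 radius is near
1000 σ.  The PM estimators (norm and gradient) divide the sampled
kernel's spectrum by the squared cloud-in-cell window spectrum per pass
(sinc⁴ per axis in total), the classical N-body window deconvolution;
this cuts the norm error at σ = 8 h from ~1.5 % to ~0.1 %.  The generic
`grid_convolve` stays a plain linear convolution.

The gradient's kernel-derivative term is obtained by convolving the same
splatted momentum with the three analytically differentiated kernels
(one forward FFT per momentum component, shared across all four
kernels), then contracting with the face normals at interpolation time —
more accurate than numerically differentiating the convolved field at
the same asymptotic cost.

Validity requires σ at least the grid spacing; below that the grid
cannot resolve the kernel and a warning is issued.  A caveat discovered
during validation: the PM gradient approximates the *analytic* gradient
of the continuous functional (cosine ≥ 0.999 against the exact gradient
at σ = 8 h).  The literal derivative of the PM functional additionally
carries the grid-crossing oscillation of the approximation error, whose
slope is O(error/h); directional finite differences of the PM
dissimilarity therefore agree with the PM gradient only at the
few-percent level, and that is inherent to CIC splatting, not a bug.

## Deformation machinery

The velocity PDE uses the positive-definite Cauchy–Navier fluid operator
L = −α∇² − β∇(∇·) + γ (α, β ≥ 0 smoothness, γ > 0 invertibility; writing
the Laplacian with a positive sign would anti-smooth high-frequency
force components and break descent).  The Fourier symbol is assembled
from the discrete central-difference stencils — so the solve is exact
for the discrete operator, verified to machine precision against the
stencil — and the 3×3 per-frequency system (a I + β s sᵀ) is inverted in
closed form via Sherman–Morrison.  Defaults α = β = 0.01, γ = 0.001 give
a smooth, long-range velocity appropriate for global alignment; raising
γ localizes the response (the multiscale experiment uses γ = 0.01 for
exactly this reason).

The inverse map is stored as a dense displacement field u with
h⁻¹(x) = x + u(x) on the posterior lattice.  One greedy step composes
h⁻¹_t(x) = h⁻¹_{t−1}(x + dt·v_rev(x)) by trilinear interpolation of the
old displacement, where v_rev = −v is the reverse velocity; geometry
advects forward along +v evaluated at the vertices.  In the greedy
small-step regime this forward/backward pair keeps the two compartments
consistent (verified on phantom recovery: meshes and label maps agree to
within a voxel).  Image pull-back uses clamp-to-edge (zero-gradient)
boundary handling — probabilities remain convex combinations, so [0, 1]
bounds and constancy are preserved and no posterior mass is invented at
the boundary.  The FFT solve implies periodic boundaries, so forces are
tapered to zero over a 3-voxel margin to suppress wrap-around coupling.
Jacobian determinants of h⁻¹ (central differences) serve as the
diffeomorphism diagnostic; every registration records the per-stage
interior minimum.

## Registration driver

Per stage of the kernel schedule: assemble F = w_p F_img + w_g F_geom,
solve L v = F, normalize the Euler step so the maximum displacement is
`step_size` (default 0.4) voxels — the guard that keeps Jacobians
positive — then compose the inverse map and advance the meshes.  Both
force terms point in the descent direction: the image force is
−Σ_c (p̃_c − q_c)∇p̃_c (the classical greedy fluid body force, validated
by a Gateaux-derivative oracle at 1e-3), and the geometry force is the
negated per-vertex PM currents gradient splatted onto the grid (splat
conservation makes the deposited total equal the vertex sum).

A trial step that increases the energy is retried at half length up to
four times and otherwise rejected outright — state kept, the persistent
step scale halved; five consecutive rejections end the stage.  This
backtracking is what makes the energy trace nonincreasing (within the
1e-5 acceptance tolerance) after the first iteration; without it,
normalized greedy steps oscillate near the minimum.  Stages also stop on
a relative energy decrease below `tolerance` over a 10-iteration window,
at the stage budget, or when the energy reaches the floating-point floor
relative to the moving anatomy's self-energy (the coincident-anatomy
case).  Energies are re-evaluated with each stage's kernel, so traces
are comparable only within a stage; the result records the stage
boundaries.

Defaults: w_p = w_g = 1 (both terms are reported separately so users can
rebalance), three stages at σ = 16, 8, 4 voxels, 1000 total iterations.
The currents kernel and the PM grid kernel are the same object; the
operator coefficients are independent smoothness controls.

## Phantoms and what the tests do (and do not) show

The phantom generator produces sphere, ellipsoid, nested two-tissue
(wm core / gm shell / csf rim — three posterior channels, two surfaces),
and sphere-with-bump label maps analytically, softens them into
posteriors by Gaussian-smoothing the one-hot indicator *including the
background channel* — smoothing preserves the partition of unity, so the
channel-sum invariant holds exactly — and extracts surfaces from the
labels.  The 1-voxel softening width is what gives the image force
nonzero gradients while keeping interior MAP labels stable.  Ground-truth
deformations (translation, scaling about the center, Gaussian bump with
a fixed-point inverse) are validated as diffeomorphic at construction;
labels warp nearest-neighbor so integer translations are exact.

Phantoms emulate the *structure* the method consumes — multicompartment
posteriors with consistent surfaces and known deformations.  They do not
emulate MRI intensity characteristics, segmentation noise, topology
changes, or inter-subject variability; passing recovery tests shows the
optimization machinery is correct, not that any particular clinical
population registers well.

Problem sizes are chosen so the whole suite runs in minutes on one CPU:
recovery on a 48³ sphere with a 3-voxel shift and a single σ = 8 stage
(overlap |h·S0 ∩ S2|/|S2| ≥ 0.95 from a 0.78 baseline; this metric is
deliberately stricter than Dice), and the multiscale comparison on a 40³
bump phantom with a (5, 5, 0)-voxel shift, geometry-driven (w_p = 0,
γ = 0.01), where the two-stage σ = 10 → 1.5 schedule beats both
single-kernel schedules on the common fine-kernel energy by a factor of
7–19: the fine kernel alone falls into the classic shrinkage local
minimum, the coarse kernel alone cannot represent the detail.

## Numerical notes and limitations

- Trilinear splat/interpolation coefficients follow the standard
  convention (weight 1−{x} on the floor node); a point exactly on a node
  deposits solely to that node.
- Exact-vs-PM refinement comparisons use octave grid steps; with window
  deconvolution the signed error is small enough that adjacent grid
  sizes can swap order through zero crossings, so trend measurements
  average the absolute error over independent realizations.
- The greedy scheme optimizes no time-integrated geodesic energy; the
  resulting map is diffeomorphic but not a geodesic endpoint, and no
  inverse-consistency averaging is performed.  The reverse velocity is
  the negated forward one (exact only in the small-step limit); a
  fixed-point inversion would be a refinement.
- Out-of-grid geometry is an explicit error in `splat` (named point), so
  targets must fit the posterior lattice with margin; phantoms enforce a
  4-voxel margin.
- Affine pre-alignment is assumed done; the package neither estimates
  nor applies affine transforms.
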