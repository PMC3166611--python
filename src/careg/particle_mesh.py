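"""Particle-mesh bridge between unstructured geometry and the image grid.

All-pairs kernel sums over face currents are approximated in four steps:
build a regular grid (normally the posterior-image lattice itself, so no
quantization is added beyond the images' own); *splat* each Dirac mass
onto its 8 enclosing nodes with trilinear weights; *integrate* by FFT
convolution with the sampled kernel; and *interpolate* the convolved
field back at the face centroids.  Complexity drops from O(N_f^2) to
O(M log M) in the grid size M.

Splatting and interpolation are adjoint: the same trilinear coefficients
gather in one direction and scatter in the other, so interpolation of a
splatted node-aligned impulse reproduces it exactly.  The approximation
is only valid when the kernel width is at least the grid spacing — below
that the grid cannot resolve the kernel and the method breaks down; a
warning is issued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfftn, next_fast_len, rfftn

from careg.anatomy import Anatomy, Image3D, ProbabilityImageSet, TriangleMesh
from careg.currents import (
    FaceCurrents,
    Kernel,
    assemble_vertex_gradient,
    face_currents,
)

__all__ = [
    "GridSpec",
    "GridField",
    "PMConfig",
    "build_grid",
    "splat",
    "interpolate",
    "grid_convolve",
    "pm_currents_norm_sq",
    "pm_currents_dissimilarity",
    "pm_currents_gradient",
]


@dataclass(frozen=True)
class GridSpec:
    """Lattice geometry: node counts, spacing, origin (physical units)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 2 for n in self.shape):
            raise ValueError(f"grid needs at least 2 nodes per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @classmethod
    def of_image(cls, img: Image3D | ProbabilityImageSet) -> "GridSpec":
        return cls(
            tuple(int(n) for n in img.shape),
            tuple(float(s) for s in img.spacing),
            tuple(float(o) for o in img.origin),
        )

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin_arr) / self.spacing_arr


@dataclass
class GridField:
    """Scalar (nx,ny,nz) or 3-vector (nx,ny,nz,3) field on a GridSpec."""

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[:3] != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        if self.values.ndim not in (3, 4):
            raise ValueError("GridField is scalar (3D) or vector (4D, last axis 3)")

    @classmethod
    def zeros(cls, spec: GridSpec, vector: bool = False) -> "GridField":
        shape = spec.shape + (3,) if vector else spec.shape
        return cls(np.zeros(shape), spec)

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4


@dataclass
class PMConfig:
    """Grid + kernel pair for particle-mesh computation.

    Warns (but proceeds) when the kernel width is below the largest grid
    spacing component, the regime where the approximation degrades.
    """

    grid: GridSpec
    kernel: Kernel = field(default_factory=Kernel)

    def __post_init__(self) -> None:
        if self.kernel.width < max(self.grid.spacing):
            warnings.warn(
                f"kernel width {self.kernel.width} below grid spacing "
                f"{max(self.grid.spacing)}: particle-mesh approximation is "
                "unreliable in this regime",
                stacklevel=2,
            )


def build_grid(
    source: Anatomy | ProbabilityImageSet | Image3D | TriangleMesh | np.ndarray,
    border: int = 0,
    spacing: float | tuple[float, float, float] = 1.0,
) -> GridSpec:
    """Choose the computational lattice.

    When posterior images exist the grid *is* their lattice (no extra
    quantization error, no resampling).  For bare geometry the grid is the
    bounding box at the requested spacing, padded by ``border`` voxels on
    every side to keep deposits in bounds.
    """
    if isinstance(source, Anatomy):
        return GridSpec.of_image(source.posteriors)
    if isinstance(source, (ProbabilityImageSet, Image3D)):
        return GridSpec.of_image(source)
    if isinstance(source, TriangleMesh):
        pts = source.vertices
    else:
        pts = np.atleast_2d(np.asarray(source, dtype=np.float64))
    sp = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    n_inner = np.ceil((hi - lo) / sp - 1e-9).astype(int) + 1
    shape = tuple(int(n + 2 * border) for n in n_inner)
    origin = lo - border * sp
    return GridSpec(shape, tuple(sp), tuple(origin))


def _corner_weights(
    spec: GridSpec, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower corner indices i0, fractional offsets, in-bounds check."""
    idx = spec.world_to_index(points)
    n = np.asarray(spec.shape)
    tol = 1e-9
    bad = np.any((idx < -tol) | (idx > n - 1 + tol), axis=1)
    if np.any(bad):
        j = int(np.argmax(bad))
        raise ValueError(
            f"point {np.atleast_2d(points)[j]} outside grid extent "
            f"[{spec.origin}, {spec.origin_arr + (n - 1) * spec.spacing_arr}]"
        )
    i0 = np.clip(np.floor(idx).astype(np.int64), 0, n - 2)
    frac = np.clip(idx - i0, 0.0, 1.0)
    return i0, frac, idx


def splat(
    points: np.ndarray, values: np.ndarray, grid: GridSpec
) -> GridField:
    """Deposit point values onto the 8 enclosing nodes of each point.

    Weights are the trilinear coefficients on the fractional offsets
    (1 - {x} toward the floor node, {x} toward the ceiling node per axis),
    so the total deposited mass equals the total input mass exactly and the
    operation is the adjoint of :func:`interpolate`.  Accumulation is a
    deterministic sum, independent of point order to rounding.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    values = np.asarray(values, dtype=np.float64)
    vector = values.ndim == 2
    if vector and values.shape != (len(points), 3):
        raise ValueError("vector values must have shape (n_points, 3)")
    if not vector and values.shape != (len(points),):
        raise ValueError("scalar values must have shape (n_points,)")
    i0, frac, _ = _corner_weights(grid, points)
    out = GridField.zeros(grid, vector=vector)
    flat = out.values.reshape(-1, 3) if vector else out.values.reshape(-1)
    ny, nz = grid.shape[1], grid.shape[2]
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = wx * wy * wz
                lin = ((i0[:, 0] + dx) * ny + (i0[:, 1] + dy)) * nz + (i0[:, 2] + dz)
                if vector:
                    np.add.at(flat, lin, values * w[:, None])
                else:
                    np.add.at(flat, lin, values * w)
    return out


def interpolate(grid: GridField, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a grid field at physical points; the
    duality partner of :func:`splat` (same coefficients, gathering)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    i0, frac, _ = _corner_weights(grid.spec, points)
    vals = grid.values
    acc = np.zeros((len(points), 3)) if grid.is_vector else np.zeros(len(points))
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = wx * wy * wz
                node = vals[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                acc += node * (w[:, None] if grid.is_vector else w)
    return acc


def _kernel_lattice(
    spec: GridSpec, kernel: Kernel, derivative: int | None = None
) -> np.ndarray:
    """Kernel (or one component of its gradient) sampled at node offsets.

    The support radius is the 1e-6 relative-decay distance, capped at the
    grid's physical extent per axis: offsets beyond the extent can never
    pair a node with another node in a linear convolution restricted to
    the grid, so the cap is exact (this matters for the heavy-tailed
    Cauchy kernel).
    """
    sp = spec.spacing_arr
    extent = (np.asarray(spec.shape) - 1) * sp
    radius = np.minimum(kernel.support_radius(1e-6), extent)
    half = np.maximum(1, np.ceil(radius / sp).astype(int))
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, sp)]
    ox, oy, oz = np.meshgrid(*axes, indexing="ij")
    d2 = ox**2 + oy**2 + oz**2
    if derivative is None:
        return kernel.eval_sq(d2)
    comp = (ox, oy, oz)[derivative]
    return kernel.grad_factor(d2) * comp


# FFTs of sampled kernels are cached per (grid, kernel, derivative); the
# registration loop reuses them every iteration.
_KERNEL_FFT_CACHE: dict = {}


def _cic_compensation(fshape: tuple[int, ...]) -> np.ndarray:
    """Inverse squared spectrum of the trilinear (cloud-in-cell) window.

    Splatting and interpolation each low-pass the signal by the CIC
    window W with per-axis spectrum sinc^2(theta/2); the PM bilinear form
    therefore carries W^2 on each side of the kernel.  Dividing the
    sampled kernel's spectrum by sinc^4 per axis deconvolves both passes,
    the standard particle-mesh window correction.
    """
    freqs = [
        2.0 * np.pi * np.fft.fftfreq(fshape[0]),
        2.0 * np.pi * np.fft.fftfreq(fshape[1]),
        2.0 * np.pi * np.fft.rfftfreq(fshape[2]),
    ]
    tx, ty, tz = np.meshgrid(*freqs, indexing="ij")
    comp = np.ones(tx.shape)
    for t in (tx, ty, tz):
        comp = comp * np.sinc(t / (2.0 * np.pi)) ** 4  # sin(t/2)/(t/2) per pass
    return np.maximum(comp, 1e-4)


def _kernel_fft(
    spec: GridSpec, kernel: Kernel, derivative: int | None, deconvolve: bool = False
):
    key = (spec, kernel, derivative, deconvolve)
    hit = _KERNEL_FFT_CACHE.get(key)
    if hit is None:
        kern = _kernel_lattice(spec, kernel, derivative)
        fshape = tuple(
            next_fast_len(n + k - 1) for n, k in zip(spec.shape, kern.shape)
        )
        kfft = rfftn(kern, fshape)
        if deconvolve:
            kfft = kfft / _cic_compensation(fshape)
        if len(_KERNEL_FFT_CACHE) > 64:
            _KERNEL_FFT_CACHE.clear()
        hit = (kern.shape, fshape, kfft)
        _KERNEL_FFT_CACHE[key] = hit
    return hit


def _convolve_ffts(
    spec: GridSpec,
    comp_ffts: list[np.ndarray],
    fshape: tuple[int, ...],
    kshape: tuple[int, ...],
    kfft: np.ndarray,
) -> np.ndarray:
    crop = tuple(
        slice((k - 1) // 2, (k - 1) // 2 + n) for k, n in zip(kshape, spec.shape)
    )
    out = [irfftn(cf * kfft, fshape)[crop] for cf in comp_ffts]
    if len(out) == 1:
        return out[0]
    return np.stack(out, axis=-1)


def _warn_if_invalid(spec: GridSpec, kernel: Kernel) -> None:
    if kernel.width < max(spec.spacing):
        warnings.warn(
            f"kernel width {kernel.width} below grid spacing: validity "
            "condition of the particle-mesh approximation violated",
            stacklevel=3,
        )


def grid_convolve(
    grid: GridField, kernel: Kernel, derivative: int | None = None
) -> GridField:
    """Convolve a grid field with the sampled kernel via zero-padded FFT.

    The convolution is linear (zero padding to grid + kernel support), not
    circular.  ``derivative`` selects one analytic kernel-gradient
    component (0..2) instead of the kernel itself; used for the
    currents-gradient term.
    """
    _warn_if_invalid(grid.spec, kernel)
    kshape, fshape, kfft = _kernel_fft(grid.spec, kernel, derivative)
    comps = (
        [grid.values[..., c] for c in range(3)] if grid.is_vector else [grid.values]
    )
    comp_ffts = [rfftn(c, fshape) for c in comps]
    return GridField(
        _convolve_ffts(grid.spec, comp_ffts, fshape, kshape, kfft), grid.spec
    )


def _union_currents(fc: FaceCurrents) -> tuple[np.ndarray, np.ndarray]:
    return fc.centers, fc.normals * fc.signs[:, None]


def pm_currents_norm_sq(fc: FaceCurrents, pm: PMConfig) -> float:
    """Particle-mesh approximation of the squared currents norm.

    Splat the signed area-weighted normals at the face centroids, convolve
    each component with the kernel on the grid, interpolate back at the
    centroids, and contract with the normals.
    """
    centers, signed = _union_currents(fc)
    momentum = splat(centers, signed, pm.grid)
    _warn_if_invalid(pm.grid, pm.kernel)
    kshape, fshape, kfft = _kernel_fft(pm.grid, pm.kernel, None, deconvolve=True)
    comp_ffts = [rfftn(momentum.values[..., c], fshape) for c in range(3)]
    conv = GridField(
        _convolve_ffts(pm.grid, comp_ffts, fshape, kshape, kfft), pm.grid
    )
    back = interpolate(conv, centers)
    return float(np.einsum("ij,ij->", signed, back))


def pm_currents_dissimilarity(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh | FaceCurrents, pm: PMConfig
) -> float:
    """PM approximation of the squared currents distance (union with the
    second shape's measure negated)."""
    fb = mesh_b if isinstance(mesh_b, FaceCurrents) else face_currents(mesh_b)
    fc = face_currents(mesh_a).union(fb.negated())
    return pm_currents_norm_sq(fc, pm)


def pm_currents_gradient(
    mesh: TriangleMesh, target_fc: FaceCurrents, pm: PMConfig
) -> np.ndarray:
    """PM approximation of the currents-dissimilarity gradient.

    The exact per-face sums G(c_f) = sum_u s_u k(c_f, c_u) eta(u) and the
    kernel-derivative sums are replaced by interpolation, at the face
    centroids, of the splatted momentum field convolved with the kernel
    and with its three analytic gradient components.
    """
    moving = face_currents(mesh)
    union = moving.union(
        FaceCurrents(target_fc.centers, target_fc.normals, -target_fc.signs)
    )
    centers, signed = _union_currents(union)
    momentum = splat(centers, signed, pm.grid)
    _warn_if_invalid(pm.grid, pm.kernel)
    # one forward FFT per momentum component, shared by the four kernels
    kshape, fshape, kfft = _kernel_fft(pm.grid, pm.kernel, None, deconvolve=True)
    comp_ffts = [rfftn(momentum.values[..., c], fshape) for c in range(3)]
    conv = GridField(
        _convolve_ffts(pm.grid, comp_ffts, fshape, kshape, kfft), pm.grid
    )
    G = interpolate(conv, moving.centers)
    # W_d(c_f) = sum_m eta_f[m] * (d_d k * momentum_m)(c_f)
    W = np.zeros_like(moving.centers)
    for d in range(3):
        dk_shape, dk_fshape, dk_fft = _kernel_fft(
            pm.grid, pm.kernel, d, deconvolve=True
        )
        assert dk_fshape == fshape  # same support radius as the plain kernel
        dconv = GridField(
            _convolve_ffts(pm.grid, comp_ffts, dk_fshape, dk_shape, dk_fft),
            pm.grid,
        )
        vals = interpolate(dconv, moving.centers)
        W[:, d] = np.einsum("ij,ij->i", vals, moving.normals)
    return assemble_vertex_gradient(mesh, G, W)
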