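"""Large-deformation machinery.

A diffeomorphism is built greedily: each iteration solves the fluid PDE
L v = F for a velocity field, where L = -alpha lap - beta grad div + gamma
is the (positive-definite) Cauchy-Navier operator, then composes a small
Euler step into the running deformation.  Images are warped by *backward*
mapping (sample the source at h^-1(x), no holes); geometry integrates
*forward* (vertices move along +v), keeping the two compartments of an
anatomy consistent.

The inverse map is stored as a dense displacement field u on the image
lattice, h^-1(x) = x + u(x); the recursion for the update is
h^-1_t(x) = h^-1_{t-1}(x + dt v(x)), evaluated by trilinear interpolation
with clamp-to-edge boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.fft import irfftn, rfftn
from scipy.ndimage import map_coordinates

from careg.anatomy import Image3D, ProbabilityImageSet, TriangleMesh
from careg.particle_mesh import GridField, GridSpec

__all__ = [
    "DiffOperatorParams",
    "Deformation",
    "solve_L",
    "apply_L",
    "compose_step",
    "pull_back_image",
    "push_forward_mesh",
    "jacobian_determinant",
    "save_deformation",
    "load_deformation",
]


@dataclass(frozen=True)
class DiffOperatorParams:
    """Coefficients of L = -alpha lap - beta grad div + gamma.

    alpha penalizes non-smooth velocity, beta couples components through
    the divergence, gamma > 0 keeps the operator invertible (and bounds
    the velocity magnitude).  All act on the discrete central-difference
    stencils, so the Fourier symbol is exact for the discrete operator.
    """

    alpha: float = 0.01
    beta: float = 0.01
    gamma: float = 0.001

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not self.gamma > 0:
            raise ValueError(
                "gamma must be strictly positive: with gamma = 0 the operator "
                "annihilates constant fields and the system is singular"
            )


@dataclass
class Deformation:
    """Dense inverse map h^-1(x) = x + disp(x) on a regular lattice.

    ``disp`` stores the displacement (not the absolute position); the
    deformation is a valid diffeomorphism when the Jacobian determinant of
    h^-1 is positive at all interior nodes.
    """

    disp: GridField

    def __post_init__(self) -> None:
        if not self.disp.is_vector:
            raise ValueError("deformation displacement must be a vector field")
        if not np.all(np.isfinite(self.disp.values)):
            raise ValueError("deformation contains non-finite values")

    @classmethod
    def identity(cls, spec: GridSpec) -> "Deformation":
        return cls(GridField.zeros(spec, vector=True))

    @property
    def spec(self) -> GridSpec:
        return self.disp.spec

    def phi_inv(self) -> np.ndarray:
        """Absolute source positions h^-1(x) at every node, (nx,ny,nz,3)."""
        return _node_positions(self.spec) + self.disp.values


def _node_positions(spec: GridSpec) -> np.ndarray:
    axes = [
        o + np.arange(n) * s
        for n, s, o in zip(spec.shape, spec.spacing, spec.origin)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _symbols(spec: GridSpec):
    """Central-difference Laplacian and first-derivative Fourier symbols
    on the rfft frequency lattice."""
    n = spec.shape
    sp = spec.spacing
    thetas = [
        2.0 * np.pi * np.fft.fftfreq(n[0]),
        2.0 * np.pi * np.fft.fftfreq(n[1]),
        2.0 * np.pi * np.fft.rfftfreq(n[2]),
    ]
    tx, ty, tz = np.meshgrid(*thetas, indexing="ij")
    lap = (
        (2.0 * np.cos(tx) - 2.0) / sp[0] ** 2
        + (2.0 * np.cos(ty) - 2.0) / sp[1] ** 2
        + (2.0 * np.cos(tz) - 2.0) / sp[2] ** 2
    )
    s = np.stack(
        [np.sin(tx) / sp[0], np.sin(ty) / sp[1], np.sin(tz) / sp[2]], axis=-1
    )
    return lap, s


def solve_L(force: GridField, params: DiffOperatorParams) -> GridField:
    """Solve L v = F in the Fourier domain (periodic boundary).

    The 3x3 symbol per frequency is A = a I + beta s s^T with
    a = gamma - alpha * lap_symbol > 0 and s the central first-difference
    symbols; it is inverted in closed form (Sherman-Morrison).  Cost is
    O(M log M) in the number of grid nodes.
    """
    if not force.is_vector:
        raise ValueError("force must be a 3-vector field")
    spec = force.spec
    lap, s = _symbols(spec)
    a = params.gamma - params.alpha * lap
    fhat = np.stack(
        [rfftn(force.values[..., c]) for c in range(3)], axis=-1
    )
    if params.beta == 0.0:
        vhat = fhat / a[..., None]
    else:
        s2 = np.einsum("...i,...i->...", s, s)
        sf = np.einsum("...i,...i->...", s, fhat)
        vhat = fhat / a[..., None] - (
            (params.beta * sf / (a * (a + params.beta * s2)))[..., None] * s
        )
    v = np.stack(
        [irfftn(vhat[..., c], spec.shape) for c in range(3)], axis=-1
    )
    return GridField(v, spec)


def apply_L(v: GridField, params: DiffOperatorParams) -> GridField:
    """Apply the discrete operator L with periodic central differences;
    the residual oracle for :func:`solve_L`."""
    vals = v.values
    sp = v.spec.spacing
    lap = np.zeros_like(vals)
    for ax in range(3):
        lap += (
            np.roll(vals, 1, axis=ax) + np.roll(vals, -1, axis=ax) - 2.0 * vals
        ) / sp[ax] ** 2
    div = np.zeros(vals.shape[:3])
    for ax in range(3):
        div += (
            np.roll(vals[..., ax], -1, axis=ax) - np.roll(vals[..., ax], 1, axis=ax)
        ) / (2.0 * sp[ax])
    graddiv = np.stack(
        [
            (np.roll(div, -1, axis=ax) - np.roll(div, 1, axis=ax)) / (2.0 * sp[ax])
            for ax in range(3)
        ],
        axis=-1,
    )
    out = -params.alpha * lap - params.beta * graddiv + params.gamma * vals
    return GridField(out, v.spec)


def _sample_field(values: np.ndarray, spec: GridSpec, points: np.ndarray) -> np.ndarray:
    """Trilinear sampling with clamp-to-edge; accepts scalar or vector values."""
    idx = spec.world_to_index(points)
    coords = [idx[:, 0], idx[:, 1], idx[:, 2]]
    if values.ndim == 3:
        return map_coordinates(values, coords, order=1, mode="nearest")
    return np.stack(
        [
            map_coordinates(values[..., c], coords, order=1, mode="nearest")
            for c in range(values.shape[-1])
        ],
        axis=-1,
    )


def compose_step(deformation: Deformation, v: GridField, dt: float) -> Deformation:
    """One Euler step of the inverse-map recursion.

    h^-1_new(x) = h^-1_old(x + dt v(x)); in displacement form
    u_new(x) = dt v(x) + u_old(x + dt v(x)), the old displacement
    interpolated trilinearly (clamp-to-edge).  v = 0 is an exact fixed
    point.
    """
    spec = deformation.spec
    if dt == 0.0 or not np.any(v.values):
        return Deformation(GridField(deformation.disp.values.copy(), spec))
    pos = _node_positions(spec)
    shifted = (pos + dt * v.values).reshape(-1, 3)
    u_old = _sample_field(deformation.disp.values, spec, shifted).reshape(
        spec.shape + (3,)
    )
    return Deformation(GridField(dt * v.values + u_old, spec))


def pull_back_image(
    img: Image3D | ProbabilityImageSet, deformation: Deformation
):
    """Backward-map an image through the deformation: out(x) = in(h^-1(x)).

    Trilinear interpolation with clamp-to-edge, so probabilities stay in
    [0, 1] (convex combination) and no posterior mass is invented at the
    boundary.  The image lattice need not coincide with the deformation
    lattice; the displacement is resampled at the image nodes if needed.
    """
    if isinstance(img, ProbabilityImageSet):
        channels = [pull_back_image(ch, deformation) for ch in img.channels]
        return ProbabilityImageSet(channels, list(img.class_names))
    spec = GridSpec.of_image(img)
    pos = _node_positions(spec).reshape(-1, 3)
    if spec == deformation.spec:
        src = pos + deformation.disp.values.reshape(-1, 3)
    else:
        u = _sample_field(deformation.disp.values, deformation.spec, pos)
        src = pos + u
    out = _sample_field(img.values, spec, src).reshape(img.shape)
    return Image3D(out, img.spacing, img.origin)


def push_forward_mesh(mesh: TriangleMesh, v: GridField, dt: float) -> TriangleMesh:
    """Advance mesh vertices one Euler step along the velocity field.

    Geometry integrates forward (x <- x + dt v(x)) while images compose
    the inverse map; in the greedy small-step regime the forward field is
    the reverse field with its direction inverted, i.e. +v itself.
    """
    vel = _sample_field(v.values, v.spec, mesh.vertices)
    return TriangleMesh(mesh.vertices + dt * vel, mesh.faces.copy(), mesh.name)


def jacobian_determinant(deformation: Deformation) -> Image3D:
    """Jacobian determinant of h^-1 at every node.

    Central differences at interior nodes, one-sided at the boundary; a
    valid diffeomorphism has strictly positive interior values.
    """
    spec = deformation.spec
    phi = deformation.phi_inv()
    J = np.empty(spec.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(phi[..., comp], *spec.spacing, edge_order=1)
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    det = np.linalg.det(J)
    return Image3D(det, spec.spacing_arr, spec.origin_arr)


def save_deformation(deformation: Deformation, path: str) -> None:
    """Write the displacement field as a 4D NIfTI (last axis = component).

    The header description records the convention: values are the
    displacement u with h^-1(x) = x + u(x), in world units.
    """
    spec = deformation.spec
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spec.spacing)
    affine[:3, 3] = spec.origin
    img = nib.Nifti1Image(deformation.disp.values, affine)
    img.header["descrip"] = b"displacement u: h_inv(x) = x + u(x)"
    nib.save(img, path)


def load_deformation(path: str) -> Deformation:
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 5:  # NIfTI vector convention (nx,ny,nz,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected a 3-component displacement field: {path}")
    affine = img.affine
    spacing = np.diag(affine[:3, :3]).copy()
    if not np.allclose(affine[:3, :3], np.diag(spacing), atol=1e-6) or np.any(
        spacing <= 0
    ):
        raise ValueError(f"unsupported deformation orientation: {path}")
    spec = GridSpec(data.shape[:3], tuple(spacing), tuple(affine[:3, 3]))
    return Deformation(GridField(data, spec))
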