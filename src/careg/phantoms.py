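"""Synthetic anatomy phantoms with known ground-truth deformations.

Geometric label maps (sphere, ellipsoid, nested tissue shells, sphere
with a bump) are built analytically on a lattice, softened into posterior
probability channels by Gaussian smoothing of the one-hot indicator
(including the background channel, so the per-voxel partition of unity is
preserved exactly and the channel sum never exceeds 1), and surfaces are
extracted from the MAP label map by marching cubes.  Analytic
diffeomorphisms (translation, scaling, Gaussian bump) then produce warped
"target" anatomies, giving every registration experiment a known answer
without any external data.

The smoothing width (default 1 voxel) is what gives the posteriors
nonzero image gradients — the greedy image force needs them — while
leaving the MAP labels of the interior unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from careg.anatomy import (
    Anatomy,
    Image3D,
    LabelMap,
    ProbabilityImageSet,
    extract_surface,
)
from careg.deformation import Deformation
from careg.particle_mesh import GridField, GridSpec

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "make_phantom",
    "make_ground_truth_deformation",
    "deform_phantom",
]

_SHAPES = ("sphere", "ellipsoid", "two_tissue_nested", "sphere_with_bump")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling of a synthetic anatomy.

    ``radius`` is in voxels; ``semiaxes`` (ellipsoid) and the nested-shell
    radii are derived from it.  The grid must leave a 4-voxel margin
    around the shape.
    """

    shape: str = "sphere"
    grid_size: int = 48
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius: float = 10.0
    smooth_sigma: float = 1.0  # voxels
    bump_height: float = 4.0  # voxels, sphere_with_bump only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown phantom shape {self.shape!r}; one of {_SHAPES}")
        max_extent = self.radius + (
            self.bump_height if self.shape == "sphere_with_bump" else 0.0
        )
        if self.grid_size / 2 - max_extent < 4:
            raise ValueError(
                f"grid size {self.grid_size} too small for radius {self.radius} "
                "plus a 4-voxel margin"
            )


def _index_radii(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = spec.grid_size
    c = (n - 1) / 2.0
    ax = np.arange(n) - c
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _label_volume(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, str]]:
    x, y, z = _index_radii(spec)
    r = np.sqrt(x**2 + y**2 + z**2)
    if spec.shape == "sphere":
        return (r <= spec.radius).astype(np.int32), {1: "tissue"}
    if spec.shape == "ellipsoid":
        a, b, c = spec.radius, 0.8 * spec.radius, 0.65 * spec.radius
        q = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
        return (q <= 1.0).astype(np.int32), {1: "tissue"}
    if spec.shape == "two_tissue_nested":
        # wm core, gm shell, csf rim
        r_wm = 0.55 * spec.radius
        r_gm = 0.85 * spec.radius
        labels = np.zeros_like(r, dtype=np.int32)
        labels[r <= spec.radius] = 3
        labels[r <= r_gm] = 2
        labels[r <= r_wm] = 1
        return labels, {1: "wm", 2: "gm", 3: "csf"}
    # sphere_with_bump: radius grows by a Gaussian lobe around one axis
    theta = np.arccos(np.clip(np.where(r > 0, x / np.maximum(r, 1e-12), 1.0), -1, 1))
    local_r = spec.radius + spec.bump_height * np.exp(-((theta / 0.5) ** 2))
    return (r <= local_r).astype(np.int32), {1: "tissue"}


def make_phantom(spec: PhantomSpec) -> tuple[Anatomy, LabelMap]:
    """Build (Anatomy, LabelMap) for a phantom spec.

    Posterior channels are Gaussian-smoothed one-hot indicators of the
    analytic labels; surfaces come from marching cubes on each foreground
    label.  Deterministic for a given spec.
    """
    labels_arr, names = _label_volume(spec)
    spacing = np.asarray(spec.spacing)
    origin = np.zeros(3)
    labels = LabelMap(labels_arr, spacing, origin, names)

    label_ids = sorted(names)
    onehot = [(labels_arr == 0).astype(np.float64)] + [
        (labels_arr == i).astype(np.float64) for i in label_ids
    ]
    smoothed = [gaussian_filter(ch, sigma=spec.smooth_sigma) for ch in onehot]
    channels = [
        Image3D(np.clip(s, 0.0, 1.0), spacing, origin) for s in smoothed[1:]
    ]
    posteriors = ProbabilityImageSet(channels, [names[i] for i in label_ids])

    surface_ids = (
        label_ids[:-1] if spec.shape == "two_tissue_nested" else label_ids
    )  # the csf rim carries no surface
    surfaces = [extract_surface(labels, i) for i in surface_ids]
    return Anatomy(posteriors, surfaces), labels


@dataclass
class GroundTruthDeformation:
    """Analytic diffeomorphism with exact forward and inverse maps."""

    kind: str
    forward: callable = field(repr=False)
    inverse: callable = field(repr=False)

    def to_deformation(self, grid: GridSpec) -> Deformation:
        pos = _grid_positions(grid)
        u = self.inverse(pos.reshape(-1, 3)).reshape(pos.shape) - pos
        return Deformation(GridField(u, grid))


def _grid_positions(spec: GridSpec) -> np.ndarray:
    axes = [
        o + np.arange(n) * s
        for n, s, o in zip(spec.shape, spec.spacing, spec.origin)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def make_ground_truth_deformation(
    kind: str,
    magnitude,
    grid: GridSpec,
    center: np.ndarray | None = None,
    width: float | None = None,
) -> GroundTruthDeformation:
    """Analytic diffeomorphic map for recovery experiments.

    kind='translation': magnitude is a 3-vector (or scalar along x) in
    physical units; forward x + t.
    kind='scaling': magnitude is the scale factor s about the grid center.
    kind='gaussian_bump': displacement a * exp(-|x-x0|^2 / (2 w^2)) along
    x, with a = magnitude and w = ``width`` (default 1/6 of the extent);
    rejected at construction when it is not invertible (max |grad u| >= 1).
    """
    spacing = grid.spacing_arr
    extent = (np.asarray(grid.shape) - 1) * spacing
    c = (
        np.asarray(center, dtype=np.float64)
        if center is not None
        else grid.origin_arr + extent / 2.0
    )
    if kind == "translation":
        t = np.broadcast_to(
            np.asarray(magnitude, dtype=np.float64), (3,)
        ).copy() if np.ndim(magnitude) else np.array([float(magnitude), 0.0, 0.0])
        forward = lambda x: x + t
        inverse = lambda x: x - t
    elif kind == "scaling":
        s = float(magnitude)
        if s <= 0:
            raise ValueError("scale factor must be positive")
        forward = lambda x: c + s * (x - c)
        inverse = lambda x: c + (x - c) / s
    elif kind == "gaussian_bump":
        a = float(magnitude)
        w = float(width) if width is not None else float(extent.min()) / 6.0
        # max |d u / d x| = |a| * exp(-1/2) / w along the bump axis
        if abs(a) * np.exp(-0.5) / w >= 1.0:
            raise ValueError(
                f"gaussian bump amplitude {a} with width {w} is not invertible "
                "(displacement gradient reaches 1)"
            )
        direction = np.array([1.0, 0.0, 0.0])

        def forward(x):
            x = np.atleast_2d(x)
            g = np.exp(-np.sum((x - c) ** 2, axis=1) / (2.0 * w**2))
            return x + a * g[:, None] * direction

        def inverse(x):
            x = np.atleast_2d(x)
            y = x.copy()
            for _ in range(30):  # contraction fixed point: y = x - u(y)
                g = np.exp(-np.sum((y - c) ** 2, axis=1) / (2.0 * w**2))
                y = x - a * g[:, None] * direction
            return y
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")

    gt = GroundTruthDeformation(kind, forward, inverse)
    from careg.deformation import jacobian_determinant

    det = jacobian_determinant(gt.to_deformation(grid))
    interior = det.values[1:-1, 1:-1, 1:-1]
    if interior.min() <= 0:
        raise ValueError(
            f"{kind} deformation of magnitude {magnitude} is not invertible "
            f"(min interior Jacobian determinant {interior.min():.4f})"
        )
    return gt


def deform_phantom(
    anatomy: Anatomy, labelmap: LabelMap, gt: GroundTruthDeformation
) -> tuple[Anatomy, LabelMap]:
    """Warp a phantom by an analytic map: posteriors pull back through the
    inverse, meshes move forward through the exact map, and labels are
    warped nearest-neighbor (so integer translations shift them exactly)."""
    grid = GridSpec.of_image(anatomy.posteriors)
    deformation = gt.to_deformation(grid)
    from careg.deformation import pull_back_image

    posteriors = pull_back_image(anatomy.posteriors, deformation)
    surfaces = [
        type(m)(gt.forward(m.vertices), m.faces.copy(), m.name)
        for m in anatomy.surfaces
    ]
    pos = _grid_positions(grid).reshape(-1, 3)
    src = gt.inverse(pos)
    idx = (src - grid.origin_arr) / grid.spacing_arr
    warped_labels = map_coordinates(
        labelmap.labels.astype(np.float64),
        [idx[:, 0], idx[:, 1], idx[:, 2]],
        order=0,
        mode="nearest",
    ).reshape(labelmap.labels.shape)
    labels = LabelMap(
        np.rint(warped_labels).astype(labelmap.labels.dtype),
        labelmap.spacing,
        labelmap.origin,
        dict(labelmap.label_names),
    )
    return Anatomy(posteriors, surfaces), labels
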