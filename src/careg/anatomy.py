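"""Multicompartment anatomy model and I/O.

An anatomy couples two views of the same subject on one physical
coordinate frame: per-tissue class-posterior probability images
(p_wm, p_gm, p_csf, ...) and oriented triangle meshes of the tissue
boundaries.  Voxel index ``i`` maps to the physical point
``origin + i * spacing`` (0-based indices, world units throughout).

Surfaces are derived from the posteriors by taking the maximum a
posteriori (MAP) label map and running marching cubes on each label's
binary mask; meshes are oriented with outward normals, which the
sign-sensitive currents norm relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import trimesh
from skimage import measure

__all__ = [
    "Image3D",
    "ProbabilityImageSet",
    "TriangleMesh",
    "Anatomy",
    "LabelMap",
    "load_image",
    "save_image",
    "load_mesh",
    "save_mesh",
    "load_anatomy",
    "save_anatomy",
    "map_labels",
    "extract_surface",
    "merge_channels",
]

_PROB_SUM_TOL = 1e-6


@dataclass
class Image3D:
    """Scalar field on a regular 3D lattice in physical coordinates."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other: "Image3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ProbabilityImageSet:
    """Ordered tissue-class posterior channels sharing one lattice.

    Per voxel every channel lies in [0, 1] and the channel sum is at most
    1 (the remainder is implied background probability).
    """

    channels: list[Image3D]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("at least one channel is required")
        if len(self.channels) != len(self.class_names):
            raise ValueError("one class name per channel is required")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if not ref.same_lattice(ch):
                raise ValueError("all channels must share lattice, spacing and origin")
        stack = self.stack()
        if stack.min() < -_PROB_SUM_TOL or stack.max() > 1 + _PROB_SUM_TOL:
            raise ValueError("posterior values must lie in [0, 1]")
        total = stack.sum(axis=0)
        if total.max() > 1 + 1e-3:
            raise ValueError(
                f"per-voxel channel sum exceeds 1 (max {total.max():.6f})"
            )

    def stack(self) -> np.ndarray:
        """Channels as a (C, nx, ny, nz) array."""
        return np.stack([ch.values for ch in self.channels], axis=0)

    @property
    def spacing(self) -> np.ndarray:
        return self.channels[0].spacing

    @property
    def origin(self) -> np.ndarray:
        return self.channels[0].origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape


@dataclass
class TriangleMesh:
    """Triangle mesh with vertices in physical coordinates.

    Faces are index triples; consistent outward orientation is assumed
    (and produced by :func:`extract_surface`) but not enforced.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite values")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of vertex range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                & (self.faces[:, 1] == self.faces[:, 2])
            )
            if np.any(same):
                raise ValueError("degenerate face with three identical indices")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)


@dataclass
class Anatomy:
    """A subject: posterior probability images plus boundary surfaces."""

    posteriors: ProbabilityImageSet
    surfaces: list[TriangleMesh] = field(default_factory=list)


@dataclass
class LabelMap:
    """Integer segmentation on an image lattice; 0 is background."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)


# ---------------------------------------------------------------------------
# image I/O


def load_image(path: str) -> Image3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume.

    The affine must be axis-aligned with positive scales; images with
    rotations or flips are rejected rather than silently reoriented.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        affine = img.affine
        linear = affine[:3, :3]
        spacing = np.diag(linear).copy()
        if not np.allclose(linear, np.diag(spacing), atol=1e-6) or np.any(
            spacing <= 0
        ):
            raise ValueError(
                f"unsupported NIfTI orientation (non axis-aligned affine): {path}"
            )
        origin = affine[:3, 3].copy()
    elif low.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=np.float64)
        origin = np.asarray(img.GetOrigin(), dtype=np.float64)
    else:
        raise ValueError(f"unsupported image format: {path}")
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar image, got shape {data.shape}: {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"image contains non-finite voxels: {path}")
    return Image3D(data, spacing, origin)


def save_image(img: Image3D, path: str) -> None:
    """Write an :class:`Image3D` as NIfTI or MetaImage."""
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(img.spacing)
        affine[:3, 3] = img.origin
        nib.save(nib.Nifti1Image(img.values, affine), path)
    elif low.endswith((".mha", ".mhd")):
        out = sitk.GetImageFromArray(img.values.transpose(2, 1, 0))
        out.SetSpacing(tuple(float(s) for s in img.spacing))
        out.SetOrigin(tuple(float(o) for o in img.origin))
        sitk.WriteImage(out, path)
    else:
        raise ValueError(f"unsupported image format: {path}")


# ---------------------------------------------------------------------------
# mesh I/O
#
# OBJ and PLY go through trimesh; VTK legacy ASCII polydata has no reader in
# the installed stack so a minimal one lives here.  ASCII files are
# pre-scanned for non-triangular faces: loading fails explicitly instead of
# silently triangulating.


def _scan_obj_triangles(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if parts and parts[0] == "f" and len(parts) != 4:
                raise ValueError(
                    f"non-triangular face (line {lineno}) in {path}; "
                    "only triangle meshes are supported"
                )


def _scan_ply_triangles(path: str) -> None:
    with open(path, "rb") as fh:
        header = fh.readline()
        if not header.startswith(b"ply"):
            raise ValueError(f"not a PLY file: {path}")
        fmt_ascii = False
        n_face = 0
        current = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"truncated PLY header: {path}")
            toks = line.split()
            if not toks:
                continue
            if toks[0] == b"format":
                fmt_ascii = toks[1] == b"ascii"
            elif toks[0] == b"element":
                current = toks[1]
                if current == b"face":
                    n_face = int(toks[2])
            elif toks[0] == b"end_header":
                break
        if not fmt_ascii:
            return  # binary PLY: trust trimesh's triangle output
        # ascii body: vertices first, then faces whose first token is a count
        lines = [ln for ln in fh.read().split(b"\n") if ln.strip()]
        for ln in lines[-n_face:] if n_face else []:
            if int(ln.split()[0]) != 3:
                raise ValueError(
                    f"non-triangular face in {path}; only triangle meshes are supported"
                )


def _load_vtk_polydata(path: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        ip = [t.upper() for t in tokens].index("POINTS")
        n_pts = int(tokens[ip + 1])
        coords = np.array(
            tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=np.float64
        ).reshape(n_pts, 3)
        upper = [t.upper() for t in tokens]
        ic = upper.index("POLYGONS")
        n_poly = int(tokens[ic + 1])
        body = tokens[ic + 3 :]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse VTK legacy polydata: {path}") from exc
    faces = []
    pos = 0
    for _ in range(n_poly):
        cnt = int(body[pos])
        if cnt != 3:
            raise ValueError(
                f"non-triangular polygon ({cnt} vertices) in {path}; "
                "only triangle meshes are supported"
            )
        faces.append([int(body[pos + 1]), int(body[pos + 2]), int(body[pos + 3])])
        pos += cnt + 1
    return coords, np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def load_mesh(path: str) -> TriangleMesh:
    """Read a triangle mesh from VTK legacy polydata, OBJ, or PLY."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"mesh file not found: {path}")
    low = path.lower()
    name = os.path.splitext(os.path.basename(path))[0]
    if low.endswith(".vtk"):
        verts, faces = _load_vtk_polydata(path)
        return TriangleMesh(verts, faces, name)
    if low.endswith(".obj"):
        _scan_obj_triangles(path)
    elif low.endswith(".ply"):
        _scan_ply_triangles(path)
    else:
        raise ValueError(f"unsupported mesh format: {path}")
    loaded = trimesh.load(path, process=False, force="mesh")
    return TriangleMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces), name)


def save_mesh(mesh: TriangleMesh, path: str) -> None:
    """Write a triangle mesh as VTK legacy polydata, OBJ, or PLY (ascii)."""
    low = path.lower()
    if low.endswith(".vtk"):
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"{mesh.name or 'mesh'}\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(mesh.vertices)} double\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif low.endswith(".obj"):
        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(path)
    elif low.endswith(".ply"):
        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(
            path, encoding="ascii"
        )
    else:
        raise ValueError(f"unsupported mesh format: {path}")


# ---------------------------------------------------------------------------
# anatomy directories: posteriors + meshes + a small manifest


def save_anatomy(anatomy: Anatomy, directory: str) -> None:
    """Write an anatomy as a directory of NIfTI posteriors, VTK surfaces
    and an ``anatomy.yaml`` manifest recording channel order."""
    import yaml

    os.makedirs(directory, exist_ok=True)
    manifest = {"posteriors": [], "surfaces": []}
    for name, ch in zip(anatomy.posteriors.class_names, anatomy.posteriors.channels):
        fname = f"posterior_{name}.nii.gz"
        save_image(ch, os.path.join(directory, fname))
        manifest["posteriors"].append({"class": name, "file": fname})
    for i, mesh in enumerate(anatomy.surfaces):
        fname = f"surface_{mesh.name or i}.vtk"
        save_mesh(mesh, os.path.join(directory, fname))
        manifest["surfaces"].append({"name": mesh.name, "file": fname})
    with open(os.path.join(directory, "anatomy.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_anatomy(directory: str) -> Anatomy:
    """Read an anatomy directory written by :func:`save_anatomy`."""
    import yaml

    manifest_path = os.path.join(directory, "anatomy.yaml")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no anatomy.yaml manifest in {directory}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    channels = []
    names = []
    for entry in manifest.get("posteriors", []):
        channels.append(load_image(os.path.join(directory, entry["file"])))
        names.append(entry["class"])
    surfaces = []
    for entry in manifest.get("surfaces", []):
        mesh = load_mesh(os.path.join(directory, entry["file"]))
        mesh.name = entry.get("name", mesh.name)
        surfaces.append(mesh)
    return Anatomy(ProbabilityImageSet(channels, names), surfaces)


# ---------------------------------------------------------------------------
# posterior -> label map -> surface pipeline


def map_labels(posteriors: ProbabilityImageSet) -> LabelMap:
    """MAP segmentation of a posterior set.

    Per voxel the label is ``1 + argmax_c p_c`` when the winning class beats
    the implied background probability ``1 - sum_c p_c``, else 0.  Ties break
    toward the lowest channel index.
    """
    stack = posteriors.stack()
    background = 1.0 - stack.sum(axis=0)
    best = np.argmax(stack, axis=0)
    best_p = np.take_along_axis(stack, best[None], axis=0)[0]
    labels = np.where(best_p > background, best + 1, 0).astype(np.int32)
    names = {i + 1: n for i, n in enumerate(posteriors.class_names)}
    return LabelMap(labels, posteriors.spacing, posteriors.origin, names)


def _decimate_vertex_clustering(
    verts: np.ndarray, faces: np.ndarray, target_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform decimation by snapping vertices to a coarser lattice.

    Cell size grows until the face count is at or below the target
    fraction; deterministic, topology not guaranteed.
    """
    target = max(4, int(round(target_fraction * len(faces))))
    lo = verts.min(axis=0)
    extent = float(np.max(verts.max(axis=0) - lo))
    cell = extent / max(4, int(round(len(faces) ** 0.5)))
    for _ in range(40):
        key = np.floor((verts - lo) / cell).astype(np.int64)
        _, inverse = np.unique(key, axis=0, return_inverse=True)
        new_faces = inverse[faces]
        ok = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[ok]
        if len(new_faces) <= target:
            n_new = inverse.max() + 1
            sums = np.zeros((n_new, 3))
            counts = np.zeros(n_new)
            np.add.at(sums, inverse, verts)
            np.add.at(counts, inverse, 1.0)
            new_verts = sums / counts[:, None]
            used = np.unique(new_faces)
            remap = -np.ones(n_new, dtype=np.int64)
            remap[used] = np.arange(len(used))
            return new_verts[used], remap[new_faces]
        cell *= 1.3
    raise RuntimeError("decimation failed to reach the target face count")


def extract_surface(
    labels: LabelMap,
    label_id: int,
    decimation_fraction: float | None = None,
    presmooth_sigma: float = 1.0,
) -> TriangleMesh:
    """Marching-cubes isosurface of one label at iso-level 0.5.

    The binary indicator is first smoothed by ``presmooth_sigma`` voxels
    (0 disables): running marching cubes on the raw indicator inflates
    surface area by a staircase factor of roughly 9% that does not vanish
    with resolution, while the smoothed indicator recovers e.g. a sphere's
    analytic area to ~2%.  Vertices are returned in physical coordinates
    and faces are ordered so area-weighted normals point out of the
    labeled region.
    """
    mask = labels.labels == label_id
    if not np.any(mask):
        raise ValueError(f"label {label_id} absent from label map")
    volume = mask.astype(np.float64)
    if presmooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(volume, presmooth_sigma)
        if smoothed.max() > 0.5:  # tiny labels may fall below the iso-level
            volume = smoothed
    verts, faces, _, _ = measure.marching_cubes(
        volume, level=0.5, spacing=tuple(labels.spacing)
    )
    verts = verts + labels.origin
    # orient outward: signed volume (1/3) sum <c_f, eta_f> must be positive
    tri = verts[faces]
    eta = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centers = tri.mean(axis=1)
    if np.einsum("ij,ij->", centers, eta) < 0:
        faces = faces[:, ::-1]
    if decimation_fraction is not None and decimation_fraction < 1.0:
        verts, faces = _decimate_vertex_clustering(verts, faces, decimation_fraction)
    name = labels.label_names.get(label_id, f"label_{label_id}")
    return TriangleMesh(verts, faces, name)


def merge_channels(
    posteriors: ProbabilityImageSet, channel_ids: list[int], new_name: str
) -> ProbabilityImageSet:
    """Sum the listed channels voxel-wise into a single channel.

    Used e.g. to fold myelinated and nonmyelinated white matter into one
    white-matter class so neonatal and mature anatomies become comparable.
    Total per-voxel probability mass is preserved exactly.
    """
    ids = list(channel_ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate channel ids: {ids}")
    n = len(posteriors.channels)
    if any(i < 0 or i >= n for i in ids):
        raise ValueError(f"channel id out of range: {ids}")
    merged_values = sum(posteriors.channels[i].values for i in ids)
    ref = posteriors.channels[ids[0]]
    merged = Image3D(merged_values, ref.spacing, ref.origin)
    channels: list[Image3D] = []
    names: list[str] = []
    placed = False
    for i, (ch, nm) in enumerate(zip(posteriors.channels, posteriors.class_names)):
        if i in ids:
            if not placed:
                channels.append(merged)
                names.append(new_name)
                placed = True
        else:
            channels.append(ch)
            names.append(nm)
    return ProbabilityImageSet(channels, names)
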