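"""Shared fixtures: random meshes and the heavyweight phantom-registration
runs, computed once per session and reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from careg.anatomy import TriangleMesh, map_labels
from careg.currents import Kernel
from careg.deformation import DiffOperatorParams
from careg.particle_mesh import GridSpec
from careg.phantoms import (
    PhantomSpec,
    deform_phantom,
    make_ground_truth_deformation,
    make_phantom,
)
from careg.registration import RegistrationConfig, Stage, energy, overlap, register


def random_mesh(
    n_vertices: int, n_faces: int, seed: int, center=16.0, scale=4.0
) -> TriangleMesh:
    """Random triangle soup: valid for currents computations (no manifold
    structure needed), kept well inside a [0, 32]^3 box."""
    rng = np.random.default_rng(seed)
    verts = rng.normal(size=(n_vertices, 3)) * scale + center
    faces = rng.integers(0, n_vertices, size=(4 * n_faces, 3))
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return TriangleMesh(verts, faces[ok][:n_faces])


@pytest.fixture(scope="session")
def sphere_phantom():
    anatomy, labels = make_phantom(PhantomSpec(radius=10, grid_size=48))
    return anatomy, labels


@pytest.fixture(scope="session")
def sphere_recovery(sphere_phantom):
    """Translated-sphere recovery: 48^3 grid, 3-voxel shift, single
    sigma=8 stage.  Returns everything criterion checks need."""
    anatomy, labels = sphere_phantom
    grid = GridSpec.of_image(anatomy.posteriors)
    gt = make_ground_truth_deformation("translation", 3.0, grid)
    target, target_labels = deform_phantom(anatomy, labels, gt)
    config = RegistrationConfig(kernel_schedule=[Stage(8.0, 0.4, 60)])
    result = register(anatomy, target, config)
    return {
        "moving": anatomy,
        "moving_labels": labels,
        "target": target,
        "target_labels": target_labels,
        "config": config,
        "result": result,
        "baseline_overlap": overlap(labels, target_labels, 1),
        "final_overlap": overlap(
            map_labels(result.deformed.posteriors), target_labels, 1
        ),
    }


@pytest.fixture(scope="session")
def multiscale_runs():
    """Bump-phantom surface matching under three schedules with a shared
    iteration budget; final states scored with the common fine kernel.
    The localized operator (gamma = 0.01) keeps the velocity short-range,
    which is the regime where a single fine kernel gets trapped."""
    anatomy, labels = make_phantom(
        PhantomSpec("sphere_with_bump", radius=8, grid_size=40, bump_height=3)
    )
    grid = GridSpec.of_image(anatomy.posteriors)
    gt = make_ground_truth_deformation("translation", (5.0, 5.0, 0.0), grid)
    target, _ = deform_phantom(anatomy, labels, gt)
    fine = Kernel("gaussian", 1.5)
    operator = DiffOperatorParams(0.01, 0.01, 0.01)
    schedules = {
        "coarse_only": [Stage(10.0, 0.4, 50)],
        "fine_only": [Stage(1.5, 0.4, 50)],
        "two_stage": [Stage(10.0, 0.4, 25), Stage(1.5, 0.4, 25)],
    }
    out = {}
    for name, schedule in schedules.items():
        config = RegistrationConfig(
            w_p=0.0, operator=operator, kernel_schedule=schedule, tolerance=1e-6
        )
        result = register(anatomy, target, config)
        final = energy(result.deformed, target, config, kernel=fine)
        out[name] = {"result": result, "final_energy": final[0]}
    return out


@pytest.fixture(scope="session")
def degenerate_weight_runs():
    """w_g = 0 (pure image SSD) twice — with and without surfaces present —
    plus a w_p = 0 (pure currents) run, on a 32^3 nested phantom."""
    anatomy, labels = make_phantom(
        PhantomSpec("two_tissue_nested", radius=10, grid_size=32)
    )
    grid = GridSpec.of_image(anatomy.posteriors)
    gt = make_ground_truth_deformation("translation", (2.0, 1.0, 0.0), grid)
    target, target_labels = deform_phantom(anatomy, labels, gt)
    schedule = [Stage(6.0, 0.4, 25)]

    from careg.anatomy import Anatomy

    cfg_img = RegistrationConfig(w_g=0.0, kernel_schedule=schedule)
    with_surfaces = register(anatomy, target, cfg_img)
    stripped = register(
        Anatomy(anatomy.posteriors, []), Anatomy(target.posteriors, []), cfg_img
    )
    cfg_geom = RegistrationConfig(w_p=0.0, kernel_schedule=schedule)
    geometry_only = register(anatomy, target, cfg_geom)
    return {
        "moving": anatomy,
        "target": target,
        "target_labels": target_labels,
        "image_with_surfaces": with_surfaces,
        "image_stripped": stripped,
        "geometry_only": geometry_only,
    }
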