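"""Greedy multicompartment registration.

The dissimilarity between two anatomies combines an L2 term on the class
posteriors with the currents distance between corresponding surfaces:

    E = w_p * sum_c int |p1_c o h^-1 - p2_c|^2 dx
      + w_g * sum_j || [h(M1_j)] - [M2_j] ||_k^2.

Each iteration assembles a body force from both compartments (image
difference times image gradient; splatted currents gradient), solves
L v = F for a smooth velocity, and takes a small Euler step: images
compose the inverse map, meshes move forward.  A kernel-width schedule
(large sigma first, then smaller) provides multiscale behaviour without
ever resampling the grid.

Both force terms point in the energy DESCENT direction, so the total
force is simply their weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from careg.anatomy import (
    Anatomy,
    Image3D,
    LabelMap,
    ProbabilityImageSet,
    TriangleMesh,
)
from careg.currents import FaceCurrents, Kernel, face_currents
from careg.deformation import (
    Deformation,
    DiffOperatorParams,
    compose_step,
    jacobian_determinant,
    pull_back_image,
    push_forward_mesh,
    solve_L,
)
from careg.particle_mesh import (
    GridField,
    GridSpec,
    PMConfig,
    pm_currents_dissimilarity,
    pm_currents_gradient,
    pm_currents_norm_sq,
    splat,
)

__all__ = [
    "Stage",
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "energy",
    "image_force",
    "geometry_force",
    "register",
    "overlap",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Stage:
    """One schedule stage: kernel width (physical units), step size as a
    fraction of one voxel of maximum displacement per iteration, and an
    iteration budget."""

    sigma: float
    step_size: float = 0.4
    iterations: int = 100

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.step_size <= 0 or self.iterations < 1:
            raise ValueError(f"invalid stage: {self}")


@dataclass
class RegistrationConfig:
    """Weights, operator, kernel schedule and stopping rules.

    Kernel widths must be nonincreasing across stages (coarse to fine).
    Convergence within a stage: relative total-energy decrease below
    ``tolerance`` over ``window`` iterations.
    """

    w_p: float = 1.0
    w_g: float = 1.0
    operator: DiffOperatorParams = field(default_factory=DiffOperatorParams)
    kernel_schedule: list[Stage] = field(default_factory=list)
    kernel_family: str = "gaussian"
    max_iterations: int = 1000
    tolerance: float = 1e-5
    window: int = 10
    taper_voxels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_p < 0 or self.w_g < 0:
            raise ValueError("weights must be nonnegative")
        if self.kernel_schedule:
            widths = [s.sigma for s in self.kernel_schedule]
            if any(b > a + 1e-12 for a, b in zip(widths, widths[1:])):
                raise ValueError("kernel widths must be nonincreasing across stages")

    @classmethod
    def default_for(cls, spacing, **kwargs) -> "RegistrationConfig":
        """Three-stage schedule at sigma = 16, 8, 4 voxels."""
        h = float(np.min(spacing))
        schedule = [
            Stage(16 * h, 0.4, 100),
            Stage(8 * h, 0.4, 100),
            Stage(4 * h, 0.4, 100),
        ]
        return cls(kernel_schedule=schedule, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RegistrationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        op = DiffOperatorParams(**raw.pop("operator", {}))
        schedule = [Stage(**s) for s in raw.pop("kernel_schedule", [])]
        return cls(operator=op, kernel_schedule=schedule, **raw)

    def to_yaml(self, path: str) -> None:
        raw = {
            "w_p": self.w_p,
            "w_g": self.w_g,
            "operator": {
                "alpha": self.operator.alpha,
                "beta": self.operator.beta,
                "gamma": self.operator.gamma,
            },
            "kernel_schedule": [
                {"sigma": s.sigma, "step_size": s.step_size, "iterations": s.iterations}
                for s in self.kernel_schedule
            ],
            "kernel_family": self.kernel_family,
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
            "window": self.window,
            "taper_voxels": self.taper_voxels,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class RegistrationResult:
    deformation: Deformation
    deformed: Anatomy
    energy_trace: np.ndarray  # (n_iter, 3): total, probabilistic, currents
    diagnostics: dict


def _check_compatible(moving: Anatomy, target: Anatomy) -> None:
    if len(moving.posteriors.channels) != len(target.posteriors.channels):
        raise ValueError(
            "anatomies have different posterior channel counts: "
            f"{len(moving.posteriors.channels)} vs {len(target.posteriors.channels)}"
        )
    if len(moving.surfaces) != len(target.surfaces):
        raise ValueError(
            "anatomies have different surface counts: "
            f"{len(moving.surfaces)} vs {len(target.surfaces)}"
        )


def _prob_term(a: ProbabilityImageSet, b: ProbabilityImageSet) -> float:
    voxvol = float(np.prod(a.spacing))
    diff = a.stack() - b.stack()
    return float(np.sum(diff * diff)) * voxvol


def energy(
    moving: Anatomy,
    target: Anatomy,
    config: RegistrationConfig,
    kernel: Kernel | None = None,
) -> tuple[float, float, float]:
    """(total, probabilistic L2 term, currents term) between anatomies.

    The currents term uses the particle-mesh approximation on the
    posterior lattice with ``kernel`` (default: the first schedule
    stage's kernel).
    """
    _check_compatible(moving, target)
    prob = _prob_term(moving.posteriors, target.posteriors)
    geom = 0.0
    if moving.surfaces and config.w_g > 0:
        if kernel is None:
            if not config.kernel_schedule:
                raise ValueError("no kernel available: empty schedule")
            kernel = Kernel(config.kernel_family, config.kernel_schedule[0].sigma)
        pm = PMConfig(GridSpec.of_image(moving.posteriors), kernel)
        for ma, mb in zip(moving.surfaces, target.surfaces):
            geom += pm_currents_dissimilarity(ma, mb, pm)
    return config.w_p * prob + config.w_g * geom, prob, geom


def image_force(
    moving_posteriors: ProbabilityImageSet, target_posteriors: ProbabilityImageSet
) -> GridField:
    """Greedy fluid body force of the posterior L2 term, descent-directed:

        F(x) = - sum_c (p~_c(x) - q_c(x)) grad p~_c(x),

    with p~ the currently deformed moving posteriors, q the target, and
    central-difference image gradients.
    """
    spec = GridSpec.of_image(moving_posteriors)
    force = np.zeros(spec.shape + (3,))
    for ch_m, ch_t in zip(moving_posteriors.channels, target_posteriors.channels):
        diff = ch_m.values - ch_t.values
        grads = np.gradient(ch_m.values, *spec.spacing, edge_order=1)
        for ax in range(3):
            force[..., ax] -= diff * grads[ax]
    return GridField(force, spec)


def geometry_force(
    moving_surfaces: list[TriangleMesh],
    target_fcs: list[FaceCurrents],
    pm: PMConfig,
) -> GridField:
    """Currents force: per-vertex particle-mesh gradients of each surface
    pair's dissimilarity, negated (descent) and splatted onto the grid.
    Splat conservation makes the deposited total equal the vertex sum."""
    out = GridField.zeros(pm.grid, vector=True)
    for mesh, tfc in zip(moving_surfaces, target_fcs):
        grad = pm_currents_gradient(mesh, tfc, pm)
        out.values += splat(mesh.vertices, -grad, pm.grid).values
    return out


def _taper_weights(spec: GridSpec, margin: int) -> np.ndarray:
    """Per-node weight ramping to zero in a boundary margin; suppresses
    wrap-around coupling of the periodic PDE solve."""
    w = np.ones(spec.shape)
    if margin <= 0:
        return w
    for ax, n in enumerate(spec.shape):
        ramp = np.ones(n)
        m = min(margin, (n - 1) // 2)
        edge = np.linspace(0.0, 1.0, m + 1)[:-1]
        ramp[:m] = edge
        ramp[n - m :] = edge[::-1]
        shape = [1, 1, 1]
        shape[ax] = n
        w = w * ramp.reshape(shape)
    return w


def register(
    moving: Anatomy, target: Anatomy, config: RegistrationConfig
) -> RegistrationResult:
    """Greedy diffeomorphic registration of ``moving`` onto ``target``.

    Per stage of the kernel schedule, iterate: assemble
    F = w_p F_img + w_g F_geom, solve L v = F, normalize the step so the
    maximum displacement is ``step_size`` voxels, compose the inverse map
    and advance the meshes, and record the energy.  A step that increases
    the energy is retried at half the length (up to 4 halvings); five
    consecutive increasing iterations abort with a diagnostic.
    """
    _check_compatible(moving, target)
    if not config.kernel_schedule:
        raise ValueError("kernel_schedule must contain at least one stage")
    spec = GridSpec.of_image(moving.posteriors)
    min_h = float(np.min(spec.spacing))
    taper = _taper_weights(spec, config.taper_voxels)

    deformation = Deformation.identity(spec)
    meshes = [m.copy() for m in moving.surfaces]
    target_fcs = [face_currents(m) for m in target.surfaces]

    trace: list[tuple[float, float, float]] = []
    stage_min_jac: list[float] = []
    total_iters = 0

    # self-energy scale of the moving anatomy: energies at the floating-point
    # floor relative to it are treated as solved (guards the coincident case,
    # where roundoff-level forces would otherwise be step-normalized)
    energy_scale = config.w_p * _prob_term(
        moving.posteriors,
        ProbabilityImageSet(
            [
                Image3D(np.zeros(spec.shape), spec.spacing_arr, spec.origin_arr)
                for _ in moving.posteriors.channels
            ],
            list(moving.posteriors.class_names),
        ),
    )
    if config.w_g > 0 and moving.surfaces:
        pm0 = PMConfig(spec, Kernel(config.kernel_family, config.kernel_schedule[0].sigma))
        for mesh in moving.surfaces:
            energy_scale += config.w_g * pm_currents_norm_sq(face_currents(mesh), pm0)

    def _energy_of(posteriors, mesh_list, kernel) -> tuple[float, float, float]:
        prob = _prob_term(posteriors, target.posteriors)
        geom = 0.0
        if mesh_list and config.w_g > 0:
            pm = PMConfig(spec, kernel)
            for ma, tfc in zip(mesh_list, target_fcs):
                geom += pm_currents_dissimilarity(ma, tfc, pm)
        return config.w_p * prob + config.w_g * geom, prob, geom

    stage_starts: list[int] = []
    for stage in config.kernel_schedule:
        kernel = Kernel(config.kernel_family, stage.sigma)
        pm = PMConfig(spec, kernel)
        deformed_post = pull_back_image(moving.posteriors, deformation)
        current = _energy_of(deformed_post, meshes, kernel)
        stage_starts.append(len(trace))
        trace.append(current)
        reject_streak = 0
        step_scale = 1.0

        for _ in range(stage.iterations):
            if total_iters >= config.max_iterations:
                break
            if current[0] <= 1e-10 * energy_scale:
                break
            total_iters += 1
            force = GridField.zeros(spec, vector=True)
            if config.w_p > 0:
                force.values += config.w_p * image_force(
                    deformed_post, target.posteriors
                ).values
            if config.w_g > 0 and meshes:
                force.values += config.w_g * geometry_force(
                    meshes, target_fcs, pm
                ).values
            force.values *= taper[..., None]
            v = solve_L(force, config.operator)
            vmax = float(np.max(np.linalg.norm(v.values, axis=-1)))
            if vmax <= 0 or not np.isfinite(vmax):
                break
            dt = step_scale * stage.step_size * min_h / vmax

            # images compose the reverse velocity -v; geometry advects along +v
            v_rev = GridField(-v.values, spec)
            accepted = False
            for _halving in range(5):
                trial_def = compose_step(deformation, v_rev, dt)
                trial_meshes = [push_forward_mesh(m, v, dt) for m in meshes]
                trial_post = pull_back_image(moving.posteriors, trial_def)
                trial_energy = _energy_of(trial_post, trial_meshes, kernel)
                if not np.isfinite(trial_energy[0]):
                    raise RegistrationError(
                        "non-finite energy encountered; step size too large "
                        "for this configuration"
                    )
                if trial_energy[0] <= current[0] * (1 + config.tolerance):
                    accepted = True
                    break
                dt *= 0.5
            if not accepted:
                # reject the step: keep the previous state, shrink future
                # steps; five rejections in a row mean the stage is done
                step_scale *= 0.5
                reject_streak += 1
                if reject_streak >= 5:
                    break
                continue
            reject_streak = 0
            deformation, meshes, deformed_post = trial_def, trial_meshes, trial_post
            trace.append(trial_energy)
            current = trial_energy

            # relative-decrease convergence over the trailing window
            # (within the current stage: energies across stages use
            # different kernels and are not comparable)
            if len(trace) - stage_starts[-1] > config.window:
                past = trace[-config.window - 1][0]
                if past > 0 and (past - current[0]) / past < config.tolerance:
                    break

        stage_min_jac.append(
            float(jacobian_determinant(deformation).values[1:-1, 1:-1, 1:-1].min())
        )

    deformed = Anatomy(pull_back_image(moving.posteriors, deformation), meshes)
    return RegistrationResult(
        deformation=deformation,
        deformed=deformed,
        energy_trace=np.asarray(trace),
        diagnostics={
            "min_jacobian_det_per_stage": stage_min_jac,
            "iterations": total_iters,
            # energy is re-evaluated with each stage's kernel, so traces are
            # comparable only within a stage segment
            "stage_start_indices": stage_starts,
        },
    )


def overlap(
    transformed: LabelMap | np.ndarray,
    reference: LabelMap | np.ndarray,
    label_id: int = 1,
) -> float:
    """Overlap(h.S0, S2) = |h.S0 intersect S2| / |S2| on binary masks.

    Stricter than Dice: the denominator is the reference volume alone, so
    values run lower than the Dice coefficient for the same masks.
    """
    a = transformed.labels if isinstance(transformed, LabelMap) else transformed
    b = reference.labels if isinstance(reference, LabelMap) else reference
    mask_a = np.asarray(a) == label_id
    mask_b = np.asarray(b) == label_id
    denom = int(mask_b.sum())
    if denom == 0:
        raise ValueError(f"label {label_id} absent from the reference map")
    return float(np.logical_and(mask_a, mask_b).sum() / denom)
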