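"""Three-step variational registration pipeline.

Step 1 — rigid prealignment: centers of mass are matched, then an
exhaustive search over equidistant rotation angles is run; each
candidate angle seeds a local rigid NGF optimization and the angle with
the smallest final distance wins.  Slides may land on the glass in any
orientation (including upside down), so the exhaustive sweep is what
makes the pipeline robust to large rotations.

Step 2 — affine registration: multilevel coarse-to-fine Gauss-Newton on
the 6 affine parameters, initialized from the promoted rigid result.

Step 3 — deformable registration: multilevel L-BFGS on a nodal
control-point grid of displacements, minimizing
``J = NGF + alpha * CURV``, initialized from the promoted affine result.

Everything is deterministic: there is no randomness anywhere in the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .imgio import Image, ImagePyramid, build_pyramid
from .ngf import (
    NgfSettings,
    ngf_objective,
    ngf_residuals_and_jacobian,
    ngf_value_and_derivative,
)
from .regularizer import curvature_energy_sampled
from .transforms import (
    AffineTransform,
    DeformationGrid,
    RigidTransform,
    count_folds,
    promote,
)

__all__ = [
    "PrealignConfig",
    "AffineConfig",
    "DeformableConfig",
    "OptimizerConfig",
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "center_of_mass",
    "rotation_angles",
    "prealign",
    "register_affine",
    "register_deformable",
    "run_pipeline",
]


class RegistrationError(RuntimeError):
    """Optimization failure; carries the last valid transform."""

    def __init__(self, message: str, last_transform=None):
        super().__init__(message)
        self.last_transform = last_transform


@dataclass
class PrealignConfig:
    n_levels: int = 4
    n_rotations: int = 32
    target_spacing_um: float = 200.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rotations < 2:
            raise ValueError("n_rotations must be >= 2")
        if not (self.epsilon > 0 and self.target_spacing_um > 0 and self.n_levels >= 1):
            raise ValueError("invalid prealignment configuration")


@dataclass
class AffineConfig:
    #: None = use every available pyramid level down to the finest.
    n_levels: int | None = None
    #: None = register down to the finest pyramid level.
    finest_spacing_um: float | None = None
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.finest_spacing_um is not None and not self.finest_spacing_um > 0:
            raise ValueError("finest_spacing_um must be positive")


@dataclass
class DeformableConfig:
    n_levels: int | None = None
    finest_spacing_um: float | None = None
    epsilon: float = 1.0
    alpha: float = 0.1
    grid_nodes: tuple[int, int] = (257, 257)

    def __post_init__(self) -> None:
        if not (self.epsilon > 0 and self.alpha > 0):
            raise ValueError("epsilon and alpha must be positive")
        if min(self.grid_nodes) < 2:
            raise ValueError("grid_nodes must each be >= 2")
        if self.finest_spacing_um is not None and not self.finest_spacing_um > 0:
            raise ValueError("finest_spacing_um must be positive")


@dataclass
class OptimizerConfig:
    max_iterations_affine: int = 100
    max_iterations_deformable: int = 200
    gradient_tolerance: float = 1e-6  # relative to the initial gradient norm
    relative_objective_tolerance: float = 1e-6
    lbfgs_memory: int = 10


@dataclass
class RegistrationConfig:
    prealign: PrealignConfig = field(default_factory=PrealignConfig)
    affine: AffineConfig = field(default_factory=AffineConfig)
    deformable: DeformableConfig = field(default_factory=DeformableConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)


@dataclass
class RegistrationResult:
    rigid: RigidTransform
    affine: AffineTransform
    deformable: DeformationGrid
    per_step_distance: dict
    diagnostics: dict


def center_of_mass(image: Image) -> np.ndarray:
    """Intensity-weighted mean of the pixel-center physical coordinates."""
    total = float(np.sum(image.data))
    if total <= 0:
        raise ValueError("center of mass undefined: total intensity is not positive")
    x = image.pixel_centers()
    return np.tensordot(image.data, x, axes=([0, 1], [0, 1])) / total


def rotation_angles(n_rotations: int) -> np.ndarray:
    """Equidistant candidate angles ``2 pi k / n`` strictly inside [0, 2pi)."""
    if n_rotations < 2:
        raise ValueError(f"n_rotations must be >= 2, got {n_rotations}")
    return 2.0 * np.pi * np.arange(n_rotations) / n_rotations


def _gauss_newton(ref: Image, template: Image, transform, settings: NgfSettings,
                  max_iterations: int, gtol: float, ftol: float):
    """Gauss-Newton with Armijo backtracking on the NGF objective.

    Residuals are the per-pixel alignment ratios q_i; the positive
    semidefinite model Hessian h^2 J^T J (plus a small Tikhonov term)
    yields descent directions for the objective (h^2/2) sum (1 - q_i^2).
    """
    value, q, jac, h = ngf_residuals_and_jacobian(ref, template, transform, settings)
    if not np.isfinite(value):
        raise RegistrationError("non-finite objective at initialization", transform)
    grad = -h * h * (jac.T @ q)
    g0 = max(np.max(np.abs(grad)), 1e-300)
    n_iter = 0
    for _ in range(max_iterations):
        if np.max(np.abs(grad)) < gtol * g0:
            break
        hess = h * h * (jac.T @ jac)
        p = hess.shape[0]
        hess = hess + (1e-10 * max(np.trace(hess) / p, 1e-12)) * np.eye(p)
        try:
            step_dir = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        slope = float(grad @ step_dir)
        if slope >= 0:
            break
        # Armijo backtracking, factor 0.5, slope parameter 1e-4
        t_new = None
        step = 1.0
        for _ in range(40):
            cand = transform.with_parameters(transform.get_parameters() + step * step_dir)
            v = ngf_objective(ref, template, cand, settings)
            if not np.isfinite(v):
                raise RegistrationError("non-finite objective during line search",
                                        transform)
            if v <= value + 1e-4 * step * slope:
                t_new = cand
                v_new = v
                break
            step *= 0.5
        if t_new is None:
            break
        prev = value
        transform = t_new
        value, q, jac, h = ngf_residuals_and_jacobian(ref, template, transform,
                                                      settings)
        grad = -h * h * (jac.T @ q)
        n_iter += 1
        if prev - value < ftol * max(abs(prev), 1e-300):
            break
    return transform, {"iterations": n_iter, "final_objective": value}


def _match_level(pyramid: ImagePyramid, spacing_um: float) -> Image:
    return pyramid[pyramid.closest_level(spacing_um)]


def _level_range(pyramid: ImagePyramid, finest_spacing_um: float | None,
                 n_levels: int | None) -> list[int]:
    """Level indices coarse -> fine for a multilevel step."""
    finest = 0 if finest_spacing_um is None else pyramid.closest_level(finest_spacing_um)
    if n_levels is None:
        coarsest = pyramid.n_levels - 1
    else:
        coarsest = min(finest + n_levels - 1, pyramid.n_levels - 1)
    coarsest = max(coarsest, finest)
    return list(range(coarsest, finest - 1, -1))


def prealign(ref_pyramid: ImagePyramid, tmpl_pyramid: ImagePyramid,
             config: PrealignConfig | RegistrationConfig | None = None,
             optimizer: OptimizerConfig | None = None) -> RigidTransform:
    """Exhaustive-rotation rigid prealignment.

    The translation is seeded by the center-of-mass offset; every
    candidate angle seeds a multilevel local rigid optimization and the
    candidate with the smallest final NGF distance is returned.  The
    result never scores worse than the raw center-of-mass alignment.
    """
    if isinstance(config, RegistrationConfig):
        optimizer = optimizer or config.optimizer
        config = config.prealign
    config = config or PrealignConfig()
    optimizer = optimizer or OptimizerConfig()
    settings = NgfSettings(config.epsilon)

    target = ref_pyramid.closest_level(config.target_spacing_um)
    levels = list(range(min(target + config.n_levels - 1, ref_pyramid.n_levels - 1),
                        target - 1, -1))
    ref_t = ref_pyramid[target]
    tmpl_t = _match_level(tmpl_pyramid, ref_t.spacing_um)
    com_r = center_of_mass(ref_t)
    com_t = center_of_mass(tmpl_t)
    t0 = com_t - com_r
    center = (float(com_r[0]), float(com_r[1]))

    best = RigidTransform(0.0, float(t0[0]), float(t0[1]), center)
    best_score = ngf_objective(ref_t, tmpl_t, best, settings)  # raw c.o.m. score
    for phi in rotation_angles(config.n_rotations):
        cand = RigidTransform(float(phi), float(t0[0]), float(t0[1]), center)
        for lv in levels:
            ref_l = ref_pyramid[lv]
            tmpl_l = _match_level(tmpl_pyramid, ref_l.spacing_um)
            cand, _ = _gauss_newton(
                ref_l, tmpl_l, cand, settings,
                optimizer.max_iterations_affine,
                optimizer.gradient_tolerance,
                optimizer.relative_objective_tolerance,
            )
        score = ngf_objective(ref_t, tmpl_t, cand, settings)
        if score < best_score:
            best, best_score = cand, score
    return best


def register_affine(ref_pyramid: ImagePyramid, tmpl_pyramid: ImagePyramid,
                    init_rigid: RigidTransform | AffineTransform,
                    config: AffineConfig | RegistrationConfig | None = None,
                    optimizer: OptimizerConfig | None = None) -> AffineTransform:
    """Multilevel coarse-to-fine Gauss-Newton affine NGF registration."""
    if isinstance(config, RegistrationConfig):
        optimizer = optimizer or config.optimizer
        config = config.affine
    config = config or AffineConfig()
    optimizer = optimizer or OptimizerConfig()
    settings = NgfSettings(config.epsilon)
    transform = init_rigid if isinstance(init_rigid, AffineTransform) else promote(init_rigid)
    for lv in _level_range(ref_pyramid, config.finest_spacing_um, config.n_levels):
        ref_l = ref_pyramid[lv]
        tmpl_l = _match_level(tmpl_pyramid, ref_l.spacing_um)
        transform, _ = _gauss_newton(
            ref_l, tmpl_l, transform, settings,
            optimizer.max_iterations_affine,
            optimizer.gradient_tolerance,
            optimizer.relative_objective_tolerance,
        )
    return transform


def _grid_shape_for_level(extent: tuple[float, float], spacing_um: float,
                          grid_nodes: tuple[int, int]) -> tuple[int, int]:
    """Node counts at one level: the configured grid, capped so nodes are
    never finer than 2 image pixels at that level."""
    m1_goal, m2_goal = grid_nodes
    sx_goal = extent[0] / (m2_goal - 1)
    sy_goal = extent[1] / (m1_goal - 1)
    sx = max(sx_goal, 2.0 * spacing_um)
    sy = max(sy_goal, 2.0 * spacing_um)
    m2 = max(2, int(math.floor(extent[0] / sx)) + 1)
    m1 = max(2, int(math.floor(extent[1] / sy)) + 1)
    return (min(m1, m1_goal), min(m2, m2_goal))


def register_deformable(ref_pyramid: ImagePyramid, tmpl_pyramid: ImagePyramid,
                        init_affine: AffineTransform,
                        config: DeformableConfig | RegistrationConfig | None = None,
                        optimizer: OptimizerConfig | None = None,
                        diagnostics: dict | None = None) -> DeformationGrid:
    """Multilevel curvature-regularized deformable registration.

    Minimizes ``NGF + alpha * CURV`` over the node displacements with
    L-BFGS at each level; the grid is prolonged to the next level's node
    layout by bilinear resampling.  A line-search breakdown inside
    L-BFGS is recorded as a warning diagnostic and the best iterate is
    kept.
    """
    if isinstance(config, RegistrationConfig):
        optimizer = optimizer or config.optimizer
        config = config.deformable
    config = config or DeformableConfig()
    optimizer = optimizer or OptimizerConfig()
    settings = NgfSettings(config.epsilon)
    levels = _level_range(ref_pyramid, config.finest_spacing_um, config.n_levels)
    domain = ref_pyramid[levels[-1]]
    extent = domain.extent_um
    origin = domain.origin
    grid: DeformationGrid | None = None
    for lv in levels:
        ref_l = ref_pyramid[lv]
        tmpl_l = _match_level(tmpl_pyramid, ref_l.spacing_um)
        shape = _grid_shape_for_level(extent, ref_l.spacing_um, config.grid_nodes)
        if grid is None:
            grid = promote(init_affine, shape, extent, origin)
        elif shape != grid.grid_shape:
            new_grid = DeformationGrid(np.zeros((*shape, 2)), extent, origin)
            new_grid.node_displacements = grid.interpolate(new_grid.node_positions())
            grid = new_grid

        def objective(u_flat, grid=grid, ref_l=ref_l, tmpl_l=tmpl_l):
            g = grid.with_parameters(u_flat)
            value, dngf = ngf_value_and_derivative(ref_l, tmpl_l, g, settings)
            # CURV sampled at this level's pixel centers: same grid and
            # units as the data term, so alpha weighs like against like
            energy, dcurv = curvature_energy_sampled(g, ref_l, with_derivative=True)
            return (value + config.alpha * energy,
                    dngf + config.alpha * dcurv.ravel())

        x0 = grid.get_parameters()
        g0 = np.max(np.abs(objective(x0)[1]))
        res = scipy.optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={
                "maxiter": optimizer.max_iterations_deformable,
                "maxcor": optimizer.lbfgs_memory,
                "ftol": optimizer.relative_objective_tolerance,
                "gtol": max(optimizer.gradient_tolerance * g0, 1e-300),
            },
        )
        grid = grid.with_parameters(res.x)
        if diagnostics is not None:
            diagnostics.setdefault("deformable_iterations", []).append(int(res.nit))
            if not res.success and "NORM" not in str(res.message).upper():
                diagnostics.setdefault("warnings", []).append(
                    f"deformable level {lv}: {res.message}"
                )
    return grid


def _pyramid_for(source: Image | ImagePyramid, target_spacing_um: float) -> ImagePyramid:
    if isinstance(source, ImagePyramid):
        return source
    n = 1
    while (source.spacing_um * 2 ** (n - 1) < target_spacing_um
           and math.ceil(min(source.shape) / 2 ** n) >= 8):
        n += 1
    return build_pyramid(source, n)


def run_pipeline(ref_source: Image | ImagePyramid,
                 tmpl_source: Image | ImagePyramid,
                 config: RegistrationConfig | None = None) -> RegistrationResult:
    """Run prealignment, affine, and deformable registration in sequence.

    Each step is initialized from the previous one; the result records
    each step's final NGF distance (at that step's finest level, with
    that step's edge parameter) and the fold count of the final grid.
    """
    config = config or RegistrationConfig()
    ref_pyr = _pyramid_for(ref_source, config.prealign.target_spacing_um)
    tmpl_pyr = _pyramid_for(tmpl_source, config.prealign.target_spacing_um)
    diagnostics: dict = {}
    per_step: dict = {}

    def _step(name, fn):
        try:
            return fn()
        except RegistrationError:
            raise
        except Exception as exc:  # annotate which step failed
            raise RegistrationError(f"{name} step failed: {exc}") from exc

    rigid = _step("prealignment", lambda: prealign(
        ref_pyr, tmpl_pyr, config.prealign, config.optimizer))
    lv = ref_pyr.closest_level(config.prealign.target_spacing_um)
    per_step["prealign"] = ngf_objective(
        ref_pyr[lv], _match_level(tmpl_pyr, ref_pyr[lv].spacing_um),
        rigid, NgfSettings(config.prealign.epsilon))

    affine = _step("affine", lambda: register_affine(
        ref_pyr, tmpl_pyr, rigid, config.affine, config.optimizer))
    lv = 0 if config.affine.finest_spacing_um is None else ref_pyr.closest_level(
        config.affine.finest_spacing_um)
    per_step["affine"] = ngf_objective(
        ref_pyr[lv], _match_level(tmpl_pyr, ref_pyr[lv].spacing_um),
        affine, NgfSettings(config.affine.epsilon))

    grid = _step("deformable", lambda: register_deformable(
        ref_pyr, tmpl_pyr, affine, config.deformable, config.optimizer,
        diagnostics))
    lv = 0 if config.deformable.finest_spacing_um is None else ref_pyr.closest_level(
        config.deformable.finest_spacing_um)
    per_step["deformable"] = ngf_objective(
        ref_pyr[lv], _match_level(tmpl_pyr, ref_pyr[lv].spacing_um),
        grid, NgfSettings(config.deformable.epsilon))

    diagnostics["fold_count"] = count_folds(grid)
    return RegistrationResult(rigid, affine, grid, per_step, diagnostics)
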