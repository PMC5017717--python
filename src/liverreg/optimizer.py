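"""Stochastic gradient descent over -MI + alpha * rigidity, multiresolution.

The composite registration cost is minimized with Robbins-Monro stochastic
gradient descent: a fresh set of mask-restricted samples is drawn every
iteration, the gain follows gamma_t = a / (A + t + 1)^decay, and the factor
``a`` is auto-scaled per resolution so the first step moves no control
point further than a set fraction of the current grid spacing. Convergence
is by iteration budget only (no early stopping), which keeps runs
deterministic for a given master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConfigurationError, OptimizationError
from .image_core import (BinaryMask, Image3D, gaussian_pyramid, resample)
from .rigidity_penalty import (RigidityWeights, default_eval_points,
                               rigidity_gradient)
from .similarity_mi import (SplineImage, draw_samples, intensity_range,
                            joint_histogram, mi_gradient, mutual_information)
from .transforms import (BSplineFFD, CompositeTransform, RigidTransform3D,
                         refine_grid)


@dataclass
class RegistrationConfig:
    """Full parameter schedule for the registration framework.

    Defaults follow the reference settings: four resolutions with B-spline
    grid spacings [80, 40, 20, 10] mm, 500 iterations and 2000 random
    samples per resolution level, and rigidity weights
    alpha = [0.1, 0.1, 0.1, 4.0] when the penalty is active.
    """

    n_resolutions: int = 4
    grid_spacings_mm: list = field(default_factory=lambda: [80.0, 40.0, 20.0, 10.0])
    pyramid_factors: list = field(default_factory=lambda: [8, 4, 2, 1])
    iterations_per_level: int = 500
    samples_per_iteration: int = 2000
    bins: int = 32
    gain_a: float | None = None          # None -> auto-scaled per level
    gain_A: float = 50.0
    gain_decay: float = 0.602
    first_step_fraction: float = 0.1     # of the grid spacing, for auto gain
    rigidity_enabled: bool = False
    rigidity_weights: RigidityWeights = field(default_factory=RigidityWeights)
    rigidity_eval_spacing_mm: float = 15.0
    seed: int = 1234
    use_fixed_mask: bool = True
    # stage-2 settings
    rigid_iterations: int = 200
    rigid_factors: list = field(default_factory=lambda: [4, 2, 1])
    rigid_rotation_scale_mm: float = 100.0
    rigid_fd_step: float = 0.1
    rigid_polish_samples: int = 20000    # 0 disables the deterministic polish
    stage2_first_level: int = 2          # start at the 20 mm grid
    needle_exclude_hu: float | None = 1500.0  # mask out metal-bright voxels

    def __post_init__(self):
        if len(self.grid_spacings_mm) != self.n_resolutions \
                or len(self.pyramid_factors) != self.n_resolutions:
            raise ConfigurationError(
                "grid_spacings_mm and pyramid_factors must have "
                "n_resolutions entries")
        if self.iterations_per_level < 1 or self.samples_per_iteration < 1:
            raise ConfigurationError("iterations and samples must be >= 1")
        if len(self.rigidity_weights.alpha_per_resolution) \
                != self.n_resolutions:
            raise ConfigurationError(
                "alpha_per_resolution must have n_resolutions entries")


@dataclass
class OptimizationTrace:
    """Per-iteration progress of one (multi-level) optimization run."""

    cost: list = field(default_factory=list)
    step_norm: list = field(default_factory=list)
    dropped_fraction: list = field(default_factory=list)
    level_start: list = field(default_factory=list)
    level_info: list = field(default_factory=list)

    def start_level(self, **info):
        self.level_start.append(len(self.cost))
        self.level_info.append(info)

    def record(self, cost, step_norm, dropped):
        self.cost.append(float(cost))
        self.step_norm.append(float(step_norm))
        self.dropped_fraction.append(float(dropped))

    def smoothed_cost(self, window=50):
        """Moving average of the stochastic cost estimates."""
        c = np.asarray(self.cost, float)
        if len(c) == 0:
            return c
        k = min(window, len(c))
        return np.convolve(c, np.ones(k) / k, mode="valid")

    def to_text(self):
        lines = ["iteration\tcost\tstep_norm\tdropped_fraction"]
        for i, (c, s, d) in enumerate(zip(self.cost, self.step_norm,
                                          self.dropped_fraction)):
            lines.append(f"{i}\t{c:.8g}\t{s:.8g}\t{d:.6g}")
        return "\n".join(lines) + "\n"


def sgd_minimize(cost_and_gradient, mu0, n_iterations, rng=None, a=None,
                 A=50.0, decay=0.602, target_first_step=None,
                 trace: OptimizationTrace | None = None):
    """Robbins-Monro SGD: mu_{t+1} = mu_t - gamma_t g_t.

    ``cost_and_gradient(mu, t)`` returns ``(cost, gradient)`` or
    ``(cost, gradient, dropped_fraction)``; the gradient is a stochastic
    estimate (the callable may consume its own RNG stream). With ``a=None``
    the gain is scaled so the first step's largest parameter motion equals
    ``target_first_step``. Runs exactly ``n_iterations`` steps.
    """
    mu = np.array(mu0, float, copy=True)
    trace = trace if trace is not None else OptimizationTrace()
    for t in range(int(n_iterations)):
        out = cost_and_gradient(mu, t)
        cost, grad = out[0], np.asarray(out[1], float)
        dropped = out[2] if len(out) > 2 else 0.0
        if not np.isfinite(cost) or not np.all(np.isfinite(grad)):
            raise OptimizationError(
                f"non-finite cost/gradient at iteration {t}", trace)
        if t == 0 and a is None:
            gmax = np.abs(grad).max()
            step0 = (target_first_step if target_first_step is not None
                     else 1.0)
            a = 0.0 if gmax == 0 else step0 * (A + 1.0) ** decay / gmax
        gamma = a / (A + t + 1.0) ** decay
        step = gamma * grad
        mu -= step
        trace.record(cost, np.linalg.norm(step), dropped)
    return mu, trace


# ---------------------------------------------------------------------------
# Non-rigid multiresolution registration
# ---------------------------------------------------------------------------

def multires_register(fixed: Image3D, moving: Image3D,
                      fixed_mask: BinaryMask, init, config: RegistrationConfig,
                      rigidity=None, first_level: int | None = None,
                      moving_mask: BinaryMask | None = None):
    """Masked multiresolution B-spline registration of ``moving`` to ``fixed``.

    Per level: pyramid images are built, the B-spline grid is created at the
    level's spacing (carried over by grid refinement between levels), and
    ``-MI`` — plus the level-weighted rigidity penalty when ``rigidity``
    supplies ``(CoefficientMask, RigidityWeights)`` — is minimized with SGD
    on samples drawn inside the fixed mask. ``moving_mask`` (when given)
    restricts the moving-image intensity range so the histogram bins
    resolve the tissue contrasts of interest rather than the full air-to-
    bone span. Returns
    ``(CompositeTransform([init, ffd]), trace)`` mapping fixed world
    coordinates into the moving image (just the FFD if ``init`` is None).
    """
    first = 0 if first_level is None else int(first_level)
    levels = range(first, config.n_resolutions)
    if len(levels) == 0:
        raise ConfigurationError("no resolution levels selected")

    factors = [config.pyramid_factors[k] for k in levels]
    fixed_pyr = gaussian_pyramid(fixed, len(factors), factors)
    moving_pyr = gaussian_pyramid(moving, len(factors), factors)

    lo, hi = fixed.geometry.world_bounds()
    rng = np.random.default_rng(config.seed)
    trace = OptimizationTrace()

    cmask, weights = (rigidity if rigidity is not None
                      else (None, config.rigidity_weights))
    ffd = None
    for li, level in enumerate(levels):
        spacing = float(config.grid_spacings_mm[level])
        if ffd is None:
            ffd = BSplineFFD.for_domain(lo, hi, spacing)
        else:
            ffd = refine_grid(ffd, spacing)
        fixed_lvl = fixed_pyr[li]
        moving_spl = SplineImage(moving_pyr[li])
        mask_lvl = resample(fixed_mask, None, fixed_lvl.geometry, "nearest",
                            0)
        franges = intensity_range(fixed_lvl,
                                  mask_lvl if mask_lvl.voxels.any() else None)
        if moving_mask is not None:
            mmask_lvl = resample(moving_mask, None,
                                 moving_pyr[li].geometry, "nearest", 0)
            mranges = intensity_range(
                moving_pyr[li], mmask_lvl if mmask_lvl.voxels.any() else None)
        else:
            mranges = intensity_range(moving_pyr[li])
        sample_mask = fixed_mask if config.use_fixed_mask else BinaryMask(
            np.ones(fixed.shape, np.uint8), fixed.spacing, fixed.origin,
            fixed.direction)

        alpha = (weights.alpha_per_resolution[level]
                 if rigidity is not None else 0.0)
        eval_pts = (default_eval_points(ffd, lo, hi,
                                        config.rigidity_eval_spacing_mm)
                    if rigidity is not None else None)

        trace.start_level(level=level, grid_spacing_mm=spacing,
                          pyramid_factor=config.pyramid_factors[level],
                          alpha=alpha)

        def cost_and_grad(mu, t, _ffd=ffd, _fixed=fixed_lvl,
                          _moving=moving_spl, _fr=franges, _mr=mranges,
                          _alpha=alpha, _eval=eval_pts):
            _ffd.coefficients = mu
            T = (CompositeTransform([init, _ffd]) if init is not None
                 else _ffd)
            samples = draw_samples(sample_mask,
                                   config.samples_per_iteration, rng)
            mi, grad = mi_gradient(_fixed, _moving, T, samples,
                                   config.bins, _fr, _mr)
            cost = -mi
            if rigidity is not None and _alpha > 0:
                pv, pg = rigidity_gradient(_ffd, cmask, weights, _eval,
                                           c_transform=T)
                cost += _alpha * pv
                grad = grad + _alpha * pg
            dropped = 0.0  # tracked via exceptions; gross drops raise
            return cost, grad, dropped

        mu_hat, trace = sgd_minimize(
            cost_and_grad, ffd.coefficients, config.iterations_per_level,
            a=config.gain_a, A=config.gain_A, decay=config.gain_decay,
            target_first_step=config.first_step_fraction * spacing,
            trace=trace)
        ffd.coefficients = mu_hat

    result = (CompositeTransform([init, ffd]) if init is not None else ffd)
    return result, trace


# ---------------------------------------------------------------------------
# Rigid MI registration (stage 2, F -> N)
# ---------------------------------------------------------------------------

def _rigid_from_params(q, center, rot_scale):
    return RigidTransform3D.from_euler_zyx(np.asarray(q[:3]) / rot_scale,
                                           np.asarray(q[3:]), center)


def rigid_register(fixed: Image3D, moving: Image3D,
                   fixed_mask: BinaryMask | None, config: RegistrationConfig,
                   init: RigidTransform3D | None = None):
    """Multiresolution rigid MI registration (rotation + translation).

    Parameterized as scaled Euler angles (characteristic arm
    ``rigid_rotation_scale_mm``) plus translation so all six parameters live
    on a millimetre-like scale; the gradient is a central finite difference
    of the sampled MI over the shared per-iteration sample set. After the
    SGD levels a deterministic derivative-free polish (Powell on a single
    large fixed sample set) removes the residual stochastic wander
    (``rigid_polish_samples = 0`` disables it).
    """
    n_lvl = len(config.rigid_factors)
    fixed_pyr = gaussian_pyramid(fixed, n_lvl, config.rigid_factors)
    moving_pyr = gaussian_pyramid(moving, n_lvl, config.rigid_factors)
    if fixed_mask is None:
        fixed_mask = BinaryMask(np.ones(fixed.shape, np.uint8),
                                fixed.spacing, fixed.origin, fixed.direction)
    center = fixed.geometry.world_from_index(
        (np.asarray(fixed.shape) - 1) / 2.0)
    rng = np.random.default_rng(config.seed + 1)
    trace = OptimizationTrace()
    rot_scale = config.rigid_rotation_scale_mm
    h = config.rigid_fd_step

    q = np.zeros(6)
    if init is not None:
        # initial translation only (rotation folded into samples is rare
        # for the shallow-breathing drift this stage compensates)
        q[3:] = init.translation

    for li in range(n_lvl):
        fixed_lvl = fixed_pyr[li]
        moving_spl = SplineImage(moving_pyr[li])
        mask_lvl = resample(fixed_mask, None, fixed_lvl.geometry, "nearest",
                            0)
        franges = intensity_range(fixed_lvl,
                                  mask_lvl if mask_lvl.voxels.any() else None)
        mranges = intensity_range(moving_pyr[li])

        trace.start_level(level=li, pyramid_factor=config.rigid_factors[li])

        def cost_and_grad(qv, t, _fixed=fixed_lvl, _moving=moving_spl,
                          _fr=franges, _mr=mranges):
            samples = draw_samples(fixed_mask,
                                   config.samples_per_iteration, rng)

            def cost_at(qq):
                T = _rigid_from_params(qq, center, rot_scale)
                hist = joint_histogram(_fixed, _moving, T, samples,
                                       config.bins, _fr, _mr)
                return -mutual_information(hist)

            c0 = cost_at(qv)
            grad = np.zeros(6)
            for d in range(6):
                e = np.zeros(6)
                e[d] = h
                grad[d] = (cost_at(qv + e) - cost_at(qv - e)) / (2 * h)
            return c0, grad

        q, trace = sgd_minimize(
            cost_and_grad, q, config.rigid_iterations,
            a=config.gain_a, A=config.gain_A, decay=config.gain_decay,
            target_first_step=1.0, trace=trace)

    if config.rigid_polish_samples > 0:
        from scipy import optimize

        fixed_lvl = fixed_pyr[-1]
        moving_spl = SplineImage(moving_pyr[-1])
        mask_lvl = resample(fixed_mask, None, fixed_lvl.geometry, "nearest",
                            0)
        franges = intensity_range(fixed_lvl,
                                  mask_lvl if mask_lvl.voxels.any() else None)
        mranges = intensity_range(moving_pyr[-1])
        samples = draw_samples(fixed_mask, config.rigid_polish_samples, rng)

        def neg_mi(qq):
            T = _rigid_from_params(qq, center, rot_scale)
            hist = joint_histogram(fixed_lvl, moving_spl, T, samples,
                                   config.bins, franges, mranges)
            return -mutual_information(hist)

        res = optimize.minimize(neg_mi, q, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-8,
                                         "maxiter": 50})
        q = np.asarray(res.x, float)
        trace.start_level(level="polish", n_samples=len(samples))
        trace.record(res.fun, 0.0, 0.0)

    return _rigid_from_params(q, center, rot_scale), trace
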