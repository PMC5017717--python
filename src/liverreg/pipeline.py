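"""The clinical two-stage registration workflow.

Stage 1 non-rigidly registers the diagnostic image D (moving) to the full
intra-operative image F (fixed), initialized by a center-of-mass alignment
of the liver masks with an optional manual z-rotation. If the result is
judged inaccurate (DSC <= 80% or MCD >= 10 mm), the user seeds a refinement
that repeats the registration with a local rigidity penalty. Stage 2
rigidly registers F to the thin needle image N, composes both results to
initialize a final non-rigid D-to-N registration, and maps the tumor
annotation into N for integrated needle/tumor visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import (ConfigurationError, ContractViolationError,
                          DomainError, EmptyInputError)
from .image_core import (BinaryMask, Image3D, PointSetMM, center_of_mass,
                         resample)
from .evaluation import EvaluationReport, evaluate_masks
from .optimizer import (RegistrationConfig, multires_register, rigid_register)
from .rigidity_penalty import build_coefficient_mask
from .transforms import CompositeTransform, RigidTransform3D

#: success rule: DSC strictly above 80% and, when available, MCD below 10 mm
DSC_SUCCESS_THRESHOLD = 0.80
MCD_SUCCESS_THRESHOLD_MM = 10.0


@dataclass
class CaseBundle:
    """All inputs of one case (synthetic or clinical)."""

    D: Image3D
    F: Image3D
    D_liver_mask: BinaryMask
    F_liver_mask: BinaryMask
    D_tumor_mask: BinaryMask | None = None
    N: Image3D | None = None
    D_landmarks: PointSetMM | None = None
    F_landmarks: PointSetMM | None = None
    refinement_seeds: PointSetMM | None = None
    z_rotation_deg: float = 0.0

    def __post_init__(self):
        if not self.D.geometry.same_as(self.D_liver_mask.geometry):
            raise ContractViolationError("D liver mask geometry mismatch")
        if not self.F.geometry.same_as(self.F_liver_mask.geometry):
            raise ContractViolationError("F liver mask geometry mismatch")
        if self.N is not None and self.N.shape[2] >= self.F.shape[2]:
            raise ContractViolationError(
                "N must have fewer slices than F")


@dataclass
class PipelineResult:
    """Transforms, mapped annotations and reports accumulated per stage."""

    T_DF: object | None = None            # maps F-domain points into D
    T_FN: RigidTransform3D | None = None  # maps N-domain points into F
    T_DN: object | None = None            # maps N-domain points into D
    tumor_on_F: BinaryMask | None = None
    tumor_on_N: BinaryMask | None = None
    reports: dict = field(default_factory=dict)
    coefficient_mask: object | None = None
    refined: bool = False
    success: bool | None = None
    traces: dict = field(default_factory=dict)


def initialize_alignment(fixed_mask: BinaryMask, moving_mask: BinaryMask,
                         z_rotation_deg: float = 0.0) -> RigidTransform3D:
    """Center-of-mass initialization with a manual z-rotation.

    Rotates by ``z_rotation_deg`` about the moving mask's center of mass and
    translates so the fixed mask's center of mass maps onto the moving one.
    """
    c_fixed = center_of_mass(fixed_mask)
    c_moving = center_of_mass(moving_mask)
    ang = np.deg2rad(z_rotation_deg)
    rot = RigidTransform3D.from_euler_zyx((0.0, 0.0, ang),
                                          (0.0, 0.0, 0.0), c_moving)
    t = -(rot.rotation @ (c_fixed - c_moving))
    return RigidTransform3D(rot.rotation, t, c_moving)


def classify_success(report: EvaluationReport) -> dict:
    """Apply the success rule: DSC > 80% and (no MCD or MCD < 10 mm)."""
    if report.dsc is None:
        raise ContractViolationError("report lacks a DSC value")
    ok = report.dsc > DSC_SUCCESS_THRESHOLD and (
        report.mcd_mm is None or report.mcd_mm < MCD_SUCCESS_THRESHOLD_MM)
    return {"success": ok, "needs_refinement": not ok}


def _range_mask(mask: BinaryMask, margin_mm: float = 12.0) -> BinaryMask:
    """Liver mask dilated by ``margin_mm`` — used only to restrict the
    moving-image intensity range so the histogram bins resolve soft-tissue
    contrast instead of spanning air to bone."""
    from scipy import ndimage
    it = max(1, int(round(margin_mm / float(np.min(mask.spacing)))))
    grown = ndimage.binary_dilation(np.asarray(mask.voxels) != 0,
                                    iterations=it)
    return BinaryMask(grown.astype(np.uint8), mask.spacing, mask.origin,
                      mask.direction)


def map_annotation(mask_on_D: BinaryMask, T, target) -> BinaryMask:
    """Nearest-neighbour mapping of a diagnostic-frame mask through ``T``
    (which maps target-domain points into D) onto the target geometry."""
    out = resample(mask_on_D, T, target, "nearest", 0)
    return BinaryMask(out.voxels, out.spacing, out.origin, out.direction)


def _evaluate_stage(bundle: CaseBundle, T, fixed_image, fixed_liver_ref,
                    landmarks_fixed):
    """DSC/MSD of the mapped D liver mask vs the fixed-frame liver, MCD when
    landmarks exist; the report also carries the success classification."""
    mapped = map_annotation(bundle.D_liver_mask, T, fixed_image.geometry)
    rep = evaluate_masks(mapped, fixed_liver_ref,
                         bundle.D_landmarks if landmarks_fixed is not None
                         else None,
                         landmarks_fixed, T)
    rep.success = classify_success(rep)["success"]
    return rep


def stage1(bundle: CaseBundle, config: RegistrationConfig,
           result: PipelineResult | None = None) -> PipelineResult:
    """Initial non-rigid D -> F registration (rigidity off)."""
    result = result or PipelineResult()
    init = initialize_alignment(bundle.F_liver_mask, bundle.D_liver_mask,
                                bundle.z_rotation_deg)
    T_DF, trace = multires_register(
        fixed=bundle.F, moving=bundle.D, fixed_mask=bundle.F_liver_mask,
        init=init, config=config, rigidity=None,
        moving_mask=_range_mask(bundle.D_liver_mask))
    result.T_DF = T_DF
    result.traces["stage1"] = trace
    result.refined = False
    rep = _evaluate_stage(bundle, T_DF, bundle.F, bundle.F_liver_mask,
                          bundle.F_landmarks)
    result.reports["stage1"] = rep
    result.success = rep.success
    if bundle.D_tumor_mask is not None:
        result.tumor_on_F = map_annotation(bundle.D_tumor_mask, T_DF,
                                           bundle.F.geometry)
    return result


def refine(bundle: CaseBundle, prior: PipelineResult, seeds: PointSetMM,
           config: RegistrationConfig) -> PipelineResult:
    """User-guided refinement: re-run the full multiresolution registration
    with the local rigidity penalty active inside the seeded regions.

    The failed deformation is exactly what must be undone, so the
    registration restarts from the same initialization rather than
    warm-starting from the failed result.
    """
    if prior.T_DF is None:
        raise ContractViolationError("refine requires a stage-1 result")
    if seeds is None or len(seeds) == 0:
        raise EmptyInputError("refinement requires at least one seed point")
    cmask = build_coefficient_mask(seeds, bundle.D.geometry)
    init = initialize_alignment(bundle.F_liver_mask, bundle.D_liver_mask,
                                bundle.z_rotation_deg)
    T_DF, trace = multires_register(
        fixed=bundle.F, moving=bundle.D, fixed_mask=bundle.F_liver_mask,
        init=init, config=config,
        rigidity=(cmask, config.rigidity_weights),
        moving_mask=_range_mask(bundle.D_liver_mask))
    prior.T_DF = T_DF
    prior.coefficient_mask = cmask
    prior.refined = True
    prior.traces["refine"] = trace
    rep = _evaluate_stage(bundle, T_DF, bundle.F, bundle.F_liver_mask,
                          bundle.F_landmarks)
    prior.reports["refine"] = rep
    prior.success = rep.success
    if bundle.D_tumor_mask is not None:
        prior.tumor_on_F = map_annotation(bundle.D_tumor_mask, T_DF,
                                          bundle.F.geometry)
    return prior


def stage2(bundle: CaseBundle, prior: PipelineResult,
           config: RegistrationConfig,
           skip_final_nonrigid: bool = False) -> PipelineResult:
    """Needle-image stage: rigid F -> N, then non-rigid D -> N.

    The rigid registration aligns the thin slab N (fixed) to F (moving,
    identity init). The final non-rigid registration of D (moving) to N
    (fixed) is initialized with the composition T_DF o T_FN and starts at
    the finer grid levels only — the slab cannot support a coarse grid and
    the initialization is already close. With ``skip_final_nonrigid`` the
    composition itself is used (the concatenation-only baseline).
    """
    if prior.T_DF is None:
        raise ContractViolationError("stage2 requires a stage-1 result")
    if bundle.N is None:
        raise ContractViolationError("stage2 requires the needle image N")
    if bundle.N.shape[2] < 3:
        raise ContractViolationError("needle slab has fewer than 3 slices")

    N = bundle.N
    n_mask = None
    if config.needle_exclude_hu is not None:
        bright = np.asarray(N.voxels) >= config.needle_exclude_hu
        if bright.any():
            # grow the exclusion to cover partial-volume / smoothing halos
            from scipy import ndimage
            bright = ndimage.binary_dilation(bright, iterations=2)
        n_mask = BinaryMask((~bright).astype(np.uint8), N.spacing, N.origin,
                            N.direction)
    T_FN, rigid_trace = rigid_register(fixed=N, moving=bundle.F,
                                       fixed_mask=n_mask, config=config)
    prior.T_FN = T_FN
    prior.traces["stage2_rigid"] = rigid_trace

    init = CompositeTransform([prior.T_DF, T_FN])
    if skip_final_nonrigid:
        prior.T_DN = init
    else:
        # fixed mask on N: the stage-1-mapped D liver mask restricted to the
        # slab's field of view (a liver mask of N itself is unavailable)
        mapped_liver = map_annotation(bundle.D_liver_mask, init, N.geometry)
        if config.needle_exclude_hu is not None:
            mapped_liver = BinaryMask(
                mapped_liver.voxels * n_mask.voxels, N.spacing, N.origin,
                N.direction)
        if mapped_liver.n_voxels == 0:
            raise DomainError("stage-1 liver mask does not reach the slab")
        rigidity = None
        if prior.coefficient_mask is not None:
            rigidity = (prior.coefficient_mask, config.rigidity_weights)
        T_DN, trace = multires_register(
            fixed=N, moving=bundle.D, fixed_mask=mapped_liver, init=init,
            config=config, rigidity=rigidity,
            first_level=config.stage2_first_level,
            moving_mask=_range_mask(bundle.D_liver_mask))
        prior.T_DN = T_DN
        prior.traces["stage2_nonrigid"] = trace
    if bundle.D_tumor_mask is not None:
        prior.tumor_on_N = map_annotation(bundle.D_tumor_mask, prior.T_DN,
                                          N.geometry)
    return prior
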