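"""Paired diagnostic / intra-operative CT phantoms with ground truth.

No clinical data ships with the package, so every pipeline stage is
exercised on synthetic deformable CT phantoms that emulate the study
conditions: a contrast-enhanced diagnostic volume (liver ~100 HU with
~180 HU vessels, hypodense tumor, soft-tissue background, air), an
intra-operative volume differing by a z-axis patient rotation, a smooth
breathing-state deformation and an optional loss of vessel contrast, and a
thin needle-check slab with a hyperdense needle and a small rigid drift.

The ground-truth deformation is itself a cubic B-spline field, but on a
coarser grid with a jittered origin, so exact recovery is representable
without handing the registration its own parameterization (no inverse
crime). Truth transforms map intra-operative (fixed-side) coordinates into
the diagnostic frame — the same direction the registration estimates — so
landmark errors under the truth transform are zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import (ConfigurationError, ContractViolationError,
                          DomainError)
from .image_core import (BinaryMask, Image3D, ImageGeometry, PointSetMM,
                         center_of_mass, resample)
from .transforms import (BSplineFFD, CompositeTransform, RigidTransform3D)

AIR_HU = -1000.0

_LBL_AIR, _LBL_SOFT, _LBL_BLOB, _LBL_LIVER, _LBL_VESSEL, _LBL_TUMOR = range(6)


@dataclass
class PhantomSpec:
    """Geometry, anatomy and noise parameters of the digital phantom."""

    shape: tuple = (128, 128, 96)
    spacing: tuple = (2.0, 2.0, 3.0)
    liver_center_mm: tuple | None = None      # None -> volume center
    liver_semiaxes_mm: tuple = (55.0, 45.0, 40.0)
    boundary_roughness: float = 0.03          # relative radial modulation
    n_vessel_branches: int = 8
    vessel_radius_mm: float = 3.0
    vessel_hu: float = 180.0
    tumor_offset_mm: tuple = (18.0, -10.0, 8.0)  # from the liver center
    tumor_radius_mm: float = 9.0
    tumor_hu_offset: float = -30.0
    liver_hu: float = 100.0
    soft_tissue_hu: float = 40.0
    blob_hu: float = 70.0
    n_background_blobs: int = 3
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.liver_semiaxes_mm):
            raise ConfigurationError("liver semi-axes must be positive")
        if self.noise_sigma_hu < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        off = np.asarray(self.tumor_offset_mm, float)
        ax = np.asarray(self.liver_semiaxes_mm, float)
        reach = np.linalg.norm(off / ax) + self.tumor_radius_mm / ax.min()
        if reach >= 1.0:
            raise ConfigurationError("tumor does not fit inside the liver")


@dataclass
class DiagnosticPhantom:
    """Rendered diagnostic volume with its annotations and tissue labels."""

    image: Image3D
    liver_mask: BinaryMask
    tumor_mask: BinaryMask
    landmarks: PointSetMM
    labels: np.ndarray
    spec: PhantomSpec


@dataclass
class IntraoperativePhantom:
    """Deformed intra-operative volume with paired landmarks and truth."""

    image: Image3D
    liver_mask: BinaryMask
    landmarks: PointSetMM          # in the F frame
    landmarks_diag: PointSetMM     # paired subset in the D frame
    truth: CompositeTransform      # maps F world coords into D
    z_rotation_deg: float


@dataclass
class NeedleSlab:
    """Thin needle-check acquisition and its ground-truth drift."""

    image: Image3D
    truth: object                  # transform mapping N world coords into F
    drift: RigidTransform3D
    needle_entry_mm: np.ndarray
    needle_tip_mm: np.ndarray


@dataclass
class PhantomTruth:
    """All ground-truth objects of one simulated case."""

    d_from_f: CompositeTransform
    f_from_n: object | None
    landmarks_d: PointSetMM
    landmarks_f: PointSetMM
    breathing_amplitude_mm: float
    drift: RigidTransform3D | None = None


# ---------------------------------------------------------------------------
# Diagnostic phantom
# ---------------------------------------------------------------------------

def _world_grid(geom: ImageGeometry):
    ax = [geom.origin[d] + geom.spacing[d] * np.arange(geom.shape[d])
          for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _ellipsoid(q_world, center, semiaxes):
    d = (q_world - np.asarray(center)) / np.asarray(semiaxes)
    return np.einsum("...d,...d->...", d, d)


def _segment_mask(geom, world, p0, p1, radius):
    """Boolean mask of a capsule (cylinder with round caps) p0 -> p1."""
    v = np.asarray(p1, float) - np.asarray(p0, float)
    L2 = float(v @ v)
    rel = world - np.asarray(p0, float)
    t = np.clip(np.einsum("...d,d->...", rel, v) / max(L2, 1e-12), 0.0, 1.0)
    closest = np.asarray(p0, float) + t[..., None] * v
    d2 = np.einsum("...d,...d->...", world - closest, world - closest)
    return d2 <= radius * radius


def _vessel_tree(spec: PhantomSpec, liver_center, rng):
    """Branching line segments inside the liver; returns (segments, branch
    points). Segments are (p0, p1, radius)."""
    ax = np.asarray(spec.liver_semiaxes_mm)
    segments = []
    points = [np.asarray(liver_center, float)]
    frontier = [(np.asarray(liver_center, float),
                 rng.normal(size=3), spec.vessel_radius_mm)]
    made = 0
    while frontier and made < spec.n_vessel_branches:
        p0, direction, radius = frontier.pop(0)
        direction = direction / np.linalg.norm(direction)
        length = rng.uniform(0.35, 0.6) * ax.min()
        p1 = p0 + direction * length
        # keep endpoints well inside the liver ellipsoid
        if np.linalg.norm((p1 - liver_center) / ax) > 0.85:
            p1 = liver_center + (p1 - liver_center) * 0.6
        segments.append((p0, p1, radius))
        points.append(p1)
        made += 1
        for _ in range(2):
            d = direction + rng.normal(scale=0.7, size=3)
            frontier.append((p1, d, max(radius * 0.7, 1.2)))
    return segments, points


def generate_diagnostic(spec: PhantomSpec) -> DiagnosticPhantom:
    """Render the diagnostic contrast-enhanced phantom (deterministic per
    seed): soft-tissue body, background organ blobs, liver with contrast
    vessels and a hypodense tumor, Gaussian noise on top."""
    rng = np.random.default_rng(spec.seed)
    geom = ImageGeometry(spec.shape, spec.spacing, (0.0, 0.0, 0.0),
                         np.eye(3))
    world = _world_grid(geom)
    extent = np.asarray(geom.shape) * np.asarray(spec.spacing, float)
    vol_center = geom.world_from_index((np.asarray(geom.shape) - 1) / 2.0)
    liver_center = (np.asarray(spec.liver_center_mm, float)
                    if spec.liver_center_mm is not None else vol_center)

    labels = np.full(geom.shape, _LBL_AIR, np.uint8)
    body = _ellipsoid(world, vol_center, extent * 0.47) <= 1.0
    labels[body] = _LBL_SOFT

    for _ in range(spec.n_background_blobs):
        c = vol_center + rng.uniform(-0.3, 0.3, 3) * extent
        axes = rng.uniform(8, 20, 3)
        blob = _ellipsoid(world, c, axes) <= 1.0
        labels[blob & body] = _LBL_BLOB

    q = _ellipsoid(world, liver_center, spec.liver_semiaxes_mm)
    if spec.boundary_roughness > 0:
        rough = ndimage.gaussian_filter(rng.normal(size=geom.shape), 6.0,
                                        mode="nearest")
        rough = rough / max(rough.std(), 1e-9) * spec.boundary_roughness
        liver = q <= (1.0 + rough) ** 2
    else:
        liver = q <= 1.0
    liver &= body
    labels[liver] = _LBL_LIVER

    segments, branch_points = _vessel_tree(spec, liver_center, rng)
    for p0, p1, r in segments:
        seg = _segment_mask(geom, world, p0, p1, r)
        labels[seg & liver] = _LBL_VESSEL

    tumor_center = liver_center + np.asarray(spec.tumor_offset_mm, float)
    tumor = _ellipsoid(world, tumor_center,
                       (spec.tumor_radius_mm,) * 3) <= 1.0
    tumor &= liver
    labels[tumor] = _LBL_TUMOR

    image = Image3D(render_labels(labels, spec, contrast=True), geom.spacing,
                    geom.origin, geom.direction)
    if spec.noise_sigma_hu > 0:
        image.voxels = image.voxels + rng.normal(
            scale=spec.noise_sigma_hu, size=geom.shape)

    liver_mask = BinaryMask(liver.astype(np.uint8), geom.spacing,
                            geom.origin, geom.direction)
    tumor_mask = BinaryMask(tumor.astype(np.uint8), geom.spacing,
                            geom.origin, geom.direction)

    # landmarks: vessel branch points (and midpoints if needed) in the liver
    pts = [p for p in branch_points
           if np.linalg.norm((p - liver_center)
                             / np.asarray(spec.liver_semiaxes_mm)) < 0.9]
    for p0, p1, _ in segments:
        if len(pts) >= 15:
            break
        mid = (np.asarray(p0) + np.asarray(p1)) / 2.0
        pts.append(mid)
    landmarks = PointSetMM(np.asarray(pts))
    return DiagnosticPhantom(image, liver_mask, tumor_mask, landmarks,
                             labels, spec)


def render_labels(labels, spec: PhantomSpec, contrast: bool) -> np.ndarray:
    """Noise-free HU volume from tissue labels; without contrast agent the
    vessels take the liver parenchyma intensity."""
    hu = {_LBL_AIR: AIR_HU, _LBL_SOFT: spec.soft_tissue_hu,
          _LBL_BLOB: spec.blob_hu, _LBL_LIVER: spec.liver_hu,
          _LBL_VESSEL: spec.vessel_hu if contrast else spec.liver_hu,
          _LBL_TUMOR: spec.liver_hu + spec.tumor_hu_offset}
    lut = np.array([hu[k] for k in range(6)])
    return lut[labels]


# ---------------------------------------------------------------------------
# Intra-operative phantom
# ---------------------------------------------------------------------------

def _random_breathing_ffd(geom: ImageGeometry, amplitude_mm, grid_mm, rng):
    lo, hi = geom.world_bounds()
    jitter = rng.uniform(0.0, grid_mm / 3.0, 3)
    ffd = BSplineFFD.for_domain(lo - jitter, hi, grid_mm, extrapolate="zero")
    coeffs = rng.normal(scale=amplitude_mm / 2.0,
                        size=ffd.coefficients.shape)
    ffd.coefficients = np.clip(coeffs, -amplitude_mm, amplitude_mm)
    return ffd


def _min_det_jacobian(transform, geom: ImageGeometry, n=12):
    lo, hi = geom.world_bounds()
    ax = [np.linspace(lo[d], hi[d], n) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return float(np.linalg.det(transform.spatial_jacobian(pts)).min())


def _invert_pointwise(truth, rigid: RigidTransform3D, ffd: BSplineFFD,
                      targets, n_iter=60, tol=1e-12):
    """Solve truth(b) = a for b when truth(x) = rigid(x + u(x)): fixed-point
    iteration b <- rigid^-1(a) - u(b), contracting for |grad u| < 1."""
    y = rigid.inverse().apply(targets)
    b = y.copy()
    for _ in range(n_iter):
        b_new = y - ffd.displacement(b)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    return b


def make_intraoperative(diag: DiagnosticPhantom, pose_z_deg: float = 30.0,
                        pose_translation_mm=(0.0, 0.0, 0.0),
                        breathing_amplitude_mm: float = 15.0,
                        breathing_grid_mm: float = 50.0,
                        contrast: bool = False,
                        seed: int = 1) -> IntraoperativePhantom:
    """Simulate the intra-operative volume F from the diagnostic phantom.

    The ground-truth transform (F world -> D world) is a z-rotation about
    the diagnostic liver center of mass plus a translation, composed with a
    smooth random B-spline "breathing" deformation clipped to the given
    amplitude. ``contrast=False`` re-renders the source without vessel
    enhancement before deforming (the intra-operative scan is typically
    non-contrast). Raises if the requested amplitude folds space.
    """
    spec = diag.spec
    rng = np.random.default_rng(seed + 10_000)
    geom = diag.image.geometry
    com = center_of_mass(diag.liver_mask)
    ang = np.deg2rad(pose_z_deg)
    rigid = RigidTransform3D.from_euler_zyx((0.0, 0.0, ang),
                                            pose_translation_mm, com)
    if breathing_amplitude_mm > 0:
        ffd = _random_breathing_ffd(geom, breathing_amplitude_mm,
                                    breathing_grid_mm, rng)
    else:
        lo, hi = geom.world_bounds()
        ffd = BSplineFFD.for_domain(lo, hi, breathing_grid_mm,
                                    extrapolate="zero")
    truth = CompositeTransform([rigid, ffd])
    if _min_det_jacobian(truth, geom) <= 0.0:
        raise ConfigurationError(
            "breathing amplitude produces a folding deformation; "
            "reduce breathing_amplitude_mm or enlarge breathing_grid_mm")

    source = Image3D(render_labels(diag.labels, spec, contrast),
                     geom.spacing, geom.origin, geom.direction)
    f_image = resample(source, truth, geom, "linear", AIR_HU)
    if spec.noise_sigma_hu > 0:
        f_image.voxels = f_image.voxels + rng.normal(
            scale=spec.noise_sigma_hu, size=geom.shape)
    f_mask = resample(diag.liver_mask, truth, geom, "nearest", 0)

    # landmarks: b_i with truth(b_i) = a_i, kept while inside the volume
    a = diag.landmarks.points
    b = _invert_pointwise(truth, rigid, ffd, a)
    lo, hi = geom.world_bounds()
    keep = np.all((b >= lo) & (b <= hi), axis=1)
    return IntraoperativePhantom(
        f_image, BinaryMask(f_mask.voxels, geom.spacing, geom.origin,
                            geom.direction),
        PointSetMM(b[keep]), PointSetMM(a[keep]), truth, pose_z_deg)


# ---------------------------------------------------------------------------
# Needle slab
# ---------------------------------------------------------------------------

def extract_needle_slab(f_image: Image3D, slab_center_mm, n_slices: int,
                        drift: RigidTransform3D | None = None,
                        needle_entry_mm=None, needle_tip_mm=None,
                        needle_radius_mm: float = 1.5,
                        needle_hu: float = 3000.0,
                        extra_deformation: BSplineFFD | None = None,
                        noise_sigma_hu: float = 0.0,
                        seed: int = 2) -> NeedleSlab:
    """Simulate the limited-FOV needle-check acquisition N.

    N is ``n_slices`` axial slices of F around ``slab_center_mm`` after a
    small rigid drift (and an optional extra non-rigid motion, emulating a
    breathing-state change between F and N); a needle — a hyperdense
    cylinder from entry to tip — is rasterized into the slab. The returned
    truth transform maps N world coordinates into F.
    """
    geom = f_image.geometry
    if not (3 <= n_slices < geom.shape[2]):
        raise ContractViolationError(
            f"n_slices must be in [3, {geom.shape[2]}), got {n_slices}")
    center_idx = geom.index_from_world(np.asarray(slab_center_mm, float))
    kc = int(round(center_idx[2]))
    k0 = kc - n_slices // 2
    if k0 < 0 or k0 + n_slices > geom.shape[2]:
        raise DomainError("requested slab extends outside the volume")
    drift = drift if drift is not None else RigidTransform3D()
    truth = (CompositeTransform([drift, extra_deformation])
             if extra_deformation is not None else drift)

    slab_origin = geom.world_from_index((0, 0, k0))
    slab_geom = ImageGeometry((geom.shape[0], geom.shape[1], n_slices),
                              geom.spacing, slab_origin, geom.direction)
    n_image = resample(f_image, truth, slab_geom, "linear", AIR_HU)
    if noise_sigma_hu > 0:
        rng = np.random.default_rng(seed + 20_000)
        n_image.voxels = n_image.voxels + rng.normal(
            scale=noise_sigma_hu, size=slab_geom.shape)

    entry = np.asarray(needle_entry_mm, float) if needle_entry_mm is not None \
        else None
    tip = np.asarray(needle_tip_mm, float) if needle_tip_mm is not None \
        else None
    if entry is not None and tip is not None:
        world = _world_grid(slab_geom)
        needle = _segment_mask(slab_geom, world, entry, tip,
                               needle_radius_mm)
        n_image.voxels[needle] = needle_hu
    return NeedleSlab(n_image, truth, drift,
                      entry if entry is not None else np.full(3, np.nan),
                      tip if tip is not None else np.full(3, np.nan))


# ---------------------------------------------------------------------------
# Full case assembly
# ---------------------------------------------------------------------------

def tumor_centroid_mm(mask: BinaryMask):
    return center_of_mass(mask)


def simulate_case(spec: PhantomSpec | None = None, seed: int = 0,
                  pose_z_deg: float = 30.0,
                  pose_translation_mm=(8.0, -5.0, 4.0),
                  breathing_amplitude_mm: float = 15.0,
                  contrast: bool = False, with_slab: bool = True,
                  n_slices: int = 5, drift_translation_mm=(3.0, -2.0, 1.5),
                  drift_z_deg: float = 1.0,
                  slab_extra_amplitude_mm: float = 0.0):
    """Generate a complete simulated case (bundle + ground truth).

    The needle slab is centered on the tumor's intra-operative position,
    with the needle tip at the tumor centroid. ``slab_extra_amplitude_mm``
    adds a small non-rigid breathing-state change between F and N (so the
    true F -> N motion is no longer purely rigid).
    """
    from .pipeline import CaseBundle

    spec = spec if spec is not None else PhantomSpec(seed=seed)
    diag = generate_diagnostic(spec)
    intra = make_intraoperative(
        diag, pose_z_deg, pose_translation_mm, breathing_amplitude_mm,
        contrast=contrast, seed=seed + 1)

    N = None
    slab_truth = None
    drift = None
    if with_slab:
        rigid, ffd = intra.truth.components
        tumor_c_d = tumor_centroid_mm(diag.tumor_mask)
        tumor_c_f = _invert_pointwise(intra.truth, rigid, ffd,
                                      tumor_c_d[None])[0]
        drift = RigidTransform3D.from_euler_zyx(
            (0.0, 0.0, np.deg2rad(drift_z_deg)), drift_translation_mm,
            tumor_c_f)
        extra = None
        if slab_extra_amplitude_mm > 0:
            rng = np.random.default_rng(seed + 30_000)
            extra = _random_breathing_ffd(diag.image.geometry,
                                          slab_extra_amplitude_mm, 60.0, rng)
        tip_n = drift.inverse().apply(tumor_c_f)
        entry_n = tip_n + np.array([55.0, 10.0, 6.0])
        slab = extract_needle_slab(
            intra.image, tumor_c_f, n_slices, drift, entry_n, tip_n,
            extra_deformation=extra, noise_sigma_hu=0.0, seed=seed + 2)
        N = slab.image
        slab_truth = slab.truth

    bundle = CaseBundle(
        D=diag.image, F=intra.image,
        D_liver_mask=diag.liver_mask, F_liver_mask=intra.liver_mask,
        D_tumor_mask=diag.tumor_mask, N=N,
        D_landmarks=intra.landmarks_diag, F_landmarks=intra.landmarks,
        z_rotation_deg=pose_z_deg)
    truth = PhantomTruth(intra.truth, slab_truth, intra.landmarks_diag,
                         intra.landmarks, breathing_amplitude_mm, drift)
    return bundle, truth
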