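"""Locally-weighted rigidity regularizer for user-guided refinement.

When the unconstrained registration produces an implausible deformation in
some region, the user marks it with a few seed points (in the diagnostic,
i.e. moving, image). Each seed is dilated with a 1x1x1 cm kernel; the union
forms a coefficient mask ``c(x)`` in [0, 1] inside which non-rigid
deformation is penalized:

    P_rigid = [ sum_x c(x + T(x)) ]^-1 * sum_x c(x + T(x)) *
              ( c_AC sum AC^2 + c_OC sum OC^2 + c_PC PC^2 )

with the three local conditions derived from the transform's spatial
derivatives: the affinity condition AC is the second-derivative tensor
(zero iff locally affine), the orthonormality condition OC = J'J - I
(zero iff the local Jacobian is orthonormal), and the properness condition
PC = det J - 1 (zero iff locally volume preserving). All three vanish
simultaneously exactly when the transform is locally rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import (ConfigurationError, DegenerateMaskError,
                          DomainError, EmptyInputError)
from .image_core import Image3D, ImageGeometry, PointSetMM
from .transforms import BSplineFFD


@dataclass
class RigidityWeights:
    """Term weights and the per-resolution overall penalty weight alpha.

    Defaults follow the reference registration settings: overall weight
    [0.1, 0.1, 0.1, 4.0] across the four resolutions, affinity 100,
    orthonormality 1, properness 2.
    """

    c_AC: float = 100.0
    c_OC: float = 1.0
    c_PC: float = 2.0
    alpha_per_resolution: list = field(
        default_factory=lambda: [0.1, 0.1, 0.1, 4.0])

    def __post_init__(self):
        if min(self.c_AC, self.c_OC, self.c_PC) < 0 \
                or any(a < 0 for a in self.alpha_per_resolution):
            raise ConfigurationError("rigidity weights must be >= 0")


@dataclass
class RigidityTermValues:
    """The three rigidity conditions evaluated at one point."""

    AC: np.ndarray  # (3, 3, 3) second-derivative tensor
    OC: np.ndarray  # (3, 3) J'J - I
    PC: float       # det J - 1


class CoefficientMask:
    """Scalar field c(x) in [0, 1] on the moving-image geometry."""

    def __init__(self, field_image: Image3D, seeds: PointSetMM,
                 kernel_mm, feather_mm: float):
        v = np.asarray(field_image.voxels, float)
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ConfigurationError("coefficient values must lie in [0, 1]")
        field_image.voxels = np.clip(v, 0.0, 1.0)
        self.field = field_image
        self.seeds = seeds
        self.kernel_mm = np.asarray(kernel_mm, float)
        self.feather_mm = float(feather_mm)

    @staticmethod
    def uniform(geometry: ImageGeometry) -> "CoefficientMask":
        """c = 1 everywhere (penalize the whole domain)."""
        img = Image3D(np.ones(geometry.shape), geometry.spacing,
                      geometry.origin, geometry.direction)
        return CoefficientMask(img, PointSetMM(np.empty((0, 3))),
                               (0, 0, 0), 0.0)

    def values_at(self, points_mm):
        """Linear interpolation of c at world points; 0 outside the field."""
        idx = self.field.index_from_world(np.atleast_2d(points_mm))
        return ndimage.map_coordinates(self.field.voxels, idx.T, order=1,
                                       mode="constant", cval=0.0)


def build_coefficient_mask(seeds: PointSetMM, meta, kernel_mm=(10.0,) * 3,
                           feather_mm: float = 5.0) -> CoefficientMask:
    """Dilate each seed by a cube of side ``kernel_mm`` and union them.

    The kernel side is converted to voxels and rounded up to the nearest odd
    count per axis (so a 10 mm kernel at 1 mm spacing spans 11 voxels). With
    ``feather_mm > 0`` the binary region is surrounded by a smoothstep ramp
    of that width (based on the Euclidean distance to the region), easing
    the transition between locally-rigid and free areas.
    """
    geom = meta.geometry if isinstance(meta, Image3D) else meta
    if len(seeds) == 0:
        raise EmptyInputError("need at least one seed point")
    kernel = np.broadcast_to(np.asarray(kernel_mm, float), (3,))
    n_vox = np.ceil(kernel / geom.spacing).astype(int)
    n_vox += 1 - (n_vox % 2)  # round up to odd
    half = n_vox // 2

    shape = np.asarray(geom.shape)
    region = np.zeros(geom.shape, bool)
    idx = np.round(geom.index_from_world(seeds.points)).astype(int)
    for p, s in zip(idx, seeds.points):
        if np.any(p < 0) or np.any(p > shape - 1):
            raise DomainError(f"seed {s} outside the image domain")
        lo = np.maximum(p - half, 0)
        hi = np.minimum(p + half + 1, shape)
        region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True

    if feather_mm > 0:
        d = ndimage.distance_transform_edt(~region, sampling=geom.spacing)
        s = np.clip(1.0 - d / feather_mm, 0.0, 1.0)
        c = s * s * (3.0 - 2.0 * s)  # smoothstep; 1 on the region itself
    else:
        c = region.astype(float)
    img = Image3D(c, geom.spacing, geom.origin, geom.direction)
    return CoefficientMask(img, seeds, kernel, feather_mm)


# ---------------------------------------------------------------------------
# Penalty terms
# ---------------------------------------------------------------------------

def _cofactor(J):
    """Cofactor matrices C with C[n, i, j] = d det(J_n) / d J_n[i, j]."""
    r0, r1, r2 = J[:, 0], J[:, 1], J[:, 2]
    return np.stack([np.cross(r1, r2), np.cross(r2, r0), np.cross(r0, r1)],
                    axis=1)


def _terms_batch(transform, points):
    """(AC (n,3,3,3), OC (n,3,3), PC (n,)) at a batch of points."""
    pts = np.atleast_2d(np.asarray(points, float))
    J = transform.spatial_jacobian(pts)
    H = transform.second_derivatives(pts)
    OC = np.einsum("nki,nkj->nij", J, J) - np.eye(3)
    PC = np.linalg.det(J) - 1.0
    return H, OC, PC, J


def rigidity_terms(transform, point) -> RigidityTermValues:
    """The three rigidity conditions at one point (zero iff locally rigid)."""
    H, OC, PC, _ = _terms_batch(transform, point)
    return RigidityTermValues(H[0], OC[0], float(PC[0]))


def default_eval_points(ffd: BSplineFFD, lo_mm, hi_mm,
                        spacing_mm: float | None = None):
    """Evaluation grid for the penalty inside both the given world box and
    the FFD's fully-supported interior.

    With ``spacing_mm=None`` the FFD's control-point locations are used;
    otherwise a regular grid with the given spacing, which keeps the
    penalty discretization independent of the (possibly very coarse)
    control grid."""
    slo, shi = ffd.supported_bounds()
    # stay strictly below the upper support bound (a node exactly on it has
    # an incomplete, though zero-weighted, neighbourhood)
    lo = np.maximum(np.asarray(lo_mm, float), slo)
    hi = np.minimum(np.asarray(hi_mm, float),
                    shi - 1e-6 * ffd.control_spacing)
    if spacing_mm is None:
        cp = ffd.control_points().reshape(-1, 3)
        keep = np.all((cp >= lo) & (cp <= hi), axis=1)
        return cp[keep]
    ax = [np.arange(lo[d], hi[d] + 1e-12, float(spacing_mm))
          for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def _point_weights(transform, cmask, eval_points):
    pts = np.atleast_2d(np.asarray(eval_points, float))
    if cmask is None:
        c = np.ones(len(pts))
    else:
        c = cmask.values_at(transform.apply(pts))
    total = c.sum()
    if total <= 0:
        raise DegenerateMaskError(
            "coefficient mask is zero at every evaluation point")
    return pts, c, total


def rigidity_penalty(transform, cmask, w: RigidityWeights, eval_points,
                     c_transform=None) -> float:
    """c-weighted mean of the squared rigidity conditions over eval_points.

    ``cmask`` lives on the moving-image geometry and is evaluated at the
    transformed locations x + T(x); pass ``cmask=None`` for a uniform mask.
    ``c_transform`` optionally supplies a different (e.g. composite)
    transform for that lookup while the conditions are evaluated on
    ``transform`` itself.
    """
    pts, c, total = _point_weights(c_transform or transform, cmask,
                                   eval_points)
    H, OC, PC, _ = _terms_batch(transform, pts)
    per_point = (w.c_AC * np.einsum("nkij->n", H ** 2)
                 + w.c_OC * np.einsum("nij->n", OC ** 2)
                 + w.c_PC * PC ** 2)
    return float((c * per_point).sum() / total)


def rigidity_gradient(ffd: BSplineFFD, cmask, w: RigidityWeights,
                      eval_points, c_transform=None):
    """(penalty, d penalty / d mu) with the coefficient weights frozen.

    The mask weights c(x + T(x)) and their normalization are treated as
    constants with respect to mu (frozen-weight approximation); only the
    rigidity conditions are differentiated, analytically through the
    B-spline basis derivatives.
    """
    pts, c, total = _point_weights(c_transform or ffd, cmask, eval_points)
    H, OC, PC, J = _terms_batch(ffd, pts)

    value = float((c * (w.c_AC * np.einsum("nkij->n", H ** 2)
                        + w.c_OC * np.einsum("nij->n", OC ** 2)
                        + w.c_PC * PC ** 2)).sum() / total)

    i0, u, ok = ffd._support(pts)
    ffd._check_support(ok)
    # basis first derivatives G (n,4,4,4,3) and second derivatives
    # Hw (n,4,4,4,3,3) of every supporting control point
    G = np.stack([ffd._tensor_weights(u, tuple(int(a == d) for a in range(3)))
                  for d in range(3)], axis=-1)
    Hw = np.zeros(G.shape[:4] + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            orders = [0, 0, 0]
            orders[i] += 1
            orders[j] += 1
            wij = ffd._tensor_weights(u, tuple(orders))
            Hw[..., i, j] = wij
            Hw[..., j, i] = wij

    # d(sum OC^2)/dJ = 4 J OC ; d(PC^2)/dJ = 2 PC cof(J) ;
    # dJ[k, i]/dmu[c, d] = delta_kd * G[c, i]
    M = (4.0 * w.c_OC * np.einsum("nij,njk->nik", J, OC)
         + 2.0 * w.c_PC * PC[:, None, None] * _cofactor(J))
    contrib = np.einsum("ndi,nabci->nabcd", M, G)
    contrib += 2.0 * w.c_AC * np.einsum("ndij,nabcij->nabcd", H, Hw)
    contrib *= (c / total)[:, None, None, None, None]

    grad = np.zeros_like(ffd.coefficients)
    off = np.arange(4)
    ix = np.clip(i0[:, 0, None] + off, 0, ffd.grid_shape[0] - 1)
    iy = np.clip(i0[:, 1, None] + off, 0, ffd.grid_shape[1] - 1)
    iz = np.clip(i0[:, 2, None] + off, 0, ffd.grid_shape[2] - 1)
    shape4 = contrib.shape[:4]
    gi = np.broadcast_to(ix[:, :, None, None], shape4)
    gj = np.broadcast_to(iy[:, None, :, None], shape4)
    gk = np.broadcast_to(iz[:, None, None, :], shape4)
    np.add.at(grad, (gi.ravel(), gj.ravel(), gk.ravel()),
              contrib.reshape(-1, 3))
    return value, grad
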