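"""Rigid, cubic B-spline free-form deformation, and composite transforms.

All transforms map fixed-image world coordinates (mm) to moving-image world
coordinates (mm) — the resampling convention: the registered moving image is
``I_M(T(x))`` on the fixed lattice. The landmark-error metric's "transform
from image B to image A" is this same object with B fixed and A moving.

The FFD is the classical uniform cubic B-spline free-form deformation
``T(x) = x + u(x)``, ``u(x) = sum_c mu_c B3((x - x_c)/h)`` over the 4x4x4
control points supporting ``x``. First and second spatial derivatives are
analytic (B-spline basis derivatives), as required by the local rigidity
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, DomainError

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Cubic B-spline basis (uniform, local coordinate u in [0, 1))
# ---------------------------------------------------------------------------

def bspline3_weights(u, order=0):
    """Weights of the 4 support control points for local coordinate ``u``.

    ``order`` selects the value (0), first (1) or second (2) derivative with
    respect to ``u``. Returns an array of shape ``u.shape + (4,)``.
    """
    u = np.asarray(u, float)
    w = np.empty(u.shape + (4,))
    if order == 0:
        w[..., 0] = (1 - u) ** 3 / 6.0
        w[..., 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
        w[..., 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
        w[..., 3] = u**3 / 6.0
    elif order == 1:
        w[..., 0] = -((1 - u) ** 2) / 2.0
        w[..., 1] = (9 * u**2 - 12 * u) / 6.0
        w[..., 2] = (-9 * u**2 + 6 * u + 3) / 6.0
        w[..., 3] = u**2 / 2.0
    elif order == 2:
        w[..., 0] = 1 - u
        w[..., 1] = 3 * u - 2
        w[..., 2] = 1 - 3 * u
        w[..., 3] = u
    else:  # pragma: no cover
        raise ConfigurationError("basis derivative order must be 0, 1 or 2")
    return w


# ---------------------------------------------------------------------------
# Transform classes
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform3D:
    """x -> center + R (x - center) + translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        self.center = np.asarray(self.center, float)
        if (not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                            atol=1e-6)
                or not np.isclose(np.linalg.det(self.rotation), 1.0,
                                  atol=1e-6)):
            raise ConfigurationError("rotation must be proper orthonormal")

    @staticmethod
    def from_euler_zyx(angles_rad, translation=(0, 0, 0), center=(0, 0, 0)):
        """R = Rz(c) @ Ry(b) @ Rx(a) for angles (a, b, c) in radians."""
        a, b, c = [float(v) for v in angles_rad]
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return RigidTransform3D(rz @ ry @ rx, np.asarray(translation, float),
                                np.asarray(center, float))

    def apply(self, points):
        p = np.asarray(points, float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = self.center + (self.rotation @ (p - self.center).T).T \
            + self.translation
        return out[0] if single else out

    def spatial_jacobian(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        return np.broadcast_to(self.rotation, (len(p), 3, 3)).copy()

    def second_derivatives(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        return np.zeros((len(p), 3, 3, 3))

    def inverse(self) -> "RigidTransform3D":
        rt = self.rotation.T
        return RigidTransform3D(rt, -rt @ self.translation, self.center)

    def to_dict(self):
        return {"type": "rigid",
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "center": self.center.tolist()}


class IdentityTransform:
    """Trivial transform; useful as an initialization placeholder."""

    def apply(self, points):
        return np.asarray(points, float).copy()

    def spatial_jacobian(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        return np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy()

    def second_derivatives(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        return np.zeros((len(p), 3, 3, 3))

    def to_dict(self):
        return {"type": "identity"}


@dataclass
class BSplineFFD:
    """Cubic B-spline free-form deformation T(x) = x + u(x).

    ``coefficients`` has shape ``grid_shape + (3,)`` and holds per-control-
    point displacement vectors (the parameter vector mu). A point is *fully
    supported* when its complete 4x4x4 control neighbourhood exists; by
    default evaluation outside that interior raises ``DomainError``
    (``extrapolate="zero"`` returns zero displacement instead, used when
    resampling whole volumes whose corners exceed the grid).
    """

    control_spacing: np.ndarray
    grid_origin: np.ndarray
    coefficients: np.ndarray
    extrapolate: str = "error"

    def __post_init__(self):
        self.control_spacing = np.asarray(self.control_spacing, float)
        self.grid_origin = np.asarray(self.grid_origin, float)
        self.coefficients = np.asarray(self.coefficients, float)
        if np.any(self.control_spacing <= 0):
            raise ConfigurationError("control_spacing must be positive")
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ConfigurationError(
                "coefficients must have shape grid_shape + (3,)")
        if any(s < 4 for s in self.coefficients.shape[:3]):
            raise ConfigurationError("grid needs >= 4 control points per axis")
        if self.extrapolate not in ("error", "zero"):
            raise ConfigurationError("extrapolate must be 'error' or 'zero'")

    # -- construction ------------------------------------------------------

    @staticmethod
    def for_domain(lo_mm, hi_mm, spacing_mm, extrapolate="error"):
        """Zero FFD whose fully-supported interior covers [lo, hi] with at
        least one control spacing of margin on every side."""
        lo = np.asarray(lo_mm, float)
        hi = np.asarray(hi_mm, float)
        h = np.broadcast_to(np.asarray(spacing_mm, float), (3,)).astype(float)
        origin = lo - 2.0 * h
        n = np.ceil((hi - lo) / h).astype(int) + 5
        coeffs = np.zeros(tuple(n) + (3,))
        return BSplineFFD(h, origin, coeffs, extrapolate)

    @property
    def grid_shape(self):
        return self.coefficients.shape[:3]

    @property
    def n_parameters(self):
        return self.coefficients.size

    def control_points(self):
        """World coordinates of all control points, shape grid_shape + (3,)."""
        ax = [self.grid_origin[d] + self.control_spacing[d]
              * np.arange(self.grid_shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def supported_bounds(self):
        """(lo, hi) of the fully-supported interior in world mm."""
        n = np.asarray(self.grid_shape, float)
        lo = self.grid_origin + self.control_spacing
        hi = self.grid_origin + (n - 2.0) * self.control_spacing
        return lo, hi

    # -- support bookkeeping ----------------------------------------------

    def _support(self, points):
        """Start control index, local coordinate and support mask per point."""
        p = np.atleast_2d(np.asarray(points, float))
        s = (p - self.grid_origin) / self.control_spacing
        i = np.floor(s).astype(int)
        u = s - i
        n = np.asarray(self.grid_shape)
        ok = np.all((i >= 1) & (i <= n - 3), axis=1)
        return i - 1, u, ok

    def _tensor_weights(self, u, orders):
        """(n, 4, 4, 4) tensor-product weights for derivative ``orders``,
        scaled to world-mm derivatives."""
        wx = bspline3_weights(u[:, 0], orders[0])
        wy = bspline3_weights(u[:, 1], orders[1])
        wz = bspline3_weights(u[:, 2], orders[2])
        w = wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
        scale = np.prod(self.control_spacing ** -np.asarray(orders, float))
        return w * scale

    def _gather(self, i0):
        """Coefficient vectors of the 4x4x4 support, shape (n, 4, 4, 4, 3).

        ``i0`` must already be clipped to valid range by the caller for
        unsupported points (their weights are zeroed)."""
        off = np.arange(4)
        ix = np.clip(i0[:, 0, None] + off, 0, self.grid_shape[0] - 1)
        iy = np.clip(i0[:, 1, None] + off, 0, self.grid_shape[1] - 1)
        iz = np.clip(i0[:, 2, None] + off, 0, self.grid_shape[2] - 1)
        return self.coefficients[ix[:, :, None, None],
                                 iy[:, None, :, None],
                                 iz[:, None, None, :]]

    def _check_support(self, ok):
        if not np.all(ok) and self.extrapolate == "error":
            raise DomainError(
                f"{int((~ok).sum())} point(s) outside the fully-supported "
                "FFD interior")

    # -- evaluation --------------------------------------------------------

    def displacement(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        i0, u, ok = self._support(p)
        self._check_support(ok)
        w = self._tensor_weights(u, (0, 0, 0))
        w[~ok] = 0.0
        c = self._gather(i0)
        return np.einsum("nijk,nijkd->nd", w, c)

    def apply(self, points):
        p = np.asarray(points, float)
        single = p.ndim == 1
        out = np.atleast_2d(p) + self.displacement(p)
        return out[0] if single else out

    def spatial_jacobian(self, points):
        """J[n, k, d] = dT_k/dx_d = I + du_k/dx_d (analytic)."""
        p = np.atleast_2d(np.asarray(points, float))
        i0, u, ok = self._support(p)
        self._check_support(ok)
        c = self._gather(i0)
        jac = np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy()
        for d in range(3):
            orders = [0, 0, 0]
            orders[d] = 1
            w = self._tensor_weights(u, orders)
            w[~ok] = 0.0
            jac[:, :, d] += np.einsum("nijk,nijkd->nd", w, c)
        return jac

    def second_derivatives(self, points):
        """H[n, k, i, j] = d2 T_k / dx_i dx_j (symmetric in i, j)."""
        p = np.atleast_2d(np.asarray(points, float))
        i0, u, ok = self._support(p)
        self._check_support(ok)
        c = self._gather(i0)
        hess = np.zeros((len(p), 3, 3, 3))
        for i in range(3):
            for j in range(i, 3):
                orders = [0, 0, 0]
                orders[i] += 1
                orders[j] += 1
                w = self._tensor_weights(u, tuple(orders))
                w[~ok] = 0.0
                hij = np.einsum("nijk,nijkd->nd", w, c)
                hess[:, :, i, j] = hij
                hess[:, :, j, i] = hij
        return hess

    def to_dict(self):
        return {"type": "bspline_ffd",
                "control_spacing": self.control_spacing.tolist(),
                "grid_origin": self.grid_origin.tolist(),
                "grid_shape": list(self.grid_shape),
                "coefficients": self.coefficients.ravel().tolist(),
                "extrapolate": self.extrapolate}


@dataclass
class CompositeTransform:
    """Ordered composition; ``apply`` runs components right-to-left
    (the last listed component is applied first)."""

    components: list

    def __post_init__(self):
        if not self.components:
            raise ConfigurationError("composite needs >= 1 component")

    def apply(self, points):
        p = np.asarray(points, float)
        for t in reversed(self.components):
            p = t.apply(p)
        return p

    def spatial_jacobian(self, points):
        """Chain-rule Jacobian of the composition."""
        p = np.atleast_2d(np.asarray(points, float))
        jac = np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy()
        for t in reversed(self.components):
            jt = t.spatial_jacobian(p)
            jac = np.einsum("nij,njk->nik", jt, jac)
            p = t.apply(p)
        return jac

    def second_derivatives(self, points):
        """Chain-rule second derivatives of the composition:
        for T = A o B,  H[k,i,j] = HA[k,a,b] JB[a,i] JB[b,j]
                                   + JA[k,a] HB[a,i,j]."""
        p = np.atleast_2d(np.asarray(points, float))
        jac = np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy()
        hess = np.zeros((len(p), 3, 3, 3))
        for t in reversed(self.components):
            ja = t.spatial_jacobian(p)
            ha = t.second_derivatives(p)
            hess = (np.einsum("nkab,nai,nbj->nkij", ha, jac, jac)
                    + np.einsum("nka,naij->nkij", ja, hess))
            p = t.apply(p)
        return hess

    def to_dict(self):
        return {"type": "composite",
                "components": [t.to_dict() for t in self.components]}

    def innermost(self):
        return self.components[-1]


# ---------------------------------------------------------------------------
# FFD utilities
# ---------------------------------------------------------------------------

def embed_affine(ffd_like, A, t):
    """FFD reproducing the affine map x -> A x + t on its interior.

    Cubic B-splines have linear precision: setting each coefficient to
    ``(A - I) x_c + t`` at its control point ``x_c`` makes ``x + u(x)``
    equal the affine map exactly wherever support is complete.
    """
    A = np.asarray(A, float)
    t = np.asarray(t, float)
    cp = ffd_like.control_points()
    coeffs = (cp.reshape(-1, 3) @ (A - np.eye(3)).T + t).reshape(cp.shape)
    return BSplineFFD(ffd_like.control_spacing.copy(),
                      ffd_like.grid_origin.copy(), coeffs,
                      ffd_like.extrapolate)


def _subdivide_axis(c, axis):
    """Exact dyadic refinement of cubic B-spline coefficients along ``axis``:
    n nodes at spacing h -> 2n-1 nodes at spacing h/2, same displacement
    field. Boundary neighbours are linearly extrapolated."""
    c = np.moveaxis(c, axis, 0)
    n = c.shape[0]
    pad_lo = (2 * c[0] - c[1])[None]
    pad_hi = (2 * c[-1] - c[-2])[None]
    cp = np.concatenate([pad_lo, c, pad_hi], axis=0)  # indices -1..n
    even = (cp[:-2] + 6 * cp[1:-1] + cp[2:]) / 8.0    # new index 2i, i=0..n-1
    odd = (cp[1:-1][:-1] + cp[1:-1][1:]) / 2.0        # new index 2i+1
    out = np.empty((2 * n - 1,) + c.shape[1:])
    out[0::2] = even
    out[1::2] = odd
    return np.moveaxis(out, 0, axis)


def refine_grid(ffd: BSplineFFD, new_spacing) -> BSplineFFD:
    """Re-express ``ffd`` on a finer control grid (same displacement field).

    Halving the spacing uses the exact cubic B-spline subdivision mask; any
    other (componentwise smaller) spacing samples the displacement field at
    the new nodes and prefilters for interpolating coefficients.
    """
    h_old = ffd.control_spacing
    h_new = np.broadcast_to(np.asarray(new_spacing, float), (3,)).astype(float)
    if np.any(h_new > h_old + 1e-9):
        raise ConfigurationError("new spacing must be <= current spacing")
    if np.allclose(h_new, h_old):
        return BSplineFFD(h_old.copy(), ffd.grid_origin.copy(),
                          ffd.coefficients.copy(), ffd.extrapolate)
    if np.allclose(h_new * 2.0, h_old):
        c = ffd.coefficients
        for ax in range(3):
            c = _subdivide_axis(c, ax)
        return BSplineFFD(h_new, ffd.grid_origin.copy(), c, ffd.extrapolate)
    # general path: sample u at the new nodes, prefilter to interpolate
    lo, hi = ffd.supported_bounds()
    new = BSplineFFD.for_domain(lo + h_new, hi - h_new, h_new,
                                ffd.extrapolate)
    nodes = new.control_points().reshape(-1, 3)
    inner = BSplineFFD(h_old, ffd.grid_origin, ffd.coefficients, "zero")
    u = inner.displacement(nodes).reshape(new.grid_shape + (3,))
    coeffs = np.stack(
        [ndimage.spline_filter(u[..., d], order=3, mode="mirror")
         for d in range(3)], axis=-1)
    new.coefficients = coeffs
    return new


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def transform_to_dict(transform):
    """JSON-ready dict (with format version) for any supported transform."""
    return {"format_version": FORMAT_VERSION, "transform": transform.to_dict()}


def _from_node(node):
    kind = node.get("type")
    if kind == "rigid":
        return RigidTransform3D(np.array(node["rotation"]),
                                np.array(node["translation"]),
                                np.array(node["center"]))
    if kind == "bspline_ffd":
        shape = tuple(node["grid_shape"])
        coeffs = np.array(node["coefficients"]).reshape(shape + (3,))
        return BSplineFFD(np.array(node["control_spacing"]),
                          np.array(node["grid_origin"]), coeffs,
                          node.get("extrapolate", "error"))
    if kind == "composite":
        return CompositeTransform([_from_node(c) for c in node["components"]])
    if kind == "identity":
        return IdentityTransform()
    raise ConfigurationError(f"unknown transform type {kind!r}")


def transform_from_dict(doc):
    if doc.get("format_version") != FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported transform file version {doc.get('format_version')!r}")
    return _from_node(doc["transform"])
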