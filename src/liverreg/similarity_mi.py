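"""Binned mutual information with masked stochastic sampling and gradient.

The similarity metric is the mutual information of the joint intensity
histogram of the fixed image and the transformed moving image,

    MI = sum_f sum_m p(f, m) log[ p(f, m) / (p_F(f) p_M(m)) ]

in natural-log units, estimated from a small random sample of points drawn
uniformly inside the fixed-image mask (a fresh set every iteration of the
optimizer). The fixed intensity is binned with a zero-order (box) window;
the moving intensity with a cubic B-spline Parzen window, which makes the
histogram — and hence MI — differentiable with respect to the B-spline
deformation parameters. Moving-image intensities are interpolated with a
cubic B-spline so the analytic gradient differentiates exactly the
interpolant the metric evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import (ConfigurationError, ContractViolationError,
                          EmptyInputError, GrossMisalignmentError)
from .image_core import BinaryMask, Image3D, sample_image
from .transforms import (BSplineFFD, CompositeTransform, bspline3_weights)

#: fraction of samples allowed to map outside the moving image
MAX_DROP_FRACTION = 0.5

#: padding (in bins) keeping the full Parzen support inside the histogram
_PAD = 1.0


@dataclass
class SampleSet:
    """Fixed-image world points used for one stochastic metric evaluation."""

    points: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))

    def __len__(self):
        return len(self.points)


@dataclass
class JointHistogram:
    """Normalized joint intensity histogram (fixed rows, moving columns)."""

    probabilities: np.ndarray
    fixed_edges: np.ndarray
    moving_edges: np.ndarray
    n_samples_used: int = 0
    n_samples_dropped: int = 0

    @property
    def bins_fixed(self):
        return self.probabilities.shape[0]

    @property
    def bins_moving(self):
        return self.probabilities.shape[1]

    @property
    def marginal_fixed(self):
        return self.probabilities.sum(axis=1)

    @property
    def marginal_moving(self):
        return self.probabilities.sum(axis=0)


def draw_samples(mask: BinaryMask, n: int, rng_seed) -> SampleSet:
    """Draw ``n`` points uniformly from the region covered by mask voxels.

    A voxel is chosen uniformly among the nonzero ones, then a uniform
    offset within the voxel extent is added, giving a uniform draw from the
    continuous union of voxel boxes. ``rng_seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 samples")
    idx = np.argwhere(np.asarray(mask.voxels) != 0)
    if idx.size == 0:
        raise EmptyInputError("cannot sample from an empty mask")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    pick = rng.integers(0, len(idx), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    pts = mask.geometry.world_from_index(idx[pick] + jitter)
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return SampleSet(pts, seed)


# ---------------------------------------------------------------------------
# Cubic-spline image interpolation with analytic gradient
# ---------------------------------------------------------------------------

class SplineImage:
    """Cubic B-spline interpolant of an Image3D with analytic gradient.

    Coefficients are prefiltered once (mirror boundary); evaluation reuses
    the FFD basis code on the voxel lattice with the same mirror boundary,
    so the spline interpolates the voxel values exactly everywhere,
    including the border.
    """

    def __init__(self, image: Image3D):
        self.image = image
        self.coeffs = ndimage.spline_filter(
            np.asarray(image.voxels, float), order=3, mode="mirror")
        self.shape = np.asarray(image.shape)

    def _support(self, points_mm):
        idx = self.image.index_from_world(np.atleast_2d(points_mm))
        # cubic interpolation around continuous index s uses floor(s)-1..+2
        i = np.floor(idx).astype(int)
        u = idx - i
        return i - 1, u, idx

    def inside(self, points_mm, margin=0.0):
        idx = self.image.index_from_world(np.atleast_2d(points_mm))
        return np.all((idx >= margin) & (idx <= self.shape - 1 - margin),
                      axis=1)

    @staticmethod
    def _mirror(idx, n):
        # reflect about the first/last sample, as scipy's "mirror" mode does
        idx = np.abs(idx)
        return np.where(idx > n - 1, 2 * (n - 1) - idx, idx)

    def _gather(self, i0):
        off = np.arange(4)
        ix = self._mirror(i0[:, 0, None] + off, self.shape[0])
        iy = self._mirror(i0[:, 1, None] + off, self.shape[1])
        iz = self._mirror(i0[:, 2, None] + off, self.shape[2])
        return self.coeffs[ix[:, :, None, None],
                           iy[:, None, :, None],
                           iz[:, None, None, :]]

    def values(self, points_mm):
        i0, u, _ = self._support(points_mm)
        c = self._gather(i0)
        w = (bspline3_weights(u[:, 0])[:, :, None, None]
             * bspline3_weights(u[:, 1])[:, None, :, None]
             * bspline3_weights(u[:, 2])[:, None, None, :])
        return np.einsum("nijk,nijk->n", w, c)

    def values_and_gradient(self, points_mm):
        """Intensity and world-mm gradient of the interpolant."""
        i0, u, _ = self._support(points_mm)
        c = self._gather(i0)
        w0 = [bspline3_weights(u[:, d], 0) for d in range(3)]
        w1 = [bspline3_weights(u[:, d], 1) for d in range(3)]
        val = np.einsum(
            "nijk,nijk->n",
            w0[0][:, :, None, None] * w0[1][:, None, :, None]
            * w0[2][:, None, None, :], c)
        grad_idx = np.empty((len(c), 3))
        for d in range(3):
            ws = [w1[a] if a == d else w0[a] for a in range(3)]
            grad_idx[:, d] = np.einsum(
                "nijk,nijk->n",
                ws[0][:, :, None, None] * ws[1][:, None, :, None]
                * ws[2][:, None, None, :], c)
        # d(index)/d(world) = diag(1/spacing) @ direction^T
        grad_world = (self.image.direction
                      @ (grad_idx / self.image.spacing).T).T
        return val, grad_world


# ---------------------------------------------------------------------------
# Histogram assembly
# ---------------------------------------------------------------------------

def intensity_range(image: Image3D, mask: BinaryMask | None = None):
    """(min, max) intensity, optionally restricted to a mask."""
    v = np.asarray(image.voxels, float)
    if mask is not None:
        v = v[np.asarray(mask.voxels) != 0]
    if v.size == 0:
        raise EmptyInputError("empty region for intensity range")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _split_transform(T):
    """(outer transforms, innermost FFD or None) for gradient chaining."""
    if isinstance(T, CompositeTransform):
        inner = T.components[-1]
        if isinstance(inner, BSplineFFD):
            return T.components[:-1], inner
        return T.components, None
    if isinstance(T, BSplineFFD):
        return [], T
    return ([T] if T is not None else []), None


def _moving_bin_coords(values, lo, hi, bins):
    """Continuous Parzen bin coordinate in [PAD, bins-2-PAD]; returns the
    coordinate and a mask of values clamped at the range ends (zero
    derivative there)."""
    scale = (bins - 2.0 - 2 * _PAD) / (hi - lo)
    b = _PAD + (np.asarray(values, float) - lo) * scale
    lo_b, hi_b = _PAD, bins - 2.0 - _PAD
    clamped = (b < lo_b) | (b > hi_b)
    return np.clip(b, lo_b, hi_b), clamped, scale


def _fixed_bins(values, lo, hi, bins):
    f = np.floor((np.asarray(values, float) - lo) / (hi - lo) * bins)
    return np.clip(f, 0, bins - 1).astype(int)


def _parzen_contributions(b):
    """Bin indices (n, 4) and cubic Parzen weights/derivatives (n, 4) for
    continuous bin coordinate ``b``; weights per integer bin m are
    beta3(b - m) with support |b - m| < 2."""
    i = np.floor(b).astype(int)
    u = b - i
    w = bspline3_weights(u)          # weights for bins i-1 .. i+2
    dw = bspline3_weights(u, 1)
    m = i[:, None] + np.arange(-1, 3)[None, :]
    return m, w, dw


def joint_histogram(I_F: Image3D, I_M, T, samples: SampleSet, bins: int = 32,
                    fixed_range=None, moving_range=None, window="parzen"):
    """Joint histogram of (I_F(x), I_M(T(x))) over the sample points.

    ``I_M`` may be an ``Image3D`` or a prebuilt ``SplineImage``. Samples
    whose transformed point falls outside the moving volume are dropped;
    more than ``MAX_DROP_FRACTION`` dropped raises
    ``GrossMisalignmentError``. ``window="nearest"`` bins both intensities
    with box windows (used by brute-force oracles); the default "parzen"
    uses a cubic B-spline window on the moving intensity.
    """
    if bins < 2:
        raise ConfigurationError("need bins >= 2")
    if window not in ("parzen", "nearest"):
        raise ConfigurationError(f"unknown window {window!r}")
    spl = I_M if isinstance(I_M, SplineImage) else SplineImage(I_M)

    pts = samples.points
    f_vals = sample_image(I_F, pts, "linear")
    tp = T.apply(pts) if T is not None else pts
    keep = spl.inside(tp)
    n_total = len(pts)
    n_drop = int((~keep).sum())
    if n_drop > MAX_DROP_FRACTION * n_total:
        raise GrossMisalignmentError(
            f"{n_drop}/{n_total} samples map outside the moving image")
    f_vals = f_vals[keep]
    m_vals = spl.values(tp[keep])

    flo, fhi = fixed_range if fixed_range is not None \
        else intensity_range(I_F)
    mlo, mhi = moving_range if moving_range is not None \
        else intensity_range(spl.image)

    fbin = _fixed_bins(f_vals, flo, fhi, bins)
    counts = np.zeros((bins, bins))
    if window == "nearest":
        mbin = _fixed_bins(m_vals, mlo, mhi, bins)
        np.add.at(counts, (fbin, mbin), 1.0)
    else:
        b, _, _ = _moving_bin_coords(m_vals, mlo, mhi, bins)
        m_idx, w, _ = _parzen_contributions(b)
        np.add.at(counts, (np.repeat(fbin, 4), m_idx.ravel()), w.ravel())
    n_used = len(f_vals)
    probs = counts / counts.sum()
    f_edges = np.linspace(flo, fhi, bins + 1)
    m_edges = np.linspace(mlo, mhi, bins + 1)
    return JointHistogram(probs, f_edges, m_edges, n_used, n_drop)


def mutual_information(h: JointHistogram) -> float:
    """MI in natural-log units; 0 log 0 is taken as 0."""
    p = np.asarray(h.probabilities, float)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ContractViolationError(
            f"histogram not normalized (sum = {total})")
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (pf * pm), 1.0)
        terms = np.where(p > 0, p * np.log(ratio), 0.0)
    return float(terms.sum())


def mi_gradient(I_F: Image3D, I_M, T, samples: SampleSet, bins: int = 32,
                fixed_range=None, moving_range=None):
    """(MI, gradient of -MI with respect to the FFD coefficients).

    ``T`` must be a ``BSplineFFD`` or a ``CompositeTransform`` whose
    innermost (first-applied) component is the FFD being optimized; any
    outer components are treated as fixed. Only control points whose
    support contains at least one sample receive nonzero entries.
    """
    outer, ffd = _split_transform(T)
    if ffd is None:
        raise ConfigurationError("mi_gradient needs an innermost BSplineFFD")
    spl = I_M if isinstance(I_M, SplineImage) else SplineImage(I_M)

    pts = samples.points
    f_vals = sample_image(I_F, pts, "linear")

    i0, u, ok = ffd._support(pts)
    w_ffd = ffd._tensor_weights(u, (0, 0, 0))
    w_ffd[~ok] = 0.0
    disp = np.einsum("nijk,nijkd->nd", w_ffd, ffd._gather(i0))
    mid = pts + disp
    # outer components applied after the FFD; their Jacobian is constant
    # (rigid) or evaluated at the FFD output
    tp = mid
    jac_outer = np.broadcast_to(np.eye(3), (len(pts), 3, 3)).copy()
    for t in reversed(outer):
        jac_outer = np.einsum("nij,njk->nik", t.spatial_jacobian(tp),
                              jac_outer)
        tp = t.apply(tp)

    keep = spl.inside(tp)
    n_total = len(pts)
    n_drop = int((~keep).sum())
    if n_drop > MAX_DROP_FRACTION * n_total:
        raise GrossMisalignmentError(
            f"{n_drop}/{n_total} samples map outside the moving image")

    flo, fhi = fixed_range if fixed_range is not None \
        else intensity_range(I_F)
    mlo, mhi = moving_range if moving_range is not None \
        else intensity_range(spl.image)

    f_vals = f_vals[keep]
    m_vals, m_grad = spl.values_and_gradient(tp[keep])
    fbin = _fixed_bins(f_vals, flo, fhi, bins)
    b, clamped, scale = _moving_bin_coords(m_vals, mlo, mhi, bins)
    m_idx, w, dw = _parzen_contributions(b)

    counts = np.zeros((bins, bins))
    np.add.at(counts, (np.repeat(fbin, 4), m_idx.ravel()), w.ravel())
    n_used = len(f_vals)
    p = counts / counts.sum()
    hist = JointHistogram(p, np.linspace(flo, fhi, bins + 1),
                          np.linspace(mlo, mhi, bins + 1), n_used, n_drop)
    mi = mutual_information(hist)

    # dMI = sum_{f,m} dp(f,m) log(p/p_M); p_F is constant (box window).
    pm = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(p > 0, np.log(np.where(p > 0, p, 1.0))
                           - np.log(np.where(pm > 0, pm, 1.0))[None, :], 0.0)
    # per-sample dMI/db_s
    l_sm = logterm[np.repeat(fbin, 4), m_idx.ravel()].reshape(dw.shape)
    alpha = (l_sm * dw).sum(axis=1) / counts.sum()
    alpha[clamped] = 0.0
    # db/dmu_{c,d} = scale * (gradI . J_outer e_d) * B_c(x)
    g_eff = np.einsum("ni,nij->nj", m_grad, jac_outer[keep]) * scale

    grad = np.zeros_like(ffd.coefficients)
    kpts = np.flatnonzero(keep)
    i0k = i0[kpts]
    wk = w_ffd[kpts]                              # (nk, 4, 4, 4)
    contrib = alpha[:, None] * g_eff              # (nk, 3)
    off = np.arange(4)
    ix = np.clip(i0k[:, 0, None] + off, 0, ffd.grid_shape[0] - 1)
    iy = np.clip(i0k[:, 1, None] + off, 0, ffd.grid_shape[1] - 1)
    iz = np.clip(i0k[:, 2, None] + off, 0, ffd.grid_shape[2] - 1)
    gi = np.broadcast_to(ix[:, :, None, None], wk.shape)
    gj = np.broadcast_to(iy[:, None, :, None], wk.shape)
    gk = np.broadcast_to(iz[:, None, None, :], wk.shape)
    full = wk[..., None] * contrib[:, None, None, None, :]  # (nk,4,4,4,3)
    np.add.at(grad, (gi.ravel(), gj.ravel(), gk.ravel()),
              full.reshape(-1, 3))
    # gradient of -MI
    return mi, -grad
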