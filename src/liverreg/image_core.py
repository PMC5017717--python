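"""Geometry-aware 3D image container, resampling and multiresolution pyramids.

Conventions used throughout the package:

* voxel indices are 0-based and denote voxel *centers*;
* arrays are indexed ``voxels[i, j, k]`` along the (x, y, z) world axes,
  matching the order of the ``spacing``/``origin`` vectors;
* all spatial quantities are in world millimetres:
  ``world = origin + direction @ (spacing * index)``;
* spatial transforms map fixed-image world coordinates to moving-image
  world coordinates (the resampling convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, EmptyInputError

_ORTHO_TOL = 1e-6

_INTERP_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}

#: Hounsfield value used for points mapping outside the source image (air).
AIR_HU = -1000.0


@dataclass(frozen=True)
class ImageGeometry:
    """Shape + spacing + origin + direction of a voxel lattice (no voxels)."""

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, float).copy())
        object.__setattr__(self, "origin", np.asarray(self.origin, float).copy())
        object.__setattr__(self, "direction", np.asarray(self.direction, float).copy())
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ConfigurationError("geometry needs three dimensions, each >= 1")
        if np.any(self.spacing <= 0):
            raise ConfigurationError("spacing components must be positive")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3),
                           atol=_ORTHO_TOL):
            raise ConfigurationError("direction matrix is not orthonormal")

    # -- coordinate mapping ------------------------------------------------

    def world_from_index(self, index):
        """World coordinates (mm) of voxel center(s) at ``index``.

        ``index`` may be a single 3-vector or an (n, 3) array; it may be
        fractional (continuous index space).
        """
        idx = np.asarray(index, float)
        return self.origin + (self.direction @ (self.spacing * idx).T).T

    def index_from_world(self, point):
        """Continuous voxel index of world point(s) ``point``."""
        p = np.asarray(point, float)
        return (self.direction.T @ (p - self.origin).T).T / self.spacing

    def world_bounds(self):
        """(lo, hi) world-mm bounding box of all voxel centers."""
        n = np.asarray(self.shape, float) - 1.0
        corners = np.array([[i * n[0], j * n[1], k * n[2]]
                            for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        w = self.world_from_index(corners)
        return w.min(axis=0), w.max(axis=0)

    def same_as(self, other, tol=1e-6):
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.direction, other.direction, atol=tol))


@dataclass
class Image3D:
    """3D scalar volume (Hounsfield-like units) with world geometry."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError("voxels must be a 3D array")
        # geometry validation happens in the ImageGeometry constructor
        self.spacing = np.asarray(self.spacing, float).copy()
        self.origin = np.asarray(self.origin, float).copy()
        self.direction = np.asarray(self.direction, float).copy()
        _ = self.geometry

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(self.voxels.shape, self.spacing, self.origin,
                             self.direction)

    @property
    def shape(self):
        return self.voxels.shape

    def world_from_index(self, index):
        return self.geometry.world_from_index(index)

    def index_from_world(self, point):
        return self.geometry.index_from_world(point)

    def with_voxels(self, voxels) -> "Image3D":
        """Copy of this image's geometry carrying different voxel data."""
        return type(self)(np.asarray(voxels), self.spacing.copy(),
                          self.origin.copy(), self.direction.copy())


class BinaryMask(Image3D):
    """Binary segmentation/region-of-interest sharing Image3D geometry."""

    def __post_init__(self):
        super().__post_init__()
        v = np.asarray(self.voxels)
        if not np.isin(np.unique(v), (0, 1)).all():
            raise ConfigurationError("mask voxels must be 0 or 1")
        self.voxels = v.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class PointSetMM:
    """Ordered list of world-mm points; index pairs corresponding landmarks."""

    points: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.size and (self.points.shape[1] != 3
                                 or not np.isfinite(self.points).all()):
            raise ConfigurationError("points must be finite (n, 3) coordinates")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ConfigurationError("one label per point required")

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def world_from_index(meta, index):
    """World mm of voxel center ``index`` (integer 3-vector, bounds-checked)."""
    geom = meta.geometry if isinstance(meta, Image3D) else meta
    idx = np.asarray(index)
    if np.any(idx < 0) or np.any(idx > np.asarray(geom.shape) - 1):
        raise IndexError(f"index {index!r} outside array bounds {geom.shape}")
    return geom.world_from_index(idx)


def index_from_world(meta, point):
    geom = meta.geometry if isinstance(meta, Image3D) else meta
    return geom.index_from_world(point)


def sample_image(image: Image3D, points_mm, interpolation="linear",
                 default_value=AIR_HU):
    """Interpolate ``image`` at world points (n, 3); outside -> default."""
    if interpolation not in _INTERP_ORDERS:
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")
    idx = image.index_from_world(np.atleast_2d(points_mm))
    return ndimage.map_coordinates(
        np.asarray(image.voxels, float), idx.T,
        order=_INTERP_ORDERS[interpolation], mode="constant",
        cval=float(default_value))


def resample(image: Image3D, transform, target, interpolation="linear",
             default_value=AIR_HU):
    """Pull ``image`` back through ``transform`` onto ``target``'s lattice.

    ``output(x) = image(T(x))`` for every target voxel center x;
    points mapping outside the source domain receive ``default_value``.
    """
    if interpolation not in _INTERP_ORDERS:
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")
    geom = target.geometry if isinstance(target, Image3D) else target
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in geom.shape),
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = geom.world_from_index(idx)
    if transform is not None:
        pts = transform.apply(pts)
    vals = sample_image(image, pts, interpolation, default_value)
    out = vals.reshape(geom.shape)
    if interpolation == "nearest":
        out = out.astype(image.voxels.dtype)
    cls = type(image) if isinstance(image, BinaryMask) else Image3D
    return cls(out, geom.spacing.copy(), geom.origin.copy(),
               geom.direction.copy())


def _clamped_factors(shape, factor, min_size=4):
    """Per-axis downsampling factors; no axis shrinks below ``min_size``."""
    out = []
    for s in shape:
        f = int(factor)
        while f > 1 and s // f < min_size and s > min_size:
            f //= 2
        if s <= min_size:
            f = 1
        out.append(max(f, 1))
    return out


def gaussian_pyramid(image: Image3D, n_levels: int, downsample_factors):
    """Gaussian multiresolution pyramid, coarsest first.

    Level k is the image smoothed with sigma = factor/2 voxels (no smoothing
    for factor 1) and decimated by the factor; spacing is scaled so world
    coordinates of retained voxel centers are preserved. Factors are clamped
    per axis so no axis drops below 4 voxels (thin-slab support).
    """
    if n_levels < 1:
        raise ConfigurationError("n_levels must be >= 1")
    factors = list(downsample_factors)
    if len(factors) != n_levels:
        raise ConfigurationError("one downsample factor per level required")
    if any(f < 1 for f in factors):
        raise ConfigurationError("downsample factors must be >= 1")
    if any(factors[i] < factors[i + 1] for i in range(n_levels - 1)):
        raise ConfigurationError("factors must be monotone non-increasing")

    levels = []
    data = np.asarray(image.voxels, float)
    for f in factors:
        fx = _clamped_factors(data.shape, f)
        if all(a == 1 for a in fx):
            levels.append(image.with_voxels(data.copy()))
            continue
        sigma = [a / 2.0 if a > 1 else 0.0 for a in fx]
        sm = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
        dec = sm[::fx[0], ::fx[1], ::fx[2]]
        levels.append(Image3D(dec, image.spacing * fx, image.origin.copy(),
                              image.direction.copy()))
    return levels


def center_of_mass(mask: BinaryMask):
    """Unweighted mean world coordinate (mm) of the mask's nonzero voxels."""
    idx = np.argwhere(np.asarray(mask.voxels) != 0)
    if idx.size == 0:
        raise EmptyInputError("center_of_mass of an empty mask")
    return mask.geometry.world_from_index(idx).mean(axis=0)
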