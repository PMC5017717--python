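"""Shared fixtures and independent brute-force oracles for the test suite."""

import numpy as np
import pytest

from liverreg.image_core import BinaryMask, Image3D, ImageGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_image(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0),
               origin=(0.0, 0.0, 0.0), seed=0, lo=0.0, hi=100.0):
    r = np.random.default_rng(seed)
    vox = r.uniform(lo, hi, size=shape)
    return Image3D(vox, spacing, origin, np.eye(3))


def make_mask(shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0),
              origin=(0.0, 0.0, 0.0), seed=0, p=0.3):
    r = np.random.default_rng(seed)
    vox = (r.uniform(size=shape) < p).astype(np.uint8)
    if vox.sum() == 0:
        vox[tuple(s // 2 for s in shape)] = 1
    return BinaryMask(vox, spacing, origin, np.eye(3))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately slow and simple)
# ---------------------------------------------------------------------------

def trilinear_oracle(image, point_mm, default=-1000.0):
    """Brute-force trilinear interpolation at one world point."""
    idx = image.index_from_world(np.asarray(point_mm, float))
    i0 = np.floor(idx).astype(int)
    f = idx - i0
    val = 0.0
    shape = np.asarray(image.shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0])
                     * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                c = i0 + (dx, dy, dz)
                if np.any(c < 0) or np.any(c > shape - 1):
                    v = default
                else:
                    v = float(image.voxels[tuple(c)])
                val += w * v
    return val


def dice_oracle(X, Y):
    x = np.asarray(X.voxels, bool).ravel()
    y = np.asarray(Y.voxels, bool).ravel()
    inter = sum(1 for a, b in zip(x, y) if a and b)
    return 2.0 * inter / (x.sum() + y.sum())


def surface_voxels_oracle(mask):
    """6-connected surface: voxel in mask with any 6-neighbour outside."""
    m = np.asarray(mask.voxels, bool)
    out = []
    for idx in np.argwhere(m):
        i, j, k = idx
        boundary = False
        for d, s in ((0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)):
            n = idx.copy()
            n[d] += s
            if np.any(n < 0) or np.any(n >= m.shape) or not m[tuple(n)]:
                boundary = True
                break
        if boundary:
            out.append(idx)
    return np.asarray(out, int).reshape(-1, 3)


def msd_oracle(X, Y):
    """O(n^2) symmetric mean closest surface distance in world mm."""
    sx = surface_voxels_oracle(X)
    sy = surface_voxels_oracle(Y)
    px = X.geometry.world_from_index(sx)
    py = Y.geometry.world_from_index(sy)
    d_xy = np.sqrt(((px[:, None, :] - py[None, :, :]) ** 2).sum(-1))
    total = d_xy.min(axis=1).sum() + d_xy.min(axis=0).sum()
    return total / (len(px) + len(py))


def mi_oracle(p):
    """Direct double sum over the joint histogram."""
    p = np.asarray(p, float)
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log(p[i, j] / (pf[i] * pm[j]))
    return total


def random_geometry(seed=0):
    r = np.random.default_rng(seed)
    # random orthonormal direction via QR
    q, _ = np.linalg.qr(r.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return ImageGeometry(tuple(r.integers(4, 9, 3)), r.uniform(0.5, 4.0, 3),
                         r.uniform(-20, 20, 3), q)
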