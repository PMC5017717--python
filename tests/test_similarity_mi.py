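"""similarity_mi: sampling, joint histograms, MI and its gradient."""

import numpy as np
import pytest
from scipy import ndimage

from liverreg._exceptions import (ConfigurationError, ContractViolationError,
                                  EmptyInputError, GrossMisalignmentError)
from liverreg.image_core import BinaryMask, Image3D
from liverreg.similarity_mi import (JointHistogram, SampleSet, SplineImage,
                                    draw_samples, intensity_range,
                                    joint_histogram, mi_gradient,
                                    mutual_information)
from liverreg.transforms import BSplineFFD, CompositeTransform, \
    IdentityTransform, RigidTransform3D

from conftest import mi_oracle


def smooth_image(shape=(20, 20, 20), seed=0, spacing=(1.0, 1.0, 1.0)):
    r = np.random.default_rng(seed)
    vox = ndimage.gaussian_filter(r.normal(size=shape), 2.0) * 200.0
    return Image3D(vox, spacing, (0.0, 0.0, 0.0), np.eye(3))


def full_mask(image):
    return BinaryMask(np.ones(image.shape, np.uint8), image.spacing,
                      image.origin, image.direction)


def centers_sample_set(image, stride=1):
    idx = np.argwhere(np.ones(image.shape, bool))[::stride]
    return SampleSet(image.geometry.world_from_index(idx))


# ---------------------------------------------------------------------------
# draw_samples
# ---------------------------------------------------------------------------

def test_draw_samples_inside_mask_and_deterministic():
    vox = np.zeros((10, 10, 10), np.uint8)
    vox[2:5, 3:8, 1:9] = 1
    m = BinaryMask(vox, (2.0, 1.0, 1.5), (5.0, -3.0, 0.0), np.eye(3))
    s1 = draw_samples(m, 500, 42)
    s2 = draw_samples(m, 500, 42)
    assert np.array_equal(s1.points, s2.points)
    idx = np.rint(m.geometry.index_from_world(s1.points)).astype(int)
    assert np.all(vox[idx[:, 0], idx[:, 1], idx[:, 2]] == 1)


def test_draw_samples_two_blob_fractions():
    vox = np.zeros((20, 10, 10), np.uint8)
    vox[0:5, 0:5, 0:5] = 1            # blob A: 125 voxels
    vox[10:20, 0:5, 0:5] = 1          # blob B: 250 voxels
    m = BinaryMask(vox, (1.0, 1.0, 1.0), (0, 0, 0), np.eye(3))
    n = 6000
    s = draw_samples(m, n, 7)
    in_a = (s.points[:, 0] < 5.0).sum()
    p = 125 / 375
    se = np.sqrt(p * (1 - p) / n)
    assert abs(in_a / n - p) <= 3 * se


def test_draw_samples_validation():
    m = BinaryMask(np.ones((4, 4, 4), np.uint8), (1, 1, 1), (0, 0, 0),
                   np.eye(3))
    with pytest.raises(ConfigurationError):
        draw_samples(m, 0, 0)
    empty = BinaryMask(np.zeros((4, 4, 4), np.uint8), (1, 1, 1), (0, 0, 0),
                       np.eye(3))
    with pytest.raises(EmptyInputError):
        draw_samples(empty, 10, 0)


# ---------------------------------------------------------------------------
# SplineImage
# ---------------------------------------------------------------------------

def test_spline_image_interpolates_voxel_centers():
    img = smooth_image(seed=1)
    spl = SplineImage(img)
    idx = np.argwhere(np.ones((20, 20, 20), bool))[::37]
    pts = img.geometry.world_from_index(idx)
    vals = spl.values(pts)
    assert np.allclose(vals, img.voxels[idx[:, 0], idx[:, 1], idx[:, 2]],
                       atol=1e-8)


def test_spline_image_gradient_matches_fd():
    img = smooth_image(seed=2)
    spl = SplineImage(img)
    r = np.random.default_rng(3)
    pts = r.uniform(3, 16, (30, 3))
    _, g = spl.values_and_gradient(pts)
    e = 1e-4
    for d in range(3):
        step = np.zeros(3)
        step[d] = e
        fd = (spl.values(pts + step) - spl.values(pts - step)) / (2 * e)
        assert np.allclose(g[:, d], fd, rtol=1e-4, atol=1e-6)


def test_intensity_range_respects_mask():
    img = smooth_image(seed=4)
    lo, hi = intensity_range(img)
    assert lo == img.voxels.min() and hi == img.voxels.max()
    vox = np.zeros((20, 20, 20), np.uint8)
    vox[5:8, 5:8, 5:8] = 1
    m = BinaryMask(vox, img.spacing, img.origin, img.direction)
    lo_m, hi_m = intensity_range(img, m)
    sub = img.voxels[5:8, 5:8, 5:8]
    assert lo_m == sub.min() and hi_m == sub.max()


# ---------------------------------------------------------------------------
# joint histogram
# ---------------------------------------------------------------------------

def two_level_image():
    vox = np.zeros((8, 8, 8))
    vox[4:] = 100.0
    return Image3D(vox, (1.0, 1.0, 1.0), (0, 0, 0), np.eye(3))


def test_histogram_normalized_and_mi_log2_for_identical():
    img = two_level_image()
    samples = centers_sample_set(img)
    h = joint_histogram(img, img, IdentityTransform(), samples, bins=2,
                        fixed_range=(0.0, 100.0), moving_range=(0.0, 100.0),
                        window="nearest")
    assert np.isclose(h.probabilities.sum(), 1.0, atol=1e-12)
    assert np.isclose(mutual_information(h), np.log(2.0), atol=1e-9)


def test_mi_zero_for_independent():
    vox_f = np.zeros((8, 8, 8))
    vox_f[4:] = 100.0                     # varies along x
    vox_m = np.zeros((8, 8, 8))
    vox_m[:, 4:] = 100.0                  # varies along y
    f = Image3D(vox_f, (1, 1, 1), (0, 0, 0), np.eye(3))
    m = Image3D(vox_m, (1, 1, 1), (0, 0, 0), np.eye(3))
    samples = centers_sample_set(f)
    h = joint_histogram(f, m, IdentityTransform(), samples, bins=2,
                        fixed_range=(0.0, 100.0), moving_range=(0.0, 100.0),
                        window="nearest")
    assert abs(mutual_information(h)) < 1e-12


def test_nearest_histogram_matches_pair_count_oracle():
    r = np.random.default_rng(5)
    f = Image3D(r.uniform(0, 100, (6, 6, 6)), (1, 1, 1), (0, 0, 0), np.eye(3))
    m = Image3D(r.uniform(0, 100, (6, 6, 6)), (1, 1, 1), (0, 0, 0), np.eye(3))
    samples = centers_sample_set(f)
    bins = 4
    h = joint_histogram(f, m, IdentityTransform(), samples, bins=bins,
                        fixed_range=(0.0, 100.0), moving_range=(0.0, 100.0),
                        window="nearest")
    # oracle: count pairs of floor-binned voxel values
    counts = np.zeros((bins, bins))
    fv = f.voxels.ravel()
    mv = m.voxels.ravel()
    fb = np.minimum((fv / 100.0 * bins).astype(int), bins - 1)
    mb = np.minimum((mv / 100.0 * bins).astype(int), bins - 1)
    for a, b in zip(fb, mb):
        counts[a, b] += 1
    assert np.allclose(h.probabilities, counts / counts.sum(), atol=1e-9)


def test_parzen_histogram_normalized_and_mi_finite():
    f = smooth_image(seed=6)
    m = smooth_image(seed=7)
    samples = draw_samples(full_mask(f), 1500, 8)
    h = joint_histogram(f, m, IdentityTransform(), samples, bins=16,
                        fixed_range=intensity_range(f),
                        moving_range=intensity_range(m))
    assert np.isclose(h.probabilities.sum(), 1.0, atol=1e-9)
    assert np.all(h.probabilities >= 0.0)
    assert np.isfinite(mutual_information(h))


def test_mi_matches_direct_double_sum():
    r = np.random.default_rng(9)
    for _ in range(5):
        p = r.uniform(size=(8, 8))
        p[r.uniform(size=p.shape) < 0.3] = 0.0
        p /= p.sum()
        h = JointHistogram(p, np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        assert np.isclose(mutual_information(h), mi_oracle(p), atol=1e-12)


def test_mi_rejects_unnormalized():
    p = np.full((4, 4), 1.0)
    h = JointHistogram(p, np.linspace(0, 1, 5), np.linspace(0, 1, 5))
    with pytest.raises(ContractViolationError):
        mutual_information(h)


def test_gross_misalignment_raises():
    f = smooth_image(seed=10)
    m = smooth_image(seed=11)
    samples = draw_samples(full_mask(f), 400, 12)
    far = RigidTransform3D(np.eye(3), np.array([500.0, 0.0, 0.0]))
    with pytest.raises(GrossMisalignmentError):
        joint_histogram(f, m, far, samples, bins=8,
                        fixed_range=intensity_range(f),
                        moving_range=intensity_range(m))


# ---------------------------------------------------------------------------
# MI gradient
# ---------------------------------------------------------------------------

def _mi_of(f, spl, T, samples, bins, fr, mr):
    h = joint_histogram(f, spl, T, samples, bins, fr, mr)
    return mutual_information(h)


def test_mi_gradient_matches_finite_differences():
    f = smooth_image(seed=13)
    m = smooth_image(seed=14)
    spl = SplineImage(m)
    ffd = BSplineFFD.for_domain((0, 0, 0), (19, 19, 19), 8.0)
    r = np.random.default_rng(15)
    ffd.coefficients = r.normal(scale=0.5, size=ffd.coefficients.shape)
    ffd.extrapolate = "zero"
    samples = draw_samples(full_mask(f), 800, 16)
    fr = intensity_range(f)
    mr = intensity_range(m)
    mi, grad = mi_gradient(f, spl, ffd, samples, 16, fr, mr)
    assert np.isclose(mi, _mi_of(f, spl, ffd, samples, 16, fr, mr),
                      atol=1e-12)
    # central differences on the largest-magnitude entries
    flat = np.argsort(np.abs(grad).ravel())[::-1][:8]
    e = 1e-3
    for k in flat:
        i, j, l, d = np.unravel_index(k, grad.shape)
        c0 = ffd.coefficients[i, j, l, d]
        ffd.coefficients[i, j, l, d] = c0 + e
        hi = _mi_of(f, spl, ffd, samples, 16, fr, mr)
        ffd.coefficients[i, j, l, d] = c0 - e
        lo = _mi_of(f, spl, ffd, samples, 16, fr, mr)
        ffd.coefficients[i, j, l, d] = c0
        fd = -(hi - lo) / (2 * e)     # gradient of -MI
        assert np.isclose(grad[i, j, l, d], fd, rtol=2e-2, atol=1e-7)


def test_mi_gradient_zero_outside_sample_support():
    f = smooth_image(seed=17)
    m = smooth_image(seed=18)
    ffd = BSplineFFD.for_domain((0, 0, 0), (19, 19, 19), 4.0)
    ffd.extrapolate = "zero"
    # samples confined to one corner
    vox = np.zeros((20, 20, 20), np.uint8)
    vox[:5, :5, :5] = 1
    corner = BinaryMask(vox, (1, 1, 1), (0, 0, 0), np.eye(3))
    samples = draw_samples(corner, 300, 19)
    _, grad = mi_gradient(f, SplineImage(m), ffd, samples, 8,
                          intensity_range(f), intensity_range(m))
    # control points whose support is far from the corner get exact zeros
    assert np.allclose(grad[10:, :, :], 0.0)
    assert np.allclose(grad[:, 10:, :], 0.0)
    assert not np.allclose(grad, 0.0)


def test_mi_higher_at_alignment_than_offset():
    f = smooth_image(seed=20)
    samples = draw_samples(full_mask(f), 2000, 21)
    fr = intensity_range(f)
    spl = SplineImage(f)
    aligned = _mi_of(f, spl, IdentityTransform(), samples, 16, fr, fr)
    shift = RigidTransform3D(np.eye(3), np.array([5.0, 0.0, 0.0]))
    offset = _mi_of(f, spl, shift, samples, 16, fr, fr)
    assert aligned > offset


def test_mi_gradient_through_composite_outer_rigid():
    f = smooth_image(seed=22)
    m = smooth_image(seed=23)
    spl = SplineImage(m)
    ffd = BSplineFFD.for_domain((0, 0, 0), (19, 19, 19), 8.0)
    ffd.extrapolate = "zero"
    rig = RigidTransform3D.from_euler_zyx((0, 0, 0.05), (0.5, -0.5, 0.2),
                                          (10, 10, 10))
    T = CompositeTransform([rig, ffd])
    samples = draw_samples(full_mask(f), 600, 24)
    fr = intensity_range(f)
    mr = intensity_range(m)
    mi, grad = mi_gradient(f, spl, T, samples, 12, fr, mr)
    flat = np.argsort(np.abs(grad).ravel())[::-1][:4]
    e = 1e-3
    for k in flat:
        i, j, l, d = np.unravel_index(k, grad.shape)
        c0 = ffd.coefficients[i, j, l, d]
        ffd.coefficients[i, j, l, d] = c0 + e
        hi = _mi_of(f, spl, T, samples, 12, fr, mr)
        ffd.coefficients[i, j, l, d] = c0 - e
        lo = _mi_of(f, spl, T, samples, 12, fr, mr)
        ffd.coefficients[i, j, l, d] = c0
        fd = -(hi - lo) / (2 * e)
        assert np.isclose(grad[i, j, l, d], fd, rtol=2e-2, atol=1e-7)
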