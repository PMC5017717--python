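"""transforms: basis, rigid, FFD, composite, refinement, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverreg._exceptions import ConfigurationError, DomainError
from liverreg.transforms import (BSplineFFD, CompositeTransform,
                                 IdentityTransform, RigidTransform3D,
                                 bspline3_weights, embed_affine, refine_grid,
                                 transform_from_dict, transform_to_dict)


def random_ffd(seed=0, spacing=10.0, scale=2.0, lo=(0, 0, 0),
               hi=(60, 60, 60)):
    r = np.random.default_rng(seed)
    ffd = BSplineFFD.for_domain(lo, hi, spacing)
    ffd.coefficients = r.normal(scale=scale, size=ffd.coefficients.shape)
    return ffd


def interior_points(ffd, n=50, seed=1):
    lo, hi = ffd.supported_bounds()
    r = np.random.default_rng(seed)
    return r.uniform(lo + 1e-6, hi - 1e-6, (n, 3))


# ---------------------------------------------------------------------------
# cubic basis
# ---------------------------------------------------------------------------

def test_basis_partition_of_unity():
    u = np.linspace(0, 1, 23)
    assert np.allclose(bspline3_weights(u).sum(axis=-1), 1.0, atol=1e-12)
    assert np.allclose(bspline3_weights(u, 1).sum(axis=-1), 0.0, atol=1e-12)
    assert np.allclose(bspline3_weights(u, 2).sum(axis=-1), 0.0, atol=1e-12)


def test_basis_derivatives_match_fd():
    u = np.linspace(0.05, 0.95, 7)
    e = 1e-6
    d1 = (bspline3_weights(u + e) - bspline3_weights(u - e)) / (2 * e)
    assert np.allclose(d1, bspline3_weights(u, 1), atol=1e-8)
    d2 = (bspline3_weights(u + e, 1) - bspline3_weights(u - e, 1)) / (2 * e)
    assert np.allclose(d2, bspline3_weights(u, 2), atol=1e-6)


# ---------------------------------------------------------------------------
# rigid
# ---------------------------------------------------------------------------

def test_rigid_apply_and_inverse():
    t = RigidTransform3D.from_euler_zyx((0.2, -0.1, 0.4), (3, -2, 1),
                                        (10, 5, 0))
    pts = np.random.default_rng(0).uniform(-20, 20, (30, 3))
    back = t.inverse().apply(t.apply(pts))
    assert np.allclose(back, pts, atol=1e-9)


def test_rigid_rotation_validated():
    with pytest.raises(ConfigurationError):
        RigidTransform3D(np.eye(3) * 1.5, np.zeros(3))
    with pytest.raises(ConfigurationError):
        RigidTransform3D(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def test_rigid_jacobian_is_rotation():
    ang = np.deg2rad(30)
    t = RigidTransform3D.from_euler_zyx((0, 0, ang))
    J = t.spatial_jacobian(np.random.default_rng(0).uniform(0, 9, (5, 3)))
    assert np.allclose(J, t.rotation)
    assert np.allclose(t.second_derivatives([(1.0, 2.0, 3.0)]), 0.0)


# ---------------------------------------------------------------------------
# FFD evaluation
# ---------------------------------------------------------------------------

def test_ffd_zero_coefficients_identity():
    ffd = BSplineFFD.for_domain((0, 0, 0), (50, 50, 50), 10.0)
    pts = interior_points(ffd, 20)
    assert np.allclose(ffd.apply(pts), pts, atol=1e-12)


def test_ffd_constant_coefficients_translation():
    ffd = BSplineFFD.for_domain((0, 0, 0), (50, 50, 50), 10.0)
    ffd.coefficients = ffd.coefficients + np.array([5.0, 0.0, 0.0])
    pts = interior_points(ffd, 20)
    assert np.allclose(ffd.apply(pts), pts + (5, 0, 0), atol=1e-9)


def test_ffd_displacement_matches_tensor_product_oracle():
    ffd = random_ffd(2)
    h = ffd.control_spacing
    for p in interior_points(ffd, 10, seed=3):
        s = (p - ffd.grid_origin) / h
        i = np.floor(s).astype(int)
        u = s - i
        expect = np.zeros(3)
        wx = bspline3_weights(u[0])
        wy = bspline3_weights(u[1])
        wz = bspline3_weights(u[2])
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    w = wx[a] * wy[b] * wz[c]
                    expect += w * ffd.coefficients[i[0] - 1 + a,
                                                   i[1] - 1 + b,
                                                   i[2] - 1 + c]
        assert np.allclose(ffd.displacement(p[None])[0], expect, atol=1e-10)


def test_ffd_outside_support_raises_or_zero():
    ffd = random_ffd(4)
    lo, hi = ffd.supported_bounds()
    outside = hi + 50.0
    with pytest.raises(DomainError):
        ffd.apply(outside)
    ffd.extrapolate = "zero"
    assert np.allclose(ffd.apply(outside), outside)


def test_ffd_jacobian_matches_fd():
    ffd = random_ffd(5)
    pts = interior_points(ffd, 15, seed=6)
    J = ffd.spatial_jacobian(pts)
    e = 1e-3
    for d in range(3):
        step = np.zeros(3)
        step[d] = e
        fd = (ffd.apply(pts + step) - ffd.apply(pts - step)) / (2 * e)
        assert np.allclose(J[:, :, d], fd, rtol=1e-4, atol=1e-6)


def test_ffd_second_derivatives_match_fd():
    ffd = random_ffd(7)
    pts = interior_points(ffd, 10, seed=8)
    H = ffd.second_derivatives(pts)
    e = 1e-3
    for i in range(3):
        for j in range(3):
            si = np.zeros(3)
            sj = np.zeros(3)
            si[i] = e
            sj[j] = e
            fd = (ffd.apply(pts + si + sj) - ffd.apply(pts + si - sj)
                  - ffd.apply(pts - si + sj) + ffd.apply(pts - si - sj)) \
                / (4 * e * e)
            assert np.allclose(H[:, :, i, j], fd, rtol=1e-3, atol=1e-5)
    assert np.allclose(H, np.swapaxes(H, 2, 3), atol=1e-12)


def test_affine_ffd_has_zero_second_derivatives():
    base = BSplineFFD.for_domain((0, 0, 0), (40, 40, 40), 10.0)
    A = np.array([[1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.0]])
    ffd = embed_affine(base, A, np.array([1.0, -2.0, 3.0]))
    pts = interior_points(ffd, 10, seed=9)
    assert np.allclose(ffd.second_derivatives(pts), 0.0, atol=1e-9)
    assert np.allclose(ffd.spatial_jacobian(pts), A, atol=1e-9)


# ---------------------------------------------------------------------------
# embed_affine
# ---------------------------------------------------------------------------

def test_embed_affine_identity_and_translation():
    base = BSplineFFD.for_domain((0, 0, 0), (40, 40, 40), 10.0)
    ident = embed_affine(base, np.eye(3), np.zeros(3))
    assert np.allclose(ident.coefficients, 0.0)
    trans = embed_affine(base, np.eye(3), np.array([3.0, -2.0, 1.0]))
    pts = interior_points(trans, 20, seed=10)
    assert np.allclose(trans.apply(pts), pts + (3, -2, 1), atol=1e-9)


def test_embed_affine_rotation_matches_rigid():
    base = BSplineFFD.for_domain((0, 0, 0), (60, 60, 60), 12.0)
    rig = RigidTransform3D.from_euler_zyx((0, 0, np.deg2rad(20)))
    ffd = embed_affine(base, rig.rotation, rig.translation)
    pts = interior_points(ffd, 100, seed=11)
    assert np.allclose(ffd.apply(pts), rig.apply(pts), atol=1e-9)


# ---------------------------------------------------------------------------
# refine_grid
# ---------------------------------------------------------------------------

def test_refine_identity_and_translation():
    ffd = BSplineFFD.for_domain((0, 0, 0), (40, 40, 40), 20.0)
    fine = refine_grid(ffd, 10.0)
    assert np.allclose(fine.coefficients, 0.0, atol=1e-12)
    ffd.coefficients = ffd.coefficients + np.array([2.0, 0.0, -1.0])
    fine = refine_grid(ffd, 10.0)
    pts = interior_points(ffd, 20, seed=12)
    assert np.allclose(fine.apply(pts), pts + (2, 0, -1), atol=1e-9)


def test_refine_dyadic_preserves_field():
    ffd = random_ffd(13, spacing=20.0, hi=(80, 80, 80))
    fine = refine_grid(ffd, 10.0)
    pts = interior_points(ffd, 100, seed=14)
    assert np.allclose(fine.displacement(pts), ffd.displacement(pts),
                       atol=1e-9)


def test_refine_general_path_close():
    ffd = random_ffd(15, spacing=20.0, hi=(80, 80, 80))
    fine = refine_grid(ffd, 8.0)   # not dyadic: resampled, not exact
    r = np.random.default_rng(16)
    pts = r.uniform(8, 72, (100, 3))
    assert np.allclose(fine.displacement(pts), ffd.displacement(pts),
                       atol=0.1)


def test_refine_coarser_spacing_rejected():
    ffd = random_ffd(17, spacing=10.0)
    with pytest.raises(ConfigurationError):
        refine_grid(ffd, 20.0)


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

def test_composite_order_right_to_left():
    t1 = RigidTransform3D(np.eye(3), np.array([1.0, 0.0, 0.0]))
    rot = RigidTransform3D.from_euler_zyx((0, 0, np.pi / 2))
    comp = CompositeTransform([rot, t1])  # t1 first, then rot
    out = comp.apply(np.array([0.0, 0.0, 0.0]))
    assert np.allclose(out, (0.0, 1.0, 0.0), atol=1e-12)


def test_composite_jacobian_and_hessian_match_fd():
    ffd = random_ffd(18, spacing=15.0, hi=(60, 60, 60), scale=1.5)
    rig = RigidTransform3D.from_euler_zyx((0.1, 0.2, 0.3), (5, -3, 2),
                                          (30, 30, 30))
    comp = CompositeTransform([rig, ffd])
    pts = interior_points(ffd, 8, seed=19)
    J = comp.spatial_jacobian(pts)
    H = comp.second_derivatives(pts)
    e = 1e-3
    for d in range(3):
        step = np.zeros(3)
        step[d] = e
        fd = (comp.apply(pts + step) - comp.apply(pts - step)) / (2 * e)
        assert np.allclose(J[:, :, d], fd, rtol=1e-4, atol=1e-6)
    for i in range(3):
        for j in range(3):
            si = np.zeros(3)
            sj = np.zeros(3)
            si[i] = e
            sj[j] = e
            fd = (comp.apply(pts + si + sj) - comp.apply(pts + si - sj)
                  - comp.apply(pts - si + sj) + comp.apply(pts - si - sj)) \
                / (4 * e * e)
            assert np.allclose(H[:, :, i, j], fd, rtol=1e-3, atol=1e-5)


def test_composite_with_inverse_is_identity():
    t = RigidTransform3D.from_euler_zyx((0.3, -0.2, 0.1), (4, 5, -6),
                                        (1, 2, 3))
    comp = CompositeTransform([t.inverse(), t])
    pts = np.random.default_rng(20).uniform(-30, 30, (40, 3))
    assert np.allclose(comp.apply(pts), pts, atol=1e-9)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_serialization_round_trip_bit_exact():
    ffd = random_ffd(21)
    rig = RigidTransform3D.from_euler_zyx((0.1, 0.2, 0.3), (1, 2, 3),
                                          (4, 5, 6))
    comp = CompositeTransform([rig, ffd, IdentityTransform()])
    doc = transform_to_dict(comp)
    back = transform_from_dict(doc)
    assert np.array_equal(back.components[1].coefficients, ffd.coefficients)
    assert np.array_equal(back.components[0].rotation, rig.rotation)
    pts = interior_points(ffd, 10, seed=22)
    assert np.array_equal(back.apply(pts), comp.apply(pts))


def test_serialization_rejects_unknown_version():
    doc = transform_to_dict(IdentityTransform())
    doc["format_version"] = 99
    with pytest.raises(ConfigurationError):
        transform_from_dict(doc)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(0, 10_000))
def test_property_partition_of_unity_ffd(seed):
    r = np.random.default_rng(seed)
    v = r.uniform(-5, 5, 3)
    spacing = float(r.uniform(5, 25))
    ffd = BSplineFFD.for_domain((0, 0, 0), (50, 50, 50), spacing)
    ffd.coefficients = ffd.coefficients + v
    lo, hi = ffd.supported_bounds()
    pts = r.uniform(lo + 1e-9, hi - 1e-9, (10, 3))
    assert np.allclose(ffd.displacement(pts), v, atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=15)
@given(st.integers(0, 10_000))
def test_property_linear_precision(seed):
    r = np.random.default_rng(seed)
    A = np.eye(3) + r.normal(scale=0.1, size=(3, 3))
    t = r.uniform(-5, 5, 3)
    base = BSplineFFD.for_domain((0, 0, 0), (40, 40, 40), 10.0)
    ffd = embed_affine(base, A, t)
    lo, hi = ffd.supported_bounds()
    pts = r.uniform(lo, hi, (10, 3))
    assert np.allclose(ffd.apply(pts), pts @ A.T + t, atol=1e-8)
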