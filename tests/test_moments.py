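"""Exact moment engine: closed forms, oracles, and invariances."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from epifold.moments import (
    MomentError,
    compute_moments,
    moment_orders,
    polarity_frame,
    rotate_moments,
    shape_features,
    surface_area,
    tetra_monomial_integral,
)
from oracles import column_moments, monte_carlo_tetra

E = np.eye(3)


@pytest.mark.parametrize(
    "verts,ijk,expected",
    [
        ((E[0], E[1], E[2]), (0, 0, 0), 1 / 6),  # unit simplex volume
        ((E[0], E[1], E[2]), (1, 0, 0), 1 / 24),  # Dirichlet 1!0!0!/4!
        ((E[1], E[0], E[2]), (0, 0, 0), -1 / 6),  # vertex swap flips sign
        ((E[0], E[1], E[2]), (1, 1, 1), 1 / 720),  # 1!1!1!/6!
        ((E[0], 2 * E[0], E[2]), (0, 0, 0), 0.0),  # degenerate tetra
    ],
)
def test_tetra_integral_closed_forms(verts, ijk, expected):
    assert tetra_monomial_integral(*verts, *ijk) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("ijk", [(0, 0, 0), (2, 1, 0), (0, 0, 3)])
def test_tetra_integral_matches_monte_carlo(ijk):
    rng = np.random.default_rng(3)
    v = rng.normal(size=(3, 3))
    exact = tetra_monomial_integral(v[0], v[1], v[2], *ijk)
    mc = monte_carlo_tetra(v[0], v[1], v[2], *ijk, seed=4)
    assert exact == pytest.approx(mc, rel=0.02, abs=1e-3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(moment_orders(3)))
def test_tetra_integral_antisymmetric_under_swap(seed, ijk):
    rng = np.random.default_rng(seed)
    v1, v2, v3 = rng.normal(size=(3, 3))
    a = tetra_monomial_integral(v1, v2, v3, *ijk)
    b = tetra_monomial_integral(v2, v1, v3, *ijk)
    assert a == pytest.approx(-b, rel=1e-12, abs=1e-15)


def test_unit_cube_moments():
    box = trimesh.creation.box((1.0, 1.0, 1.0))
    m = compute_moments(box.vertices, box.faces)
    assert m.volume == pytest.approx(1.0, rel=1e-12)
    for axis in [(2, 0, 0), (0, 2, 0), (0, 0, 2)]:
        assert m[axis] == pytest.approx(1 / 12, rel=1e-12)
    for key, val in m.values.items():
        if sum(key) % 2 == 1:
            assert abs(val) < 1e-12


def test_icosphere_volume():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=3.0)
    m = compute_moments(sph.vertices, sph.faces)
    assert m.volume == pytest.approx(4 / 3 * np.pi * 27, rel=0.005)


def test_random_convex_meshes_match_dense_integration():
    """Facet-sum moments vs brute-force column quadrature, 25 random shapes."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        pts = rng.normal(size=(int(rng.integers(10, 40)), 3)) * rng.uniform(0.5, 3, size=3)
        hull = trimesh.convex.convex_hull(pts)
        m = compute_moments(hull.vertices, hull.faces)
        dense = column_moments(np.asarray(hull.vertices), m.origin)
        scale = np.sqrt((m[(2, 0, 0)] + m[(0, 2, 0)] + m[(0, 0, 2)]) / m.volume)
        for key in m.values:
            floor = m.volume * scale ** sum(key) / 10
            assert m[key] == pytest.approx(dense[key], rel=0.01, abs=0.01 * floor)


def test_nonconvex_topology_torus_volume():
    """The signed facet sum handles genus-1 shapes: torus volume 2 pi^2 R r^2."""
    tor = trimesh.creation.torus(major_radius=4.0, minor_radius=1.5,
                                 major_sections=96, minor_sections=48)
    m = compute_moments(tor.vertices, tor.faces)
    assert m.volume == pytest.approx(2 * np.pi**2 * 4.0 * 1.5**2, rel=0.01)


def test_first_central_moments_vanish():
    rng = np.random.default_rng(11)
    hull = trimesh.convex.convex_hull(rng.normal(size=(30, 3)) + 5.0)
    m = compute_moments(hull.vertices, hull.faces)
    diag = np.linalg.norm(hull.extents)
    for key in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
        assert abs(m[key]) < 1e-6 * m.volume * diag


def test_open_mesh_rejected():
    box = trimesh.creation.box((1, 1, 1))
    with pytest.raises(MomentError, match="not closed"):
        compute_moments(box.vertices, box.faces[:-1])


def test_inverted_winding_rejected():
    """Flipping every face winding negates the enclosed volume: the engine
    uses the sign as its closed-surface orientation check."""
    box = trimesh.creation.box((1, 1, 1))
    with pytest.raises(MomentError, match="orientation"):
        compute_moments(box.vertices, box.faces[:, ::-1])


class TestRotation:
    def test_identity_axis_is_identity(self):
        box = trimesh.creation.box((1, 2, 3))
        m = compute_moments(box.vertices, box.faces)
        r = rotate_moments(m, np.array([0.0, 0.0, 1.0]))
        for key in m.values:
            assert r[key] == pytest.approx(m[key], rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        box = trimesh.creation.box((1, 1, 1))
        m = compute_moments(box.vertices, box.faces)
        r = rotate_moments(m, n)
        assert r.volume == pytest.approx(m.volume, rel=1e-12)
        tr_m = m[(2, 0, 0)] + m[(0, 2, 0)] + m[(0, 0, 2)]
        tr_r = r[(2, 0, 0)] + r[(0, 2, 0)] + r[(0, 0, 2)]
        assert tr_r == pytest.approx(tr_m, rel=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_tensor_route_equals_vertex_rotation(self, seed):
        """Transforming the moment tensors must agree with recomputing the
        moments on rotated vertices to machine precision."""
        rng = np.random.default_rng(seed)
        hull = trimesh.convex.convex_hull(rng.normal(size=(25, 3)))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        m = compute_moments(hull.vertices, hull.faces)
        r_tensor = rotate_moments(m, n)
        Q = polarity_frame(n)
        verts = (np.asarray(hull.vertices) - m.origin) @ Q.T
        r_direct = compute_moments(verts, hull.faces, origin=np.zeros(3))
        scale = max(abs(v) for v in m.values.values())
        for key in m.values:
            assert abs(r_tensor[key] - r_direct[key]) < 1e-9 * scale

    def test_elongated_box_longitudinal_moment(self):
        """A 1x1x4 box pre-rotated arbitrarily: with the polarity along its
        long axis the aligned variance must recover 4^2 / 12."""
        box = trimesh.creation.box((1.0, 1.0, 4.0))
        rot = trimesh.transformations.rotation_matrix(0.9, (1, 2, 0.5))
        box.apply_transform(rot)
        long_axis = rot[:3, :3] @ np.array([0.0, 0.0, 1.0])
        m = compute_moments(box.vertices, box.faces)
        r = rotate_moments(m, long_axis)
        assert r[(0, 0, 2)] / r.volume == pytest.approx(16 / 12, rel=1e-9)


def test_translation_invariance_of_central_moments():
    rng = np.random.default_rng(21)
    hull = trimesh.convex.convex_hull(rng.normal(size=(30, 3)))
    m0 = compute_moments(hull.vertices, hull.faces)
    m1 = compute_moments(np.asarray(hull.vertices) + [17.0, -4.0, 8.0], hull.faces)
    scale = max(abs(v) for v in m0.values.values())
    for key in m0.values:
        assert abs(m0[key] - m1[key]) < 1e-9 * scale


class TestShapeFeatures:
    def test_icosphere_is_spherical_and_unskewed(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        m = compute_moments(sph.vertices, sph.faces)
        f = shape_features(
            rotate_moments(m, np.array([0, 0, 1.0])),
            surface_area(sph.vertices, sph.faces),
        )
        assert f.sphericity >= 0.99
        assert abs(f.skewness) < 0.01

    def test_cube_sphericity_closed_form(self):
        box = trimesh.creation.box((1.0, 1.0, 1.0))
        m = compute_moments(box.vertices, box.faces)
        f = shape_features(
            rotate_moments(m, np.array([0, 0, 1.0])),
            surface_area(box.vertices, box.faces),
        )
        assert f.sphericity == pytest.approx((np.pi / 6) ** (1 / 3), rel=0.01)

    def test_cone_skew_antisymmetric(self):
        """Apex apical vs apex basal: equal magnitude, opposite sign; the
        positive sign denotes apical constriction."""
        cone = trimesh.creation.cone(radius=2.0, height=3.0, sections=64)
        up = np.array([0.0, 0.0, 1.0])
        m = compute_moments(cone.vertices, cone.faces)
        area = surface_area(cone.vertices, cone.faces)
        f_up = shape_features(rotate_moments(m, up), area)
        f_dn = shape_features(rotate_moments(m, -up), area)
        assert f_up.skewness > 0.3  # apex toward apical side
        assert f_dn.skewness == pytest.approx(-f_up.skewness, rel=1e-9)

    def test_spreads_nonnegative_and_volume_positive(self):
        rng = np.random.default_rng(8)
        hull = trimesh.convex.convex_hull(rng.normal(size=(20, 3)))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        m = compute_moments(hull.vertices, hull.faces)
        f = shape_features(rotate_moments(m, n), surface_area(hull.vertices, hull.faces))
        assert f.volume > 0
        assert f.longitudinal_spread >= 0
        assert f.transversal_spread >= 0
        assert 0 < f.sphericity <= 1 + 1e-6
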