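import numpy as np
import pytest

from kneemorph.mesh_core import points_inside
from kneemorph.meniscus import (
    build_meniscus,
    cross_section_triangle,
    meniscal_center,
)
from kneemorph.profiles import PolynomialProfile
from kneemorph.wrap_engine import ObstacleSet
from tests.conftest import icosphere


def semicircle(n=40, R=15.0):
    th = np.linspace(0, np.pi, n)
    return np.c_[R * np.cos(th), R * np.sin(th), np.zeros(n)]


class TestMeniscalCenter:
    def test_semicircle_center_near_circle_center(self):
        c = meniscal_center(semicircle(), plane=(np.zeros(3),
                                                 np.array([0.0, 0.0, 1.0])))
        # arc centroid of a semicircle sits at (0, 2R/pi); the projected
        # center must stay within 0.05 R of the circle center in x
        assert abs(c[0]) < 0.05 * 15.0
        assert c[1] == pytest.approx(2 * 15.0 / np.pi, rel=0.01)

    def test_symmetric_c_shape_center_on_symmetry_plane(self):
        pts = semicircle()  # symmetric about the y axis
        c = meniscal_center(pts)
        assert abs(c[0]) < 1e-6

    def test_collinear_centerline_rejected(self):
        pts = np.c_[np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)]
        with pytest.raises(ValueError, match="collinear"):
            meniscal_center(pts)


class TestCrossSection:
    def test_definitional_geometry(self):
        tri = cross_section_triangle([0, 0, 0], [1, 0, 0], [0, 0, 1],
                                     height=2.0, width=3.0)
        assert np.allclose(tri, [[3, 0, 0], [0, 0, 1], [0, 0, -1]])

    def test_area_is_half_height_times_width(self):
        tri = cross_section_triangle([0, 0, 0], [1, 0, 0], [0, 0, 1],
                                     height=2.0, width=3.0)
        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        assert area == pytest.approx(3.0)

    def test_rigid_equivariance(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        node = rng.normal(size=3)
        tc, up = q[:, 0], q[:, 2]
        a = cross_section_triangle([0, 0, 0], [1, 0, 0], [0, 0, 1], 2.0, 3.0)
        b = cross_section_triangle(q @ node * 0 + node, tc, up, 2.0, 3.0)
        expect = a @ np.column_stack([tc, q[:, 1] * 0 + np.cross(up, tc) * -1,
                                      up]).T
        # equivariance checked via invariants instead of frame bookkeeping:
        assert np.linalg.norm(b[1] - b[2]) == pytest.approx(2.0)
        assert np.linalg.norm(b[0] - node) == pytest.approx(3.0)

    def test_non_orthonormal_inputs_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            cross_section_triangle([0, 0, 0], [1, 0, 0], [0.6, 0, 0.8],
                                   1.0, 1.0)
        with pytest.raises(ValueError, match="unit"):
            cross_section_triangle([0, 0, 0], [2, 0, 0], [0, 0, 1], 1.0, 1.0)


class TestBuildMeniscus:
    @pytest.fixture(scope="class")
    def condyle(self):
        return icosphere(3, 12.0)

    def test_constant_profiles_reproduce_cross_sections(self):
        # roots flanking a small condyle; the path bows around it in-plane
        condyle = icosphere(3, 6.0)
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([3.0]))
        wp = PolynomialProfile(np.array([2.0]))
        ant = np.array([-12.0, 1.0, 0.0])
        post = np.array([12.0, 1.0, 0.0])
        model = build_meniscus(obstacles, ant, post, hp, wp, side="medial",
                               n_nodes=40,
                               tibial_plane=(np.zeros(3),
                                             np.array([0.0, 0.0, 1.0])))
        sections = model.surface.vertices.reshape(-1, 3, 3)
        # height everywhere; width at stations whose apex stays clear of
        # the condyle (near-root stations)
        for i in range(1, 39):
            apex, top, bottom = sections[i]
            assert np.linalg.norm(top - bottom) == pytest.approx(3.0, rel=0.02)
        for i in (2, 4, 35, 37):
            apex, top, bottom = sections[i]
            mid = 0.5 * (top + bottom)
            assert np.linalg.norm(apex - mid) == pytest.approx(2.0, rel=0.02)

    def test_wedge_watertight_and_clear_of_obstacle(self, condyle):
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([4.0]))
        wp = PolynomialProfile(np.array([8.0]))
        model = build_meniscus(obstacles, np.array([-16.0, 0, 0]),
                               np.array([16.0, 0, 0]), hp, wp,
                               n_nodes=40,
                               tibial_plane=(np.zeros(3),
                                             np.array([0.0, 0.0, 1.0])))
        assert model.surface.is_watertight()
        inside = points_inside(condyle, model.surface.vertices)
        assert not inside.any()

    def test_centerline_endpoints_are_roots(self, condyle):
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([4.0]))
        wp = PolynomialProfile(np.array([8.0]))
        ant = np.array([-16.0, 0.0, 0.0])
        post = np.array([16.0, 0.0, 0.0])
        model = build_meniscus(obstacles, ant, post, hp, wp, n_nodes=30,
                               tibial_plane=(np.zeros(3),
                                             np.array([0.0, 0.0, 1.0])))
        assert np.allclose(model.centerline.nodes[0], ant)
        assert np.allclose(model.centerline.nodes[-1], post)

    def test_degenerate_height_profile_warns_but_builds(self, condyle):
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([1e-4]))
        wp = PolynomialProfile(np.array([8.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            model = build_meniscus(obstacles, np.array([-16.0, 0, 0]),
                                   np.array([16.0, 0, 0]), hp, wp,
                                   n_nodes=20,
                                   tibial_plane=(np.zeros(3),
                                                 np.array([0.0, 0.0, 1.0])))
        assert model.surface.n_vertices == 60

    def test_mostly_nonpositive_profile_rejected(self, condyle):
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([-1.0]))
        wp = PolynomialProfile(np.array([8.0]))
        with pytest.raises(ValueError, match="non-positive"):
            build_meniscus(obstacles, np.array([-16.0, 0, 0]),
                           np.array([16.0, 0, 0]), hp, wp, n_nodes=20)

    def test_doubling_nodes_stable_volume(self, condyle):
        obstacles = ObstacleSet([condyle])
        hp = PolynomialProfile(np.array([4.0]))
        wp = PolynomialProfile(np.array([8.0]))
        args = (np.array([-16.0, 0, 0]), np.array([16.0, 0, 0]), hp, wp)
        kw = dict(tibial_plane=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
        v30 = build_meniscus(obstacles, *args, n_nodes=30,
                             **kw).surface.to_trimesh().volume
        v60 = build_meniscus(obstacles, *args, n_nodes=60,
                             **kw).surface.to_trimesh().volume
        assert abs(v60 - v30) / v30 < 0.02
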