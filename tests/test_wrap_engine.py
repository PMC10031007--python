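import numpy as np
import pytest

from kneemorph.mesh_core import points_inside
from kneemorph.wrap_engine import (
    ObstacleSet,
    RelaxParams,
    grid_to_mesh,
    project_out,
    wrap_chain,
    wrap_chain_offset,
    wrap_membrane,
)
from tests.conftest import icosphere


@pytest.fixture(scope="module")
def sphere_obstacles(sphere10):
    return ObstacleSet([sphere10])


def sphere_anchor_pair(R, theta):
    return (np.array([R, 0.0, 0.0]),
            np.array([R * np.cos(theta), R * np.sin(theta), 0.0]))


class TestWrapChain:
    def test_free_space_is_straight(self):
        res = wrap_chain([0, 0, 0], [30, 0, 0], ObstacleSet([]), n_nodes=50)
        assert res.length == pytest.approx(30.0, abs=1e-9)
        assert res.converged
        assert not res.contact.any()

    @pytest.mark.parametrize("R,theta", [(10.0, np.pi / 2),
                                         (10.0, 2 * np.pi / 3)])
    def test_taut_string_matches_great_circle(self, R, theta):
        sphere = icosphere(4, R)
        start, end = sphere_anchor_pair(R, theta)
        res = wrap_chain(start, end, ObstacleSet([sphere]), n_nodes=200)
        assert res.length == pytest.approx(R * theta, rel=0.02)

    def test_energy_trace_non_increasing(self, sphere_obstacles):
        start, end = sphere_anchor_pair(10.0, np.pi / 2)
        res = wrap_chain(start, end, sphere_obstacles, n_nodes=100)
        assert np.all(np.diff(res.energy_trace) <= 1e-9)

    def test_length_never_below_anchor_distance(self, sphere_obstacles, rng):
        for _ in range(3):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            e = rng.normal(size=3)
            e /= np.linalg.norm(e)
            res = wrap_chain(d * 14, e * 14, sphere_obstacles, n_nodes=60)
            anchor_dist = np.linalg.norm(d * 14 - e * 14)
            assert res.length >= anchor_dist - 1e-9

    def test_refinement_consistency(self, sphere_obstacles):
        start, end = sphere_anchor_pair(10.0, np.pi / 2)
        l1 = wrap_chain(start, end, sphere_obstacles, n_nodes=100).length
        l2 = wrap_chain(start, end, sphere_obstacles, n_nodes=200).length
        assert abs(l2 - l1) / l1 < 0.005

    def test_no_node_penetrates(self, sphere_obstacles):
        start, end = sphere_anchor_pair(10.0, 2 * np.pi / 3)
        res = wrap_chain(start, end, sphere_obstacles, n_nodes=100)
        # nodes may rest on the faceted faces, slightly under the true
        # radius by the chordal sagitta; the surface itself is respected
        assert sphere_obstacles.clearance(res.nodes).min() > -1e-6
        assert np.linalg.norm(res.nodes, axis=1).min() > 10.0 - 0.02

    def test_anchor_inside_obstacle_rejected(self, sphere_obstacles):
        with pytest.raises(ValueError, match="anchors"):
            wrap_chain([0, 0, 0], [20, 0, 0], sphere_obstacles)


class TestWrapChainOffset:
    def test_zero_offset_reduces_to_wrap_chain(self, sphere_obstacles):
        start, end = sphere_anchor_pair(10.0, np.pi / 2)
        a = wrap_chain(start, end, sphere_obstacles, n_nodes=80)
        b = wrap_chain_offset(start, end, sphere_obstacles, n_nodes=80,
                              offset_profile=0.0)
        assert np.allclose(a.nodes, b.nodes)

    def test_contact_nodes_sit_on_offset_surface(self, sphere10):
        obstacles = ObstacleSet([sphere10])
        res = wrap_chain_offset(np.array([15.0, 0, 0]), np.array([0, 15.0, 0]),
                                obstacles, n_nodes=100, offset_profile=2.0)
        d = np.linalg.norm(res.nodes, axis=1)
        # R + offset, minus the chordal depth of the faceted sphere
        assert d.min() > 12.0 - 0.02
        assert d[res.contact].max() < 12.0 + 0.01

    def test_anchor_violating_offset_rejected(self, sphere_obstacles):
        start, end = sphere_anchor_pair(10.0, np.pi / 2)  # on the surface
        with pytest.raises(ValueError, match="clearance"):
            wrap_chain_offset(start, end, sphere_obstacles, n_nodes=50,
                              offset_profile=3.0)

    def test_negative_offsets_rejected(self, sphere_obstacles):
        with pytest.raises(ValueError, match=">= 0"):
            wrap_chain_offset([15, 0, 0], [0, 15, 0], sphere_obstacles,
                              n_nodes=10, offset_profile=-1.0)


class TestWrapMembrane:
    def test_parallel_segments_give_planar_strip(self):
        oc = np.c_[np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)]
        ic = oc + np.array([0.0, 20.0, 0.0])
        res = wrap_membrane(oc, ic, ObstacleSet([]), n_rows=12)
        assert res.converged
        assert np.abs(res.nodes[..., 2]).max() < 1e-9

    def test_grid_clears_sphere(self, sphere10):
        oc = np.c_[np.linspace(-6, 6, 10), np.full(10, -14.0), np.zeros(10)]
        ic = np.c_[np.linspace(-6, 6, 10), np.full(10, 14.0), np.zeros(10)]
        res = wrap_membrane(oc, ic, ObstacleSet([sphere10]), n_rows=20)
        d = np.linalg.norm(res.nodes.reshape(-1, 3), axis=1)
        assert d.min() > 10.0 - 0.02
        assert np.all(np.diff(res.energy_trace) <= 1e-9)

    def test_single_point_curves_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            wrap_membrane([[0, 0, 0]], [[1, 0, 0]], ObstacleSet([]))

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same point count"):
            wrap_membrane(np.zeros((3, 3)), np.zeros((4, 3)), ObstacleSet([]))

    def test_grid_to_mesh_watertight_when_periodic_capped(self):
        t = np.linspace(0, 2 * np.pi, 13)[:-1]
        rows = []
        for z in np.linspace(0, 10, 5):
            rows.append(np.c_[np.cos(t) * 3, np.sin(t) * 3, np.full(12, z)])
        grid = np.stack(rows)
        verts, faces = grid_to_mesh(grid, periodic=True)
        assert len(faces) == 4 * 12 * 2


class TestProjectOut:
    def test_interior_point_moved_to_surface(self, sphere10):
        obstacles = ObstacleSet([sphere10])
        out = project_out([[0.0, 0.0, 0.0]], obstacles)
        assert np.linalg.norm(out[0]) == pytest.approx(10.0, abs=0.05)

    def test_exterior_point_unchanged(self, sphere10):
        obstacles = ObstacleSet([sphere10])
        p = np.array([[15.0, 1.0, -2.0]])
        assert np.array_equal(project_out(p, obstacles), p)

    def test_idempotent(self, sphere10, rng):
        obstacles = ObstacleSet([sphere10])
        pts = rng.uniform(-12, 12, size=(50, 3))
        once = project_out(pts, obstacles)
        twice = project_out(once, obstacles)
        assert np.allclose(once, twice, atol=1e-9)
        assert not points_inside(sphere10, once).any()

    def test_overlapping_obstacles_resolved(self):
        a = icosphere(3, 5.0)
        b = icosphere(3, 5.0).translated([4.0, 0.0, 0.0])
        obstacles = ObstacleSet([a, b])
        pts = np.array([[2.0, 0.0, 0.0]])  # inside both spheres
        out = project_out(pts, obstacles)
        assert not points_inside(a, out).any()
        assert not points_inside(b, out).any()


class TestObstacleSet:
    def test_requires_watertight(self):
        from kneemorph.mesh_core import CorrespondedMesh
        open_tri = CorrespondedMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="watertight"):
            ObstacleSet([open_tri])

    def test_inflation_grows_clearance(self, sphere10):
        plain = ObstacleSet([sphere10])
        inflated = ObstacleSet([sphere10], inflation=[2.0])
        p = np.array([[13.0, 0.0, 0.0]])
        assert inflated.clearance(p)[0] == pytest.approx(
            plain.clearance(p)[0] - 2.0, abs=1e-9)

    def test_negative_inflation_rejected(self, sphere10):
        with pytest.raises(ValueError):
            ObstacleSet([sphere10], inflation=[-1.0])
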