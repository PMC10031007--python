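import numpy as np
import pytest
import trimesh

from kneemorph.mesh_core import (
    CorrespondedMesh,
    MeshFormatError,
    SURFACE_TOL,
    _argmin_tiebreak,
    _closest_on_triangles,
    closest_point,
    fit_spline,
    is_inside,
    points_inside,
    ray_first_hit,
    read_mesh,
    vertex_normals,
    winding_numbers,
    write_mesh,
)
from tests.conftest import icosphere

TETRA_PLY = """ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 4
property list uchar int vertex_indices
end_header
1 1 1
1 -1 -1
-1 1 -1
-1 -1 1
3 0 1 2
3 0 3 1
3 0 2 3
3 1 3 2
"""


class TestIO:
    def test_tetrahedron_ply(self, tmp_path):
        p = tmp_path / "tet.ply"
        p.write_text(TETRA_PLY)
        mesh = read_mesh(p)
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 4
        assert mesh.is_watertight()

    @pytest.mark.parametrize("fmt", ["PLY", "OBJ"])
    def test_round_trip_preserves_order_and_coords(self, tmp_path, fmt):
        mesh = icosphere(2, 7.5)
        path = tmp_path / f"s.{fmt.lower()}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert np.array_equal(back.faces, mesh.faces)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)

    def test_stl_round_trip_welds_vertices(self, tmp_path):
        mesh = icosphere(2, 7.5)
        path = tmp_path / "s.stl"
        write_mesh(mesh, path)
        back = read_mesh(path)
        # STL drops shared indexing; welding must restore the vertex count
        assert back.n_vertices == mesh.n_vertices
        assert back.is_watertight()

    def test_out_of_range_face_index_rejected(self, tmp_path):
        bad = TETRA_PLY.replace("3 1 3 2", "3 1 3 99")
        p = tmp_path / "bad.ply"
        p.write_text(bad)
        with pytest.raises(MeshFormatError, match="99"):
            read_mesh(p)

    def test_degenerate_face_rejected(self):
        with pytest.raises(MeshFormatError, match="degenerate"):
            CorrespondedMesh(np.eye(3), np.array([[0, 1, 1]]))

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshFormatError, match="no such file"):
            read_mesh(tmp_path / "nope.ply")


class TestVertexNormals:
    def test_sphere_normals_radial(self):
        mesh = icosphere(3, 10.0)
        n = vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1,
                                                keepdims=True)
        ang = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", n, radial), -1, 1)))
        assert ang.max() < 1.0

    def test_flat_grid_normals_exact(self):
        # open 3x3 grid in the z=0 plane
        xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0))
        verts = np.c_[xs.ravel(), ys.ravel(), np.zeros(9)]
        faces = []
        for i in range(2):
            for j in range(2):
                a = i * 3 + j
                faces += [[a, a + 1, a + 4], [a, a + 4, a + 3]]
        mesh = CorrespondedMesh(verts, np.asarray(faces))
        n = vertex_normals(mesh)
        assert np.allclose(n, [0.0, 0.0, 1.0])

    def test_cube_corner_matches_angle_weighted_accumulation(self):
        box = trimesh.creation.box(extents=(2, 2, 2))
        mesh = CorrespondedMesh(np.asarray(box.vertices), np.asarray(box.faces))
        n = vertex_normals(mesh)
        # brute-force oracle: accumulate angle-weighted face normals
        fn = mesh.face_normals()
        for v in range(mesh.n_vertices):
            acc = np.zeros(3)
            for fi, face in enumerate(mesh.faces):
                if v not in face:
                    continue
                corner = list(face).index(v)
                a = mesh.vertices[face[corner]]
                b = mesh.vertices[face[(corner + 1) % 3]] - a
                c = mesh.vertices[face[(corner + 2) % 3]] - a
                cosang = b @ c / (np.linalg.norm(b) * np.linalg.norm(c))
                acc += fn[fi] * np.arccos(np.clip(cosang, -1, 1))
            acc /= np.linalg.norm(acc)
            assert np.allclose(n[v], acc, atol=1e-12)

    def test_rigid_motion_equivariance(self, rng):
        mesh = icosphere(2, 5.0)
        n0 = vertex_normals(mesh)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = mesh.with_vertices(mesh.vertices @ q.T + np.array([3.0, -1.0, 2.0]))
        n1 = vertex_normals(moved)
        assert np.allclose(n1, n0 @ q.T, atol=1e-9)


class TestClosestPoint:
    def test_matches_brute_force(self, sphere10, rng):
        pts = rng.normal(size=(100, 3)) * 15
        tri = sphere10.triangles
        prox = sphere10.proximity()
        cps, faces, dists = prox.query(pts)
        for i, p in enumerate(pts):
            all_cp = _closest_on_triangles(
                np.broadcast_to(p, (len(tri), 3)).copy(), tri)
            dd = np.linalg.norm(all_cp - p, axis=1)
            j = _argmin_tiebreak(dd, np.arange(len(tri)))
            assert faces[i] == j
            assert abs(dists[i] - dd[j]) < 1e-12

    def test_vertex_query_is_identity(self, sphere10):
        q = sphere10.vertices[17]
        res = closest_point(sphere10, q)
        assert res.distance < 1e-12
        assert np.allclose(res.point, q)

    def test_outside_distance_matches_sphere(self, sphere10):
        res = closest_point(sphere10, [0.0, 0.0, 12.0])
        assert res.distance == pytest.approx(2.0, abs=0.01)  # chordal error
        assert not res.inside


class TestContainment:
    def test_centroid_inside_far_point_outside(self, sphere10):
        assert is_inside(sphere10, [0.0, 0.0, 0.0])
        assert not is_inside(sphere10, [100.0, 0.0, 0.0])

    def test_on_surface_band_counts_as_outside(self, sphere10):
        v = sphere10.vertices[0]
        assert not is_inside(sphere10, v)

    def test_matches_ray_parity_oracle(self, rng):
        mesh = icosphere(2, 5.0)
        pts = rng.uniform(-8, 8, size=(300, 3))
        got = points_inside(mesh, pts)
        tri = mesh.triangles
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]

        def crossings(p, d):
            # plain Moller-Trumbore count of t>0 intersections
            pvec = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, pvec)
            ok = np.abs(det) > 1e-12
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            tvec = p - tri[:, 0]
            u = np.einsum("ij,ij->i", tvec, pvec) * inv
            qvec = np.cross(tvec, e1)
            v = qvec @ d * inv
            t = np.einsum("ij,ij->i", e2, qvec) * inv
            return int(np.count_nonzero(
                ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)))

        # irrational-ish directions avoid edge/vertex grazing
        for d in (np.array([0.912, 0.311, 0.267]),
                  np.array([-0.173, 0.871, 0.459]),
                  np.array([0.403, -0.557, 0.727])):
            d = d / np.linalg.norm(d)
            parity = np.array([crossings(p, d) % 2 == 1 for p in pts])
            _, _, dist = mesh.proximity().query(pts)
            expect = parity & (dist > SURFACE_TOL)
            assert np.array_equal(got, expect)

    def test_open_mesh_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        tri = CorrespondedMesh(verts, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="watertight"):
            is_inside(tri, [0.1, 0.1, 0.5])


class TestRays:
    def test_ray_hits_sphere_at_radius(self, sphere10):
        d = ray_first_hit(sphere10, [[0, 0, 0]], [[0, 0, 1]])
        assert d[0] == pytest.approx(10.0, abs=0.05)

    def test_ray_missing_returns_nan(self, sphere10):
        d = ray_first_hit(sphere10, [[20, 0, 0]], [[1, 0, 0]])
        assert np.isnan(d[0])


class TestSpline:
    def test_two_point_open_is_straight_segment(self):
        sp = fit_spline([[0, 0, 0], [3, 4, 0]])
        assert sp.arc_length() == pytest.approx(5.0, rel=1e-9)
        assert np.allclose(sp(0.0), [0, 0, 0])
        assert np.allclose(sp(1.0), [3, 4, 0])

    def test_closed_circle_circumference(self):
        th = np.linspace(0, 2 * np.pi, 65)[:-1]
        pts = np.c_[5 * np.cos(th), 5 * np.sin(th), np.zeros(64)]
        sp = fit_spline(pts, closed=True)
        assert sp.arc_length() == pytest.approx(10 * np.pi, rel=1e-3)

    def test_open_spline_interpolates_endpoints_exactly(self, rng):
        pts = rng.normal(size=(7, 3))
        sp = fit_spline(pts)
        assert np.array_equal(sp(0.0), pts[0])
        assert np.allclose(sp(1.0), pts[-1], atol=1e-12)

    def test_arc_length_additive_and_monotone(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.0, size=(6, 3)), axis=0)
        sp = fit_spline(pts)
        total = sp.arc_length(0, 1)
        parts = sp.arc_length(0, 0.37) + sp.arc_length(0.37, 1.0)
        assert parts == pytest.approx(total, rel=1e-3)
        ts = np.linspace(0, 1, 20)
        lens = [sp.arc_length(0, t) for t in ts]
        assert np.all(np.diff(lens) > 0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_spline([[0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            fit_spline([[0, 0, 0], [0, 0, 0], [1, 1, 1]])
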