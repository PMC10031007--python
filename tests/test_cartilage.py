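import numpy as np
import pytest

from kneemorph.cartilage import (
    ThicknessMap,
    compute_thickness,
    femoral_length,
    mean_map,
    predict_cartilage,
    region_edges,
    relative_error_map,
    scale_map,
    seal_edges,
)
from kneemorph.landmarks import LandmarkSet
from kneemorph.mesh_core import vertex_normals
from tests.conftest import icosphere


@pytest.fixture(scope="module")
def bone():
    return icosphere(3, 10.0, label="femur")


def cap_region(mesh, max_angle=np.deg2rad(60)):
    """Vertices of the +z spherical cap."""
    d = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    return np.nonzero(np.arccos(np.clip(d[:, 2], -1, 1)) < max_angle)[0]


def smooth_cap_field(mesh, region, amplitude=1.5, max_angle=np.deg2rad(60)):
    """Smooth field, exactly zero on the region's discrete boundary."""
    d = mesh.vertices[region] / np.linalg.norm(mesh.vertices[region],
                                               axis=1, keepdims=True)
    u = np.arccos(np.clip(d[:, 2], -1, 1)) / max_angle
    vals = amplitude * np.cos(np.pi * u / 2) ** 2
    edge = region_edges(mesh, region)
    vals[np.isin(region, edge)] = 0.0
    return vals


class TestComputeThickness:
    def test_concentric_spheres(self, bone):
        cart = bone.with_vertices(bone.vertices * 1.1)  # radius 11
        region = np.arange(bone.n_vertices)
        tmap = compute_thickness(bone, cart, region)
        assert np.allclose(tmap.values, 1.0, atol=1e-3)

    def test_identical_meshes_give_zero(self, bone):
        tmap = compute_thickness(bone, bone, np.arange(bone.n_vertices))
        assert np.all(tmap.values == 0.0)

    def test_construct_then_recover_round_trip(self, bone):
        region = cap_region(bone)
        field = smooth_cap_field(bone, region)
        normals = vertex_normals(bone)
        verts = bone.vertices.copy()
        verts[region] += normals[region] * field[:, None]
        cart = bone.with_vertices(verts)
        tmap = compute_thickness(bone, cart, region)
        interior = ~np.isin(region, tmap.edge_indices)
        assert np.abs(tmap.values - field)[interior].max() < 1e-6

    def test_correspondence_violation_rejected(self, bone):
        other = icosphere(2, 10.0)
        with pytest.raises(ValueError, match="corresponded"):
            compute_thickness(bone, other, [0, 1])

    def test_empty_region_rejected(self, bone):
        with pytest.raises(ValueError, match="region"):
            compute_thickness(bone, bone, np.array([], dtype=int))


class TestSealEdges:
    def test_boundary_zeroed_interior_untouched(self, bone):
        region = cap_region(bone)
        tmap = ThicknessMap("femur", region, np.ones(len(region)),
                            region_edges(bone, region), 1.0)
        sealed = seal_edges(tmap)
        on_edge = np.isin(region, tmap.edge_indices)
        assert np.all(sealed.values[on_edge] == 0.0)
        assert np.all(sealed.values[~on_edge] == 1.0)

    def test_idempotent(self, bone):
        region = cap_region(bone)
        tmap = ThicknessMap("femur", region, np.ones(len(region)),
                            region_edges(bone, region), 1.0)
        once = seal_edges(tmap)
        twice = seal_edges(once)
        assert np.array_equal(once.values, twice.values)

    def test_closed_region_has_no_edges(self, bone):
        region = np.arange(bone.n_vertices)
        assert len(region_edges(bone, region)) == 0
        tmap = ThicknessMap("femur", region, np.ones(len(region)),
                            region_edges(bone, region), 1.0)
        assert np.array_equal(seal_edges(tmap).values, tmap.values)


class TestMeanMap:
    def _map(self, region, values, length):
        return ThicknessMap("femur", region, values, np.array([], dtype=int),
                            length)

    def test_idempotent_on_identical_inputs(self, bone):
        region = cap_region(bone)
        m = self._map(region, np.linspace(0, 2, len(region)), 400.0)
        out = mean_map([m, m, m])
        assert np.allclose(out.values, m.values)
        assert out.reference_length == 400.0

    def test_two_case_mean(self, bone, rng):
        region = cap_region(bone)
        a = rng.uniform(0, 2, len(region))
        b = rng.uniform(0, 2, len(region))
        out = mean_map([self._map(region, a, 400.0),
                        self._map(region, b, 400.0)])
        assert np.allclose(out.values, (a + b) / 2)

    def test_proportional_cohort_normalizes_exactly(self, bone, rng):
        region = cap_region(bone)
        base = rng.uniform(0.5, 2.0, len(region))
        lengths = [400.0, 440.0, 420.0]
        maps = [self._map(region, base * (L / 420.0), L) for L in lengths]
        out = mean_map(maps)
        assert out.reference_length == pytest.approx(420.0)
        assert np.allclose(out.values, base, atol=1e-9)

    def test_permutation_invariant(self, bone, rng):
        region = cap_region(bone)
        maps = [self._map(region, rng.uniform(0, 2, len(region)),
                          400 + 10 * i) for i in range(4)]
        a = mean_map(maps)
        b = mean_map(maps[::-1])
        assert np.allclose(a.values, b.values)

    def test_mixed_regions_rejected(self, bone):
        r1 = cap_region(bone)
        with pytest.raises(ValueError):
            mean_map([self._map(r1, np.ones(len(r1)), 400.0),
                      self._map(r1[:-1], np.ones(len(r1) - 1), 400.0)])


class TestFemoralLength:
    def _landmarks(self):
        return LandmarkSet(entries={
            "femur_length_proximal": {"bone": "femur", "indices": [0]},
            "femur_length_distal": {"bone": "femur", "indices": [1]},
        })

    def test_known_separation(self, bone):
        lm = self._landmarks()
        expect = np.linalg.norm(bone.vertices[0] - bone.vertices[1])
        assert femoral_length(bone, lm) == pytest.approx(expect)

    def test_rigid_invariance_and_homogeneity(self, bone, rng):
        lm = self._landmarks()
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = bone.with_vertices(bone.vertices @ q.T + 5.0)
        assert femoral_length(rotated, lm) == pytest.approx(
            femoral_length(bone, lm))
        scaled = bone.with_vertices(bone.vertices * 1.1)
        assert femoral_length(scaled, lm) == pytest.approx(
            femoral_length(bone, lm) * 1.1)

    def test_missing_landmark(self, bone):
        with pytest.raises(KeyError):
            femoral_length(bone, LandmarkSet(entries={}))


class TestPredictCartilage:
    def test_constant_map_inflates_sphere(self, bone):
        region = np.arange(bone.n_vertices)
        tmap = ThicknessMap("femur", region, np.ones(len(region)),
                            np.array([], dtype=int), 100.0)
        out = predict_cartilage(bone, tmap)
        assert np.allclose(np.linalg.norm(out.vertices, axis=1), 11.0,
                           atol=1e-9)

    def test_target_length_scales_displacement(self, bone):
        region = np.arange(bone.n_vertices)
        tmap = ThicknessMap("femur", region, np.ones(len(region)),
                            np.array([], dtype=int), 100.0)
        out = predict_cartilage(bone, tmap, target_length=110.0)
        assert np.allclose(np.linalg.norm(out.vertices, axis=1), 11.1,
                           atol=1e-9)

    def test_round_trip_recovers_scaled_map(self, bone):
        region = cap_region(bone)
        field = smooth_cap_field(bone, region)
        tmap = ThicknessMap("femur", region, field,
                            region_edges(bone, region), 100.0)
        cart = predict_cartilage(bone, tmap, target_length=110.0)
        back = compute_thickness(bone, cart, region, reference_length=110.0)
        interior = ~np.isin(region, tmap.edge_indices)
        assert np.abs(back.values - field * 1.1)[interior].max() < 1e-6

    def test_never_moves_inward(self, bone, rng):
        region = cap_region(bone)
        vals = rng.uniform(0, 2, len(region))
        tmap = ThicknessMap("femur", region, vals, np.array([], dtype=int),
                            100.0)
        out = predict_cartilage(bone, tmap)
        assert np.all(np.linalg.norm(out.vertices, axis=1)
                      >= np.linalg.norm(bone.vertices, axis=1) - 1e-12)


class TestRelativeErrorMap:
    def test_ratio_and_floor(self, bone):
        region = cap_region(bone)[:4]
        tmap = ThicknessMap("femur", region, np.array([1.0, 2.0, 0.0, 0.01]),
                            np.array([], dtype=int), 100.0)
        out = relative_error_map(np.array([0.5, 0.5, 0.5, 0.5]), tmap)
        assert out[0] == pytest.approx(0.5)
        assert out[1] == pytest.approx(0.25)
        assert np.isnan(out[2]) and np.isnan(out[3])

    def test_zero_error(self, bone):
        region = cap_region(bone)[:3]
        tmap = ThicknessMap("femur", region, np.ones(3),
                            np.array([], dtype=int), 100.0)
        out = relative_error_map(np.zeros(3), tmap)
        assert np.all(out == 0.0)


def test_map_csv_round_trip(tmp_path, bone):
    region = cap_region(bone)
    field = smooth_cap_field(bone, region)
    tmap = ThicknessMap("femur", region, field, region_edges(bone, region),
                        431.5, region_name="femoral")
    tmap.save(tmp_path / "m.csv")
    back = ThicknessMap.load(tmp_path / "m.csv")
    assert back.same_region(tmap)
    assert np.array_equal(back.values, tmap.values)
    assert back.reference_length == tmap.reference_length
    assert np.array_equal(back.edge_indices, tmap.edge_indices)


def test_scale_map_round_trip(bone):
    region = cap_region(bone)
    tmap = ThicknessMap("femur", region, np.ones(len(region)),
                        np.array([], dtype=int), 400.0)
    back = scale_map(scale_map(tmap, 440.0), 400.0)
    assert np.allclose(back.values, tmap.values)
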