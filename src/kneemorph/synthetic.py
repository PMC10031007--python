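"""Deterministic synthetic knee cohorts for end-to-end testing.

Real corresponded MRI cohorts cannot be redistributed, so this module
generates geometric stand-ins that exercise every pipeline stage with known
ground truth: a distal-femur analog (a sphere with two condylar lobes), a
tibial-plateau analog (a flattened ellipsoid with shallow articular dips),
and a patella analog (a lens), all produced by displacing one icosphere
template so vertex correspondence across cases is exact by construction.
Cartilage meshes are the bone meshes displaced outward along vertex normals
by a prescribed smooth thickness field (zero at the region boundary) that
scales linearly with the case's femoral length, plus optional i.i.d.
per-vertex noise.  Landmarks for every modeled attachment are fixed
template vertices; meniscal and cruciate profiles are sampled from known
truth polynomials.  Everything is reproducible from the spec's seed.

The analog joint lives in a right-handed frame with +x lateral, +y
anterior, +z superior, at true anatomical scale (condyle radius ~25 mm,
cartilage ~2 mm) so geometric tolerances carry over to real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from kneemorph.cartilage import ThicknessMap, region_edges
from kneemorph.landmarks import LandmarkSet
from kneemorph.mesh_core import CorrespondedMesh, vertex_normals
from kneemorph.profiles import ProfileSamples

#: below this base thickness (mm) no measurement noise is added — sub-half-
#: millimetre cartilage is below imaging measurement resolution, and keeping
#: the taper band noise-free avoids clipping thickness at zero.
NOISE_FLOOR_MM = 0.5


@dataclass
class SyntheticCohortSpec:
    """Conditions of a synthetic cohort.

    ``femur_length_range`` is the per-case distance between the two femoral
    length landmarks of the analog (the template measures ~50 mm, so the
    default range spans roughly +/-8% size variation, comparable to adult
    femoral-length spread); ``thickness_amplitude`` is the plateau cartilage
    thickness of the truth field; ``thickness_sigma`` the i.i.d. per-vertex
    measurement noise; ``subdivision`` the icosphere refinement of the
    templates (femur, tibia, patella).
    """

    n_cases: int = 10
    seed: int = 0
    femur_length_range: tuple = (46.0, 54.0)
    thickness_amplitude: float = 2.0
    thickness_sigma: float = 0.05
    profile_noise_frac: float = 0.01
    subdivision: tuple = (4, 4, 3)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.thickness_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if min(self.subdivision) < 1 or max(self.subdivision) > 5:
            raise ValueError("subdivision levels must be in [1, 5]")


@dataclass
class SyntheticCase:
    """One synthetic subject: bones, cartilage, ground truth."""

    case_id: str
    bones: dict
    cartilage: dict
    thickness_truth: dict           # region name -> ThicknessMap (with noise)
    noise_mask: dict                # region name -> bool array over region
    femur_length: float
    scale: float


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    cases: list
    landmarks: LandmarkSet
    regions: dict                   # region name -> (bone label, vertex indices)
    profile_truth: dict             # structure label -> PolynomialProfile coeffs
    profile_samples: dict           # structure label -> ProfileSamples
    mean_femur_length: float


# ---------------------------------------------------------------------------
# Analog bone templates
# ---------------------------------------------------------------------------

def _unit_sphere(subdiv: int):
    s = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    return np.asarray(s.vertices, dtype=float), np.asarray(s.faces, dtype=np.int64)


def _femur_template(subdiv: int) -> CorrespondedMesh:
    """Distal femur analog: sphere of radius 25 with two condylar lobes
    bulging infero-laterally / infero-medially, centered at z = +22."""
    v, f = _unit_sphere(subdiv)
    lobes = [np.array([0.445, -0.099, -0.889]), np.array([-0.445, -0.099, -0.889])]
    r = np.full(len(v), 25.0)
    for d in lobes:
        ang = np.arccos(np.clip(v @ d, -1, 1))
        r += 25.0 * 0.18 * np.exp(-((ang / 0.45) ** 2))
    verts = v * r[:, None] + np.array([0.0, 0.0, 24.0])
    return CorrespondedMesh(verts, f, bone_label="femur")


def _tibia_template(subdiv: int) -> CorrespondedMesh:
    """Proximal tibia analog: flattened ellipsoid (32 x 24 x 14 mm
    semi-axes) with two shallow concave articular dips on the plateau,
    centered at z = -23."""
    v, f = _unit_sphere(subdiv)
    verts = v * np.array([32.0, 24.0, 14.0])
    dips = [np.array([0.5, 0.0, 0.866]), np.array([-0.5, 0.0, 0.866])]
    for d in dips:
        ang = np.arccos(np.clip(v @ d, -1, 1))
        verts -= (v * 1.2 * np.exp(-((ang / 0.45) ** 2))[:, None])
    return CorrespondedMesh(verts + np.array([0.0, 0.0, -23.0]), f,
                            bone_label="tibia_fibula")


def _patella_template(subdiv: int) -> CorrespondedMesh:
    """Patella analog: lens solid (11 x 5 x 13 mm semi-axes) anterior to
    the femur."""
    v, f = _unit_sphere(subdiv)
    verts = v * np.array([11.0, 5.0, 13.0]) + np.array([0.0, 36.0, 5.0])
    return CorrespondedMesh(verts, f, bone_label="patella")


def _cap_region(template: CorrespondedMesh, center: np.ndarray,
                axis: np.ndarray, max_angle: float) -> np.ndarray:
    """Vertex indices within an angular cap about ``axis`` seen from
    ``center`` (the articular-surface analog)."""
    d = template.vertices - center
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    ang = np.arccos(np.clip(d @ (axis / np.linalg.norm(axis)), -1, 1))
    return np.nonzero(ang < max_angle)[0]


def _cap_field(template: CorrespondedMesh, region: np.ndarray,
               center: np.ndarray, axis: np.ndarray, max_angle: float,
               amplitude: float, taper: float = 0.35) -> np.ndarray:
    """Smooth thickness field over a cap region: a flat plateau of
    ``amplitude`` with a smoothstep taper to exactly zero at the cap
    boundary (outermost ``taper`` fraction of the angular extent)."""
    d = template.vertices[region] - center
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    ang = np.arccos(np.clip(d @ (axis / np.linalg.norm(axis)), -1, 1))
    u = ang / max_angle
    x = np.clip((1.0 - u) / taper, 0.0, 1.0)
    vals = amplitude * (3 * x**2 - 2 * x**3)
    # force exact zero on the discrete region boundary
    edge = region_edges(template, region)
    edge_pos = np.isin(region, edge)
    vals[edge_pos] = 0.0
    return vals


# ---------------------------------------------------------------------------
# Landmark table (template anchor points, patch sizes)
# ---------------------------------------------------------------------------

# name -> (bone, anchor point in template frame, n nearest vertices)
_LANDMARK_TABLE = {
    "femur_length_proximal": ("femur", (0.0, 0.0, 60.0), 1),
    "femur_length_distal": ("femur", (0.0, 0.0, -20.0), 1),
    "LCL_origin": ("femur", (27.0, 0.0, 22.0), 5),
    "LCL_insertion": ("tibia_fibula", (31.0, 0.0, -26.0), 5),
    "sMCL_ant_origin": ("femur", (-27.0, 4.0, 22.0), 5),
    "sMCL_ant_insertion": ("tibia_fibula", (-30.0, 6.0, -28.0), 5),
    "sMCL_post_origin": ("femur", (-27.0, -4.0, 22.0), 5),
    "sMCL_post_insertion": ("tibia_fibula", (-30.0, -4.0, -28.0), 5),
    "MPFL_origin": ("femur", (-26.0, 10.0, 26.0), 5),
    "MPFL_insertion": ("patella", (-11.0, 36.0, 8.0), 5),
    "LPFL_origin": ("femur", (26.0, 10.0, 26.0), 5),
    "LPFL_insertion": ("patella", (11.0, 36.0, 8.0), 5),
    "ALL_origin": ("femur", (26.0, 6.0, 18.0), 5),
    "ALL_insertion": ("tibia_fibula", (24.0, 16.0, -24.0), 5),
    "POL_origin": ("femur", (-25.0, -10.0, 20.0), 5),
    "POL_insertion": ("tibia_fibula", (-22.0, -14.0, -26.0), 5),
    "OPL_origin": ("femur", (14.0, -20.0, 24.0), 5),
    "OPL_insertion": ("tibia_fibula", (-16.0, -18.0, -27.0), 5),
    "PT_origin": ("patella", (0.0, 38.0, -7.0), 12),
    "PT_insertion": ("tibia_fibula", (0.0, 24.0, -16.0), 12),
    "ACL_origin": ("femur", (6.0, -6.0, -2.0), 3),
    "ACL_insertion": ("tibia_fibula", (3.0, 10.0, -10.0), 3),
    "PCL_origin": ("femur", (-6.0, -6.0, -2.0), 3),
    "PCL_insertion": ("tibia_fibula", (-1.0, -16.0, -11.0), 3),
    "MM_anterior_root": ("tibia_fibula", (-9.0, 16.0, -10.0), 3),
    "MM_posterior_root": ("tibia_fibula", (-11.0, -15.0, -10.0), 3),
    "LM_anterior_root": ("tibia_fibula", (9.0, 16.0, -10.0), 3),
    "LM_posterior_root": ("tibia_fibula", (11.0, -15.0, -10.0), 3),
}


def _template_landmarks(templates: dict) -> LandmarkSet:
    entries = {}
    for name, (bone, anchor, k) in _LANDMARK_TABLE.items():
        verts = templates[bone].vertices
        d = np.linalg.norm(verts - np.asarray(anchor, dtype=float), axis=1)
        idx = np.argsort(d, kind="stable")[:k]
        entries[name] = {"bone": bone, "indices": sorted(int(i) for i in idx)}
    return LandmarkSet(entries=entries, provenance="manual")


# ---------------------------------------------------------------------------
# Truth profiles
# ---------------------------------------------------------------------------

#: geometry-truth polynomials (ascending power-basis coefficients, mm) used
#: to *build* synthetic structures: meniscal wedges taller and wider at
#: mid-body, cruciates thickest at mid-substance.
GEOMETRY_TRUTH = {
    "MM_height": np.array([4.0, 8.0, -8.0]),
    "MM_width": np.array([6.0, 10.0, -10.0]),
    "LM_height": np.array([4.0, 6.0, -6.0]),
    "LM_width": np.array([6.0, 8.0, -8.0]),
    "ACL_radius": np.array([3.0, 4.0, -4.0]),
    "PCL_radius": np.array([3.5, 4.0, -4.0]),
}


def make_profile_samples(degree: int, n_samples: int = 50,
                         noise_frac: float = 0.01,
                         rng: np.random.Generator | None = None,
                         mean_value: float = 8.0,
                         scale: float = 2.0,
                         structure_label: str = "") -> tuple:
    """Noisy samples from a random polynomial with a known true degree.

    The truth is built in the orthonormal shifted-Legendre basis with the
    per-degree RMS amplitudes declining linearly, so every degree up to
    ``degree`` carries a substantial, detectable share of the variance
    (a polynomial whose top-degree term is negligible has no recoverable
    degree).  Sample positions are equispaced, like slice-wise
    measurements; noise is i.i.d. Gaussian with sd ``noise_frac`` times the
    value range.  Returns (samples, truth_coefficients).
    """
    rng = rng or np.random.default_rng(0)
    coeffs = np.zeros(degree + 1)
    coeffs[0] = mean_value
    if degree > 0:
        # residual rms after fitting degree d declines linearly to 10%
        r = scale * (1.0 - 0.9 * np.arange(degree + 1) / degree)
        amp2 = r[:-1] ** 2 - r[1:] ** 2
        signs = rng.choice([-1.0, 1.0], size=degree)
        for k in range(1, degree + 1):
            b = signs[k - 1] * np.sqrt(amp2[k - 1])
            leg = np.polynomial.legendre.Legendre.basis(k, domain=[0.0, 1.0])
            pk = leg.convert(kind=np.polynomial.polynomial.Polynomial)
            coeffs[: k + 1] += b * np.sqrt(2 * k + 1) * pk.coef
    # keep values positive on a dense grid
    dense = np.polynomial.polynomial.polyval(np.linspace(0, 1, 512), coeffs)
    if dense.min() < 0.3:
        coeffs[0] += 0.3 - dense.min()
        dense += 0.3 - dense.min()
    s = np.linspace(0.0, 1.0, n_samples)
    vals = np.polynomial.polynomial.polyval(s, coeffs)
    sigma = noise_frac * (dense.max() - dense.min() + 1e-12)
    vals = np.maximum(vals + rng.normal(0.0, sigma, n_samples), 0.0)
    return ProfileSamples(s, vals, structure_label), coeffs


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a corresponded synthetic cohort with known ground truth.

    Each case is the common template uniformly scaled to its drawn femoral
    length, with cartilage displaced by the scaled truth thickness field
    plus per-vertex noise.  One pseudorandom stream is derived per case
    from (seed, case index), so extending ``n_cases`` never perturbs
    earlier cases.
    """
    sub_f, sub_t, sub_p = spec.subdivision
    templates = {
        "femur": _femur_template(sub_f),
        "tibia_fibula": _tibia_template(sub_t),
        "patella": _patella_template(sub_p),
    }
    landmarks = _template_landmarks(templates)

    femur = templates["femur"]
    regions = {
        "femoral": ("femur",
                    _cap_region(femur, np.array([0.0, 0.0, 22.0]),
                                np.array([0.0, 0.0, -1.0]), np.deg2rad(70))),
        "tibial_medial": ("tibia_fibula",
                          _cap_region(templates["tibia_fibula"],
                                      np.array([0.0, 0.0, -23.0]),
                                      np.array([-0.5, 0.0, 0.866]),
                                      np.deg2rad(28))),
        "tibial_lateral": ("tibia_fibula",
                           _cap_region(templates["tibia_fibula"],
                                       np.array([0.0, 0.0, -23.0]),
                                       np.array([0.5, 0.0, 0.866]),
                                       np.deg2rad(28))),
        "patellar": ("patella",
                     _cap_region(templates["patella"],
                                 np.array([0.0, 36.0, 5.0]),
                                 np.array([0.0, -1.0, 0.0]), np.deg2rad(55))),
    }
    base_fields = {
        "femoral": _cap_field(femur, regions["femoral"][1],
                              np.array([0.0, 0.0, 22.0]),
                              np.array([0.0, 0.0, -1.0]), np.deg2rad(70),
                              spec.thickness_amplitude),
        "tibial_medial": _cap_field(templates["tibia_fibula"],
                                    regions["tibial_medial"][1],
                                    np.array([0.0, 0.0, -23.0]),
                                    np.array([-0.5, 0.0, 0.866]),
                                    np.deg2rad(28),
                                    spec.thickness_amplitude),
        "tibial_lateral": _cap_field(templates["tibia_fibula"],
                                     regions["tibial_lateral"][1],
                                     np.array([0.0, 0.0, -23.0]),
                                     np.array([0.5, 0.0, 0.866]),
                                     np.deg2rad(28),
                                     spec.thickness_amplitude),
        "patellar": _cap_field(templates["patella"], regions["patellar"][1],
                               np.array([0.0, 36.0, 5.0]),
                               np.array([0.0, -1.0, 0.0]), np.deg2rad(55),
                               spec.thickness_amplitude * 0.9),
    }

    # femoral length of the template
    a = femur.vertices[landmarks.indices("femur_length_proximal")].mean(axis=0)
    b = femur.vertices[landmarks.indices("femur_length_distal")].mean(axis=0)
    base_length = float(np.linalg.norm(a - b))
    lo, hi = spec.femur_length_range
    lengths = [lo + (hi - lo) * float(np.random.default_rng([spec.seed, i]).uniform())
               for i in range(spec.n_cases)]
    mean_length = float(np.mean(lengths))

    normals = {name: vertex_normals(m) for name, m in templates.items()}
    cases = []
    for i in range(spec.n_cases):
        rng = np.random.default_rng([spec.seed, i, 7919])
        length = lengths[i]
        scale = length / base_length
        bones = {name: m.with_vertices(m.vertices * scale)
                 for name, m in templates.items()}
        for name, m in bones.items():
            m.case_id = f"case{i:03d}"
        cartilage = {}
        truth = {}
        masks = {}
        for rname, (bone_label, region) in regions.items():
            base = base_fields[rname] * scale
            mask = base > NOISE_FLOOR_MM
            noise = np.where(mask, rng.normal(0.0, spec.thickness_sigma,
                                              len(region)), 0.0)
            vals = np.maximum(base + noise, 0.0)
            bone = bones[bone_label]
            verts = bone.vertices.copy()
            verts[region] += normals[bone_label][region] * vals[:, None]
            cart = bone.with_vertices(verts)
            cart.case_id = f"case{i:03d}"
            cartilage[rname] = cart
            truth[rname] = ThicknessMap(
                bone_label, region, vals,
                region_edges(bone, region), length, region_name=rname,
            )
            masks[rname] = mask
        cases.append(SyntheticCase(
            case_id=f"case{i:03d}", bones=bones, cartilage=cartilage,
            thickness_truth=truth, noise_mask=masks,
            femur_length=length, scale=scale,
        ))

    # pooled profile measurement samples from the geometry truth
    rng = np.random.default_rng([spec.seed, 104729])
    profile_samples = {}
    for label, coeffs in GEOMETRY_TRUTH.items():
        s = np.sort(rng.uniform(0, 1, 60))
        s[0], s[-1] = 0.0, 1.0
        vals = np.polynomial.polynomial.polyval(s, coeffs)
        sigma = spec.profile_noise_frac * (vals.max() - vals.min() + 1e-12)
        vals = np.maximum(vals + rng.normal(0, sigma, len(s)), 0.0)
        profile_samples[label] = ProfileSamples(s, vals, label)

    return SyntheticCohort(
        spec=spec, cases=cases, landmarks=landmarks, regions=regions,
        profile_truth={k: v.copy() for k, v in GEOMETRY_TRUTH.items()},
        profile_samples=profile_samples, mean_femur_length=mean_length,
    )


# ---------------------------------------------------------------------------
# Wrap benchmarks
# ---------------------------------------------------------------------------

def generate_wrap_benchmarks(seed: int = 0) -> list[dict]:
    """Obstacle/anchor suites with reference path lengths for the wrap
    engine: free space (straight-line reference), spheres (great-circle
    closed form), and a condyle-analog surface (graph-geodesic reference,
    an upper bound good to a few percent)."""
    import networkx as nx

    from kneemorph.wrap_engine import ObstacleSet

    rng = np.random.default_rng(seed)
    suites = []

    # free space
    a = rng.normal(size=3) * 10
    b = a + np.array([30.0, 0.0, 0.0])
    suites.append({
        "name": "free_space",
        "obstacles": ObstacleSet([]),
        "start": a, "end": b,
        "reference_length": float(np.linalg.norm(b - a)),
        "kind": "exact",
    })

    # spheres: anchors on the surface separated by a central angle
    for R, theta in ((10.0, np.pi / 2), (10.0, 2 * np.pi / 3), (25.0, np.pi / 2)):
        v, f = _unit_sphere(4)
        sphere = CorrespondedMesh(v * R, f, bone_label="other")
        p = np.array([R, 0.0, 0.0])
        q = np.array([R * np.cos(theta), R * np.sin(theta), 0.0])
        suites.append({
            "name": f"sphere_R{R:g}_theta{theta:.3f}",
            "obstacles": ObstacleSet([sphere]),
            "start": p, "end": q,
            "reference_length": float(R * theta),
            "kind": "closed_form",
        })

    # condyle analog: graph geodesic over the surface between two
    # surface points forced to wrap over the lobes
    femur = _femur_template(3)
    start = femur.vertices[int(np.argmin(femur.vertices[:, 1]
                                         - 0.5 * femur.vertices[:, 2]))]
    end = femur.vertices[int(np.argmax(femur.vertices[:, 1]
                                       - 0.5 * femur.vertices[:, 2]))]
    g = nx.Graph()
    edges = np.vstack([femur.faces[:, [0, 1]], femur.faces[:, [1, 2]],
                       femur.faces[:, [2, 0]]])
    for u, vtx in edges:
        w = float(np.linalg.norm(femur.vertices[u] - femur.vertices[vtx]))
        g.add_edge(int(u), int(vtx), weight=w)
    si = int(np.argmin(np.linalg.norm(femur.vertices - start, axis=1)))
    ei = int(np.argmin(np.linalg.norm(femur.vertices - end, axis=1)))
    ref = nx.shortest_path_length(g, si, ei, weight="weight")
    suites.append({
        "name": "condyle_analog",
        "obstacles": ObstacleSet([femur]),
        "start": start, "end": end,
        "reference_length": float(ref),
        "kind": "graph_upper_bound",
    })
    return suites


# ---------------------------------------------------------------------------
# Cohort persistence (PLY meshes + CSV/JSON sidecars)
# ---------------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort to a directory in the same open formats every other
    stage consumes: PLY meshes (vertex order preserved), thickness-map CSVs
    with JSON sidecars, landmark JSON and profile-sample CSVs."""
    import json
    from pathlib import Path

    from kneemorph.mesh_core import write_mesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    meta = {
        "n_cases": spec.n_cases,
        "seed": spec.seed,
        "femur_length_range": list(spec.femur_length_range),
        "thickness_amplitude": spec.thickness_amplitude,
        "thickness_sigma": spec.thickness_sigma,
        "profile_noise_frac": spec.profile_noise_frac,
        "subdivision": list(spec.subdivision),
        "mean_femur_length": cohort.mean_femur_length,
        "case_ids": [c.case_id for c in cohort.cases],
        "regions": {r: {"bone": b, "indices": [int(i) for i in idx]}
                    for r, (b, idx) in cohort.regions.items()},
        "profile_truth": {k: [float(x) for x in v]
                          for k, v in cohort.profile_truth.items()},
        "femur_lengths": [c.femur_length for c in cohort.cases],
        "scales": [c.scale for c in cohort.cases],
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=1))
    cohort.landmarks.to_json(out / "landmarks.json")
    for label, samples in cohort.profile_samples.items():
        samples.to_csv(out / f"profile_{label}.csv")
    for case in cohort.cases:
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        for bone, mesh in case.bones.items():
            write_mesh(mesh, cdir / f"bone_{bone}.ply")
        for rname, mesh in case.cartilage.items():
            write_mesh(mesh, cdir / f"cartilage_{rname}.ply")
        for rname, tmap in case.thickness_truth.items():
            tmap.save(cdir / f"thickness_{rname}.csv")
        json_masks = {r: [bool(x) for x in m]
                      for r, m in case.noise_mask.items()}
        (cdir / "noise_mask.json").write_text(json.dumps(json_masks))


def load_cohort(in_dir) -> SyntheticCohort:
    """Load a cohort saved by :func:`save_cohort`."""
    import json
    from pathlib import Path

    from kneemorph.mesh_core import read_mesh

    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    spec = SyntheticCohortSpec(
        n_cases=meta["n_cases"], seed=meta["seed"],
        femur_length_range=tuple(meta["femur_length_range"]),
        thickness_amplitude=meta["thickness_amplitude"],
        thickness_sigma=meta["thickness_sigma"],
        profile_noise_frac=meta["profile_noise_frac"],
        subdivision=tuple(meta["subdivision"]),
    )
    regions = {r: (d["bone"], np.asarray(d["indices"], dtype=np.int64))
               for r, d in meta["regions"].items()}
    landmarks = LandmarkSet.from_json(src / "landmarks.json")
    profile_samples = {}
    for label in meta["profile_truth"]:
        profile_samples[label] = ProfileSamples.from_csv(
            src / f"profile_{label}.csv", structure_label=label)
    cases = []
    for case_id, length, scale in zip(meta["case_ids"], meta["femur_lengths"],
                                      meta["scales"]):
        cdir = src / case_id
        bones = {}
        for bone in ("femur", "tibia_fibula", "patella"):
            bones[bone] = read_mesh(cdir / f"bone_{bone}.ply",
                                    bone_label=bone, case_id=case_id)
        cartilage = {}
        truth = {}
        for rname, (bone_label, _idx) in regions.items():
            cart = read_mesh(cdir / f"cartilage_{rname}.ply",
                             bone_label=bone_label, case_id=case_id)
            cartilage[rname] = cart
            truth[rname] = ThicknessMap.load(cdir / f"thickness_{rname}.csv")
        masks = {r: np.asarray(m, dtype=bool) for r, m in json.loads(
            (cdir / "noise_mask.json").read_text()).items()}
        cases.append(SyntheticCase(
            case_id=case_id, bones=bones, cartilage=cartilage,
            thickness_truth=truth, noise_mask=masks,
            femur_length=length, scale=scale,
        ))
    return SyntheticCohort(
        spec=spec, cases=cases, landmarks=landmarks, regions=regions,
        profile_truth={k: np.asarray(v) for k, v in meta["profile_truth"].items()},
        profile_samples=profile_samples,
        mean_femur_length=meta["mean_femur_length"],
    )
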