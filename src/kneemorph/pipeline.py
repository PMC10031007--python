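"""End-to-end model assembly and leave-one-out validation drivers.

``build_case_model`` turns one case's corresponded bone meshes plus the
cohort-derived mean thickness maps, landmark template and profile fits into
a complete knee soft-tissue model, in dependency order: cartilage layers
first, then the menisci, then the ligament bands and patellar tendon, then
the ACL and finally the PCL — each stage's output joins the obstacle set of
the stages after it (ACL before PCL, so the PCL wraps around the ACL tube).

``run_validation`` performs leave-one-out experiments over a cohort and
pools per-case RMSE / ASD / HD as median with (min-max) range.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import yaml

from kneemorph.cartilage import (
    ThicknessMap,
    compute_thickness,
    femoral_length,
    mean_map,
    predict_cartilage,
    scale_map,
)
from kneemorph.cruciate import predict_cruciate
from kneemorph.landmarks import transfer_point
from kneemorph.ligament import (
    default_ligament_table,
    predict_ligament,
    predict_patellar_tendon,
)
from kneemorph.meniscus import build_meniscus
from kneemorph.mesh_core import CorrespondedMesh, best_fit_plane, write_mesh
from kneemorph.profiles import DEFAULT_DEGREES, PolynomialProfile, fit_polynomial
from kneemorph.validation import compare_thickness_maps, leave_one_out
from kneemorph.wrap_engine import ObstacleSet, RelaxParams

_CONFIG_KEYS = {
    "cohort_dir", "case_id", "output_dir", "seed",
    "relaxation", "n_meniscus_nodes", "ligament_rows", "ligament_cols",
    "cruciate_segments",
}
_RELAX_KEYS = {"omega", "tol", "max_iter", "coarse_to_fine", "penetration_tol"}


@dataclass
class PipelineConfig:
    """Validated configuration of a full-model build."""

    cohort_dir: str
    output_dir: str
    case_id: str = ""
    seed: int = 0
    relaxation: dict = dataclass_field(default_factory=dict)
    n_meniscus_nodes: int = 60
    ligament_rows: int = 30
    ligament_cols: int = 20
    cruciate_segments: int = 15

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad_relax = set(data.get("relaxation", {})) - _RELAX_KEYS
        if bad_relax:
            raise ValueError(f"unknown relaxation keys: {sorted(bad_relax)}")
        return cls(**data)

    def relax_params(self) -> RelaxParams:
        return RelaxParams(**self.relaxation)


# ---------------------------------------------------------------------------
# Cohort-level model building blocks
# ---------------------------------------------------------------------------

def fit_default_profiles(profile_samples: dict) -> dict:
    """Fit each structure's samples at its default polynomial degree."""
    out = {}
    for label, samples in profile_samples.items():
        out[label] = fit_polynomial(samples, DEFAULT_DEGREES[label])
    return out


def build_mean_maps(cases: list, regions: dict) -> dict:
    """Cohort mean thickness map per region from the cases' maps."""
    return {
        rname: mean_map([c.thickness_truth[rname] for c in cases])
        for rname in regions
    }


def measure_case_maps(case, regions: dict) -> dict:
    """Re-measure each region's thickness map from the case's meshes by
    normal ray casting (rather than trusting stored ground truth)."""
    out = {}
    for rname, (bone_label, region) in regions.items():
        out[rname] = compute_thickness(
            case.bones[bone_label], case.cartilage[rname], region,
            reference_length=case.femur_length, region_name=rname,
        )
    return out


@dataclass
class KneeModel:
    """A complete predicted knee soft-tissue model for one case."""

    case_id: str
    bones: dict
    cartilage: dict                 # region name -> predicted CorrespondedMesh
    menisci: dict                   # side -> MeniscusModel
    ligaments: dict                 # name -> LigamentMesh
    cruciates: dict                 # name -> CruciateModel
    build_order: list

    def meshes(self) -> dict:
        """All output meshes keyed by stage/name."""
        out = {f"bone_{k}": v for k, v in self.bones.items()}
        out.update({f"cartilage_{k}": v for k, v in self.cartilage.items()})
        out.update({f"meniscus_{k}": v.surface for k, v in self.menisci.items()})
        out.update({f"ligament_{k}": v.solid for k, v in self.ligaments.items()})
        out.update({f"cruciate_{k}": v.tube.surface for k, v in self.cruciates.items()})
        return out


def _composite_obstacles(cartilage_meshes: dict) -> ObstacleSet:
    """Watertight bone+cartilage composites: each predicted cartilage mesh
    is the bone mesh with the articular region displaced outward, so it
    already encloses the bone and serves directly as the composite."""
    seen = {}
    for mesh in cartilage_meshes.values():
        key = mesh.bone_label
        if key in seen:
            # several regions on one bone: merge displacements vertex-wise
            seen[key] = _merge_displaced(seen[key], mesh)
        else:
            seen[key] = mesh
    return ObstacleSet(list(seen.values()))


def _merge_displaced(a: CorrespondedMesh, b: CorrespondedMesh) -> CorrespondedMesh:
    """Merge two displaced copies of the same bone: per vertex, keep the
    position farther from the shared base (regions are disjoint, so at most
    one of the two moved any given vertex)."""
    # regions are disjoint, so where the copies disagree exactly one of them
    # was displaced — and displacement is always outward along the normal
    centroid = a.vertices.mean(axis=0)
    ra = np.linalg.norm(a.vertices - centroid, axis=1)
    rb = np.linalg.norm(b.vertices - centroid, axis=1)
    verts = np.where((rb > ra)[:, None], b.vertices, a.vertices)
    return a.with_vertices(verts)


def build_case_model(case, landmarks, regions: dict, mean_maps: dict,
                     profiles: dict, config: PipelineConfig | None = None,
                     log: list | None = None) -> KneeModel:
    """Assemble the full soft-tissue model for one case.

    ``mean_maps`` are cohort mean thickness maps (built without this case
    for honest validation); ``profiles`` maps structure labels to fitted
    polynomial profiles; ``landmarks`` is the shared template landmark set.
    """
    config = config or PipelineConfig(cohort_dir="", output_dir="")
    params = config.relax_params()
    log = log if log is not None else []
    build_order = []

    def stage(name):
        build_order.append(name)
        log.append(f"stage: {name}")

    # --- cartilage ---------------------------------------------------------
    stage("cartilage")
    length = femoral_length(case.bones["femur"], landmarks)
    cartilage = {}
    for rname, (bone_label, _region) in regions.items():
        cartilage[rname] = predict_cartilage(
            case.bones[bone_label], mean_maps[rname], target_length=length)
        cartilage[rname].case_id = case.case_id
    obstacles = _composite_obstacles(cartilage)

    tibia_cart = [m for m in obstacles.surfaces if m.bone_label == "tibia_fibula"][0]
    plateau_idx = np.unique(np.concatenate(
        [regions[r][1] for r in regions if regions[r][0] == "tibia_fibula"]))
    plane_pt, plane_n = best_fit_plane(tibia_cart.vertices[plateau_idx])
    if plane_n[2] < 0:
        plane_n = -plane_n
    tibial_plane = (plane_pt, plane_n)

    # --- menisci ------------------------------------------------------------
    menisci = {}
    for side, prefix in (("medial", "MM"), ("lateral", "LM")):
        stage(f"meniscus_{side}")
        hp = profiles[f"{prefix}_height"]
        wp = profiles[f"{prefix}_width"]
        ant = transfer_point(landmarks, f"{prefix}_anterior_root",
                             case.bones["tibia_fibula"])
        post = transfer_point(landmarks, f"{prefix}_posterior_root",
                              case.bones["tibia_fibula"])
        # roots sit on the bone; give them the clearance their own height
        # profile requires before wrapping
        ant = obstacles.project(ant, float(hp(0.0)) / 2.0)[0][0]
        post = obstacles.project(post, float(hp(1.0)) / 2.0)[0][0]
        menisci[side] = build_meniscus(
            obstacles, ant, post, hp, wp, side=side,
            n_nodes=config.n_meniscus_nodes, tibial_plane=tibial_plane,
            params=params, case_id=case.case_id)
    for side in menisci:
        obstacles.add(menisci[side].surface)

    # --- ligaments and patellar tendon --------------------------------------
    ligaments = {}
    for spec in default_ligament_table():
        stage(f"ligament_{spec.name}")
        origin_group = case.bones[landmarks.bone(spec.origin)].vertices[
            landmarks.indices(spec.origin)]
        insertion_group = case.bones[landmarks.bone(spec.insertion)].vertices[
            landmarks.indices(spec.insertion)]
        ligaments[spec.name] = predict_ligament(
            spec, origin_group, insertion_group, obstacles,
            n_cols=config.ligament_cols, n_rows=config.ligament_rows,
            params=params, case_id=case.case_id)
    stage("patellar_tendon")
    pt_origin = case.bones["patella"].vertices[landmarks.indices("PT_origin")]
    pt_insert = case.bones["tibia_fibula"].vertices[landmarks.indices("PT_insertion")]
    ligaments["PT"] = predict_patellar_tendon(
        pt_origin, pt_insert, obstacles,
        n_cols=config.ligament_cols, n_rows=config.ligament_rows,
        params=params, case_id=case.case_id)
    # --- cruciates: ACL first, PCL wraps around it ---------------------------
    # the cruciates run inside the capsule and wrap around the
    # osseous-cartilage-meniscus surfaces (plus the ACL tube for the PCL);
    # the peripheral ligament bands sit plastered onto the bone and are not
    # cruciate obstacles — they would create zero-gap regions with no
    # feasible clearance for the penetration correction
    cruciates = {}
    for name in ("ACL", "PCL"):
        stage(f"cruciate_{name}")
        profile = profiles[f"{name}_radius"]
        origin = transfer_point(landmarks, f"{name}_origin", case.bones["femur"])
        insertion = transfer_point(landmarks, f"{name}_insertion",
                                   case.bones["tibia_fibula"])
        origin = obstacles.project(origin, 0.0)[0][0]
        insertion = obstacles.project(insertion, 0.0)[0][0]
        cruciates[name] = predict_cruciate(
            name, origin, insertion, obstacles, profile,
            n_segments=config.cruciate_segments,
            params=params, case_id=case.case_id)
        obstacles.add(cruciates[name].tube.surface)

    return KneeModel(case.case_id, dict(case.bones), cartilage, menisci,
                     ligaments, cruciates, build_order)


def model_manifest(model: KneeModel) -> dict:
    """Stage list, mesh inventory and content hashes of a built model."""
    meshes = model.meshes()
    entries = {}
    for name, mesh in sorted(meshes.items()):
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(np.round(mesh.vertices, 9)).tobytes())
        h.update(np.ascontiguousarray(mesh.faces).tobytes())
        entries[name] = {
            "n_vertices": mesh.n_vertices,
            "n_faces": mesh.n_faces,
            "sha256": h.hexdigest(),
        }
    counts = {
        "bones": len(model.bones),
        "cartilage_regions": len(model.cartilage),
        "menisci": len(model.menisci),
        "ligament_tendon_solids": len(model.ligaments),
        "cruciate_tubes": len(model.cruciates),
    }
    return {"case_id": model.case_id, "build_order": model.build_order,
            "counts": counts, "meshes": entries}


def build_full_model(config: PipelineConfig):
    """File-level driver: load a cohort directory, build the configured
    case end to end, write PLY meshes + JSON manifest + log."""
    from kneemorph.synthetic import load_cohort

    cohort = load_cohort(config.cohort_dir)
    ids = [c.case_id for c in cohort.cases]
    case_id = config.case_id or ids[0]
    if case_id not in ids:
        raise ValueError(f"case {case_id!r} not in cohort ({ids})")
    idx = ids.index(case_id)
    training = [c for i, c in enumerate(cohort.cases) if i != idx] or cohort.cases
    mean_maps = build_mean_maps(training, cohort.regions)
    profiles = fit_default_profiles(cohort.profile_samples)
    log: list = []
    model = build_case_model(cohort.cases[idx], cohort.landmarks,
                             cohort.regions, mean_maps, profiles,
                             config=config, log=log)
    manifest = model_manifest(model)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mesh in model.meshes().items():
        write_mesh(mesh, out / f"{name}.ply")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "build.log").write_text("\n".join(log) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Leave-one-out validation
# ---------------------------------------------------------------------------

def loo_cartilage_thickness(cohort, use_measured: bool = False,
                            masked_only: bool = True):
    """Leave-one-out cartilage thickness validation over a cohort.

    For each held-out case the cohort mean map (built from the other
    cases, normalized by femoral length) is rescaled to the case's length
    and compared with the case's map in thickness space, pooled over all
    regions.  ``masked_only`` restricts the statistics to vertices carrying
    measurement noise (the sealed taper band is identically reproduced by
    construction and would deflate the error).
    """
    regions = cohort.regions

    def builder(training):
        return build_mean_maps(training, regions)

    def predictor(maps, held):
        ds = []
        for rname in regions:
            predicted = scale_map(maps[rname], held.femur_length)
            measured = (measure_case_maps(held, {rname: regions[rname]})[rname]
                        if use_measured else held.thickness_truth[rname])
            d = np.abs(predicted.values - measured.values)
            if masked_only:
                d = d[held.noise_mask[rname]]
            ds.append(d)
        from kneemorph.validation import DistanceReport
        return DistanceReport.from_distances(np.concatenate(ds))

    return leave_one_out(cohort.cases, builder, predictor)


def run_validation(cohort, out_dir=None):
    """LOO thickness validation with a pooled median/range table; written
    as CSV when ``out_dir`` is given."""
    reports, pooled = loo_cartilage_thickness(cohort)
    rows = [{
        "structure": "cartilage_thickness",
        **{f"{m}_{k}": pooled[m][k] for m in pooled for k in pooled[m]},
    }]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "validation.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0]))
            w.writeheader()
            w.writerows(rows)
        per_case = [{"case": c.case_id, "rmse": r.rmse, "asd": r.asd,
                     "hd": r.hd, "n": r.n}
                    for c, r in zip(cohort.cases, reports)]
        with open(out / "validation_per_case.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(per_case[0]))
            w.writeheader()
            w.writerows(per_case)
    return reports, pooled
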