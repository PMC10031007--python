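"""Per-vertex cartilage thickness maps: build, average, scale, project.

Thickness at a bone vertex is the distance from the subchondral bone to the
cartilage surface along the bone's vertex normal.  Maps from a training
cohort are normalized to a common femoral length, averaged per vertex into
a mean map, and a new case's cartilage is predicted by displacing its bone
vertices outward along their normals by the mean map values rescaled to the
case's femoral length.  Map edges are sealed to zero so predicted cartilage
attaches smoothly to the bone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from kneemorph.landmarks import LandmarkSet
from kneemorph.mesh_core import CorrespondedMesh, ray_first_hit, vertex_normals

#: mean thicknesses below this floor (mm) are treated as undefined when
#: forming relative errors (sealed edges would otherwise divide by ~0)
RELATIVE_ERROR_FLOOR = 0.05

#: rays are abandoned beyond this multiple of the corresponding-vertex
#: distance (grazing rays fall back to the corresponded-vertex distance)
RAY_CUTOFF_FACTOR = 4.0


@dataclass
class ThicknessMap:
    """Scalar thickness field (mm) over a named vertex region of a bone.

    ``region`` lists the bone vertex indices carrying values (same order as
    ``values``); ``edge_indices`` is the subset of the region forming its
    boundary; ``reference_length`` is the femoral length (mm) of the case
    the map was measured on (or the cohort mean for an averaged map).
    """

    bone_label: str
    region: np.ndarray
    values: np.ndarray
    edge_indices: np.ndarray
    reference_length: float
    region_name: str = ""

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.edge_indices = np.asarray(self.edge_indices, dtype=np.int64)
        if len(self.values) != len(self.region):
            raise ValueError("values and region must have equal length")
        if np.any(self.values < 0):
            raise ValueError("negative thickness")
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")

    def same_region(self, other: "ThicknessMap") -> bool:
        return (
            self.bone_label == other.bone_label
            and len(self.region) == len(other.region)
            and bool(np.all(self.region == other.region))
        )

    # -- persistence: CSV of (vertex_index, thickness_mm) + JSON sidecar ----

    def save(self, csv_path) -> None:
        csv_path = Path(csv_path)
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vertex_index", "thickness_mm"])
            for i, v in zip(self.region, self.values):
                w.writerow([int(i), repr(float(v))])
        sidecar = {
            "bone": self.bone_label,
            "region_name": self.region_name,
            "reference_length": self.reference_length,
            "edge_indices": [int(i) for i in self.edge_indices],
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, csv_path) -> "ThicknessMap":
        csv_path = Path(csv_path)
        region, values = [], []
        with open(csv_path) as fh:
            for row in csv.DictReader(fh):
                region.append(int(row["vertex_index"]))
                values.append(float(row["thickness_mm"]))
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(
            bone_label=meta["bone"],
            region=np.asarray(region),
            values=np.asarray(values),
            edge_indices=np.asarray(meta["edge_indices"], dtype=np.int64),
            reference_length=meta["reference_length"],
            region_name=meta.get("region_name", ""),
        )


def region_edges(mesh: CorrespondedMesh, region) -> np.ndarray:
    """Region vertices adjacent (by a mesh edge) to any non-region vertex.

    A region covering a closed component has no such vertices and the
    returned set is empty.
    """
    region = np.asarray(region, dtype=np.int64)
    in_region = np.zeros(mesh.n_vertices, dtype=bool)
    in_region[region] = True
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    a, b = edges[:, 0], edges[:, 1]
    boundary = np.zeros(mesh.n_vertices, dtype=bool)
    mask = in_region[a] & ~in_region[b]
    boundary[a[mask]] = True
    mask = in_region[b] & ~in_region[a]
    boundary[b[mask]] = True
    return region[boundary[region]]


def compute_thickness(bone: CorrespondedMesh, cartilage: CorrespondedMesh,
                      region, reference_length: float = 1.0,
                      region_name: str = "") -> ThicknessMap:
    """Measure cartilage thickness at each region vertex of the bone.

    A ray is cast from the bone vertex along its (outward) vertex normal
    and the first intersection with the cartilage surface is recorded.
    Where the ray misses (grazing geometry) the distance to the
    *corresponding* cartilage vertex is used instead — bone and cartilage
    meshes are vertex-corresponded by construction.  Negative/inward cases
    clamp to zero (cartilage cannot lie inside the bone).
    """
    if bone.n_vertices != cartilage.n_vertices or not np.array_equal(bone.faces, cartilage.faces):
        raise ValueError("bone and cartilage must be vertex-corresponded")
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ValueError("empty region")
    normals = vertex_normals(bone)[region]
    origins = bone.vertices[region]
    corr = np.linalg.norm(cartilage.vertices[region] - origins, axis=1)
    cutoff = RAY_CUTOFF_FACTOR * max(float(corr.max()), 1e-6)
    hits = ray_first_hit(cartilage, origins, normals, max_dist=cutoff)
    values = np.where(np.isnan(hits), corr, hits)
    values = np.maximum(values, 0.0)
    edges = region_edges(bone, region)
    return ThicknessMap(bone.bone_label, region, values, edges,
                        reference_length, region_name)


def seal_edges(tmap: ThicknessMap) -> ThicknessMap:
    """Zero the thickness at the region's boundary vertices."""
    values = tmap.values.copy()
    pos = {int(v): i for i, v in enumerate(tmap.region)}
    for e in tmap.edge_indices:
        values[pos[int(e)]] = 0.0
    return replace(tmap, values=values)


def mean_map(maps: list[ThicknessMap], target_length: float | None = None) -> ThicknessMap:
    """Average per-vertex thickness across cases, normalized for size.

    Each case's values are first rescaled to the cohort-mean femoral length
    (factor ``mean_length / case_length``), then averaged vertex-wise.  The
    returned map carries ``reference_length`` = cohort mean (or
    ``target_length`` if given), so later prediction scales by
    ``target_length / mean_length``.
    """
    if not maps:
        raise ValueError("no maps")
    first = maps[0]
    for m in maps[1:]:
        if not m.same_region(first):
            raise ValueError("maps cover different regions")
    lengths = np.array([m.reference_length for m in maps], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("non-positive reference length")
    mean_length = float(lengths.mean())
    stacked = np.stack([m.values * (mean_length / m.reference_length) for m in maps])
    avg = stacked.mean(axis=0)
    out = ThicknessMap(first.bone_label, first.region.copy(), avg,
                       first.edge_indices.copy(), mean_length,
                       first.region_name)
    if target_length is not None:
        out = scale_map(out, target_length)
    return out


def scale_map(tmap: ThicknessMap, target_length: float) -> ThicknessMap:
    """Rescale a map to a target femoral length (linear in the length ratio)."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    factor = target_length / tmap.reference_length
    return replace(tmap, values=tmap.values * factor, reference_length=target_length)


def femoral_length(femur: CorrespondedMesh, landmarks: LandmarkSet,
                   proximal: str = "femur_length_proximal",
                   distal: str = "femur_length_distal") -> float:
    """Euclidean distance between the two designated length landmarks.

    Femoral length drives the size normalization of thickness maps; using
    landmark vertices (rather than a principal axis) keeps the measure
    meaningful on partial, distal-only meshes.
    """
    for name in (proximal, distal):
        if name not in landmarks.entries:
            raise KeyError(f"missing femoral length landmark {name!r}")
    a = femur.vertices[landmarks.indices(proximal)].mean(axis=0)
    b = femur.vertices[landmarks.indices(distal)].mean(axis=0)
    return float(np.linalg.norm(a - b))


def predict_cartilage(bone: CorrespondedMesh, mean: ThicknessMap,
                      target_length: float | None = None) -> CorrespondedMesh:
    """Predict a case's cartilage surface from the mean thickness map.

    Region vertices are displaced outward along their vertex normals by the
    map values scaled by ``target_length / reference_length``; all other
    vertices are untouched.  Because edge values are sealed to zero the
    predicted surface meets the bone smoothly.
    """
    if mean.region.size and (mean.region.max() >= bone.n_vertices or mean.region.min() < 0):
        raise ValueError("map region exceeds bone vertex count")
    if mean.bone_label != bone.bone_label:
        raise ValueError(f"map is for {mean.bone_label}, bone is {bone.bone_label}")
    factor = 1.0 if target_length is None else target_length / mean.reference_length
    disp = np.maximum(mean.values * factor, 0.0)
    verts = bone.vertices.copy()
    verts[mean.region] += vertex_normals(bone)[mean.region] * disp[:, None]
    out = bone.with_vertices(verts)
    out.bone_label = bone.bone_label
    return out


def relative_error_map(error: np.ndarray, mean: ThicknessMap,
                       floor: float = RELATIVE_ERROR_FLOOR) -> np.ndarray:
    """Per-vertex error / mean-thickness ratio; NaN where the mean
    thickness is below ``floor`` (sealed edges) rather than a division."""
    error = np.asarray(error, dtype=float)
    if len(error) != len(mean.values):
        raise ValueError("error vector does not match map region")
    out = np.full_like(error, np.nan)
    defined = mean.values >= floor
    out[defined] = error[defined] / mean.values[defined]
    return out
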