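"""Index-based landmark anchoring, averaging and transfer.

Because all meshes of one bone in a cohort share vertex count and ordering,
a landmark stored as vertex indices on a reference template refers to the
same anatomical location on every case.  Transferring a landmark to a new
case is therefore pure index lookup, with no geometric computation.

Landmark names follow the usual knee abbreviations: MPFL, LPFL, sMCL_ant,
sMCL_post, LCL, ALL, POL, OPL, PT (patellar tendon), ACL, PCL, and the
meniscal roots (e.g. ``MM_anterior_root``).  Each named entry may hold
several indices (an attachment *area*); the attachment "point" is the
centroid of the transferred vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from kneemorph.mesh_core import CorrespondedMesh


@dataclass
class LandmarkSet:
    """Named vertex-index groups on a reference template.

    ``entries`` maps landmark name -> dict with keys ``bone`` (bone label)
    and ``indices`` (list of vertex indices).  ``provenance`` records how
    the set was produced (manual / averaged / transferred).
    """

    entries: dict = field(default_factory=dict)
    provenance: str = "manual"

    def __post_init__(self) -> None:
        seen = set()
        for name, entry in self.entries.items():
            if name in seen:
                raise ValueError(f"duplicate landmark name {name!r}")
            seen.add(name)
            entry["indices"] = [int(i) for i in entry["indices"]]

    def names(self) -> list[str]:
        return list(self.entries)

    def indices(self, name: str) -> np.ndarray:
        return np.asarray(self.entries[name]["indices"], dtype=np.int64)

    def bone(self, name: str) -> str:
        return self.entries[name]["bone"]

    # -- persistence --------------------------------------------------------

    @classmethod
    def from_json(cls, path, one_based: bool = False) -> "LandmarkSet":
        """Load ``{name: {"bone": ..., "indices": [...]}}``; pass
        ``one_based=True`` for legacy Matlab-style index files."""
        data = json.loads(Path(path).read_text())
        entries = {}
        for name, entry in data.items():
            idx = [int(i) - (1 if one_based else 0) for i in entry["indices"]]
            if one_based and any(i < 0 for i in idx):
                raise ValueError(f"{name}: index 0 in a one-based file")
            entries[name] = {"bone": entry["bone"], "indices": idx}
        return cls(entries=entries)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=1))


def anchor_points(mesh: CorrespondedMesh, points) -> np.ndarray:
    """Nearest-vertex indices for each point; ties go to the lowest index.

    This anchors coordinates (e.g. a manually placed or cohort-averaged
    attachment) to the template so it can be transferred by index.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(points)
    # cKDTree tie behaviour is unspecified; re-resolve ties deterministically
    out = np.empty(len(points), dtype=np.int64)
    for i, (p, d) in enumerate(zip(points, dist)):
        cand = tree.query_ball_point(p, d * (1 + 1e-12) + 1e-12)
        out[i] = min(cand) if cand else idx[i]
    return out


def average_landmark(case_points) -> np.ndarray:
    """Component-wise arithmetic centroid of one point per case."""
    case_points = np.atleast_2d(np.asarray(case_points, dtype=float))
    if len(case_points) == 0:
        raise ValueError("no cases to average")
    return case_points.mean(axis=0)


def transfer(lset: LandmarkSet, target: CorrespondedMesh) -> dict[str, np.ndarray]:
    """Look up each landmark's stored indices on the target mesh.

    Only entries whose ``bone`` matches ``target.bone_label`` are
    transferred; returns name -> (k, 3) coordinate group.
    """
    out: dict[str, np.ndarray] = {}
    for name in lset.names():
        if lset.bone(name) != target.bone_label:
            continue
        idx = lset.indices(name)
        if idx.size and (idx.min() < 0 or idx.max() >= target.n_vertices):
            raise IndexError(
                f"{name}: index {int(idx.max())} out of range for "
                f"{target.n_vertices}-vertex {target.bone_label}"
            )
        out[name] = target.vertices[idx]
    return out


def transfer_point(lset: LandmarkSet, name: str, target: CorrespondedMesh) -> np.ndarray:
    """Single-point reduction of a transferred landmark group: the centroid
    of its vertices on the target."""
    if lset.bone(name) != target.bone_label:
        raise ValueError(
            f"{name} lives on {lset.bone(name)}, not {target.bone_label}"
        )
    idx = lset.indices(name)
    if idx.max(initial=0) >= target.n_vertices or idx.min(initial=0) < 0:
        raise IndexError(f"{name}: index out of range")
    return target.vertices[idx].mean(axis=0)


def swap_variant(lset: LandmarkSet, name: str, new_indices) -> LandmarkSet:
    """Return a copy with only the named entry's indices replaced.

    This is how anatomical variants are modeled: e.g. re-assigning the
    medial-meniscus anterior root to a more anterior vertex patch moves the
    downstream meniscal origin accordingly.
    """
    if name not in lset.entries:
        raise KeyError(f"unknown landmark {name!r}")
    entries = {k: {"bone": v["bone"], "indices": list(v["indices"])}
               for k, v in lset.entries.items()}
    entries[name]["indices"] = [int(i) for i in np.asarray(new_indices).ravel()]
    return LandmarkSet(entries=entries, provenance=lset.provenance)
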