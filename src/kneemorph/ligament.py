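"""Main-ligament bands and the patellar tendon.

Each ligament is modeled as an elastic membrane of springs spanning its
origin and insertion attachment curves, relaxed over the accumulated
obstacle surfaces (bone + cartilage + menisci) without penetration, then
thickened symmetrically into a solid band by a fixed, ligament-specific
mid-substance thickness taken from cadaveric and MRI literature.

The patellar tendon is the exception: closed splines are fitted through the
origin (patella) and insertion (tibial tuberosity) vertex loops, resampled
at corresponding parameters, and corresponding points are connected by a
wrapped membrane sleeve — its thickness is inherent to the loop geometry
and never an assigned number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kneemorph.mesh_core import CorrespondedMesh, best_fit_plane, ensure_outward, fit_spline
from kneemorph.wrap_engine import (
    ObstacleSet,
    RelaxParams,
    WrapResult,
    grid_to_mesh,
    wrap_membrane,
)

LIGAMENT_NAMES = ("MPFL", "LPFL", "sMCL_ant", "sMCL_post", "LCL", "ALL",
                  "POL", "OPL")

#: assigned mid-substance thickness (mm) per ligament; both sMCL bundles
#: share the single published sMCL value.
_THICKNESS_MM = {
    "MPFL": 2.90,
    "LPFL": 1.80,
    "sMCL_ant": 2.10,
    "sMCL_post": 2.10,
    "LCL": 2.20,
    "ALL": 1.50,
    "POL": 1.00,
    "OPL": 1.44,
}

DEFAULT_GRID_COLS = 20
DEFAULT_GRID_ROWS = 30


@dataclass(frozen=True)
class LigamentSpec:
    """Name, attachment landmark names, and assigned thickness (mm)."""

    name: str
    origin: str
    insertion: str
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class LigamentMesh:
    """Wrapped midsurface grid plus the thickened (or sleeve) solid."""

    midsurface: WrapResult
    solid: CorrespondedMesh
    spec: LigamentSpec | None = None


def default_ligament_table() -> list[LigamentSpec]:
    """The modeled ligaments with their assigned mid-substance thicknesses
    (mm): MPFL 2.90, LPFL 1.80, sMCL (both bundles) 2.10, LCL 2.20,
    ALL 1.50, POL 1.00, OPL 1.44."""
    return [
        LigamentSpec(name, f"{name}_origin", f"{name}_insertion",
                     _THICKNESS_MM[name])
        for name in LIGAMENT_NAMES
    ]


def ligament_thickness(name: str) -> float:
    """Assigned mid-substance thickness (mm) for a known ligament."""
    try:
        return _THICKNESS_MM[name]
    except KeyError:
        raise KeyError(f"unknown ligament {name!r}; known: {LIGAMENT_NAMES}") from None


def attachment_curve(points, n: int) -> np.ndarray:
    """Reduce an attachment vertex group to an ordered open curve.

    The group is projected onto its best-fit plane, ordered by polar angle
    about the centroid (opened at the largest angular gap), and resampled
    to ``n`` points along an interpolating spline.  One- and two-point
    groups degenerate to repeated points / a straight segment.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise ValueError("empty attachment group")
    if len(points) == 1:
        return np.repeat(points, n, axis=0)
    if len(points) == 2:
        t = np.linspace(0, 1, n)[:, None]
        return (1 - t) * points[0] + t * points[1]
    centroid = points.mean(axis=0)
    _u, sv, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if sv[1] < 1e-6 * max(sv[0], 1e-12):
        # (nearly) collinear group: order along the principal axis
        order = np.argsort((points - centroid) @ vt[0], kind="stable")
    else:
        normal = vt[-1]
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, normal)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = a - np.dot(a, normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        rel = points - centroid
        ang = np.arctan2(rel @ e2, rel @ e1)
        order = np.argsort(ang, kind="stable")
        ang_sorted = ang[order]
        gaps = np.diff(np.concatenate([ang_sorted,
                                       [ang_sorted[0] + 2 * np.pi]]))
        cut = int(np.argmax(gaps)) + 1  # open the loop at the widest gap
        order = np.concatenate([order[cut:], order[:cut]])
    ordered = points[order]
    # drop coincident consecutive points before spline fitting
    keep = [0]
    for i in range(1, len(ordered)):
        if np.linalg.norm(ordered[i] - ordered[keep[-1]]) > 1e-9:
            keep.append(i)
    ordered = ordered[keep]
    if len(ordered) == 1:
        return np.repeat(ordered, n, axis=0)
    if len(ordered) == 2:
        t = np.linspace(0, 1, n)[:, None]
        return (1 - t) * ordered[0] + t * ordered[1]
    return fit_spline(ordered, closed=False).resample(n)


def _align_curves(origin: np.ndarray, insertion: np.ndarray) -> np.ndarray:
    """Reverse the insertion curve if that shortens the fiber columns
    (detects mismatched travel directions that would cross the membrane)."""
    direct = np.linalg.norm(origin - insertion, axis=1).sum()
    reversed_ = np.linalg.norm(origin - insertion[::-1], axis=1).sum()
    return insertion[::-1] if reversed_ < direct else insertion


def _thicken_grid(grid: np.ndarray, thickness: float, name: str,
                  case_id: str) -> CorrespondedMesh:
    """Extrude a midsurface grid symmetrically into a closed solid band."""
    rows, cols, _ = grid.shape
    # grid normals: cross of the two surface tangent directions
    du = np.gradient(grid, axis=0)
    dv = np.gradient(grid, axis=1)
    nrm = np.cross(du, dv)
    ln = np.linalg.norm(nrm, axis=2, keepdims=True)
    nrm = nrm / np.maximum(ln, 1e-300)
    top = grid + 0.5 * thickness * nrm
    bot = grid - 0.5 * thickness * nrm
    vt, ft = grid_to_mesh(top)
    vb, fb = grid_to_mesh(bot)
    nb = len(vt)
    faces = [ft, fb[:, ::-1] + nb]

    def wall(idx_top, idx_bot, flip=False):
        w = []
        for k in range(len(idx_top) - 1):
            a, b = idx_top[k], idx_top[k + 1]
            c, d = idx_bot[k] + nb, idx_bot[k + 1] + nb
            if flip:
                w.append([a, b, d])
                w.append([a, d, c])
            else:
                w.append([a, d, b])
                w.append([a, c, d])
        return np.asarray(w, dtype=np.int64)

    grid_idx = np.arange(rows * cols).reshape(rows, cols)
    faces.append(wall(grid_idx[0], grid_idx[0], flip=False))
    faces.append(wall(grid_idx[-1], grid_idx[-1], flip=True))
    faces.append(wall(grid_idx[:, 0], grid_idx[:, 0], flip=True))
    faces.append(wall(grid_idx[:, -1], grid_idx[:, -1], flip=False))
    verts = np.vstack([vt, vb])
    mesh = CorrespondedMesh(verts, np.vstack(faces),
                            bone_label=f"ligament_{name}", case_id=case_id)
    return ensure_outward(mesh)


def predict_ligament(spec: LigamentSpec, origin_points, insertion_points,
                     obstacles: ObstacleSet,
                     n_cols: int = DEFAULT_GRID_COLS,
                     n_rows: int = DEFAULT_GRID_ROWS,
                     params: RelaxParams | None = None,
                     case_id: str = "") -> LigamentMesh:
    """Wrap a ligament band between its transferred attachment groups.

    The attachment vertex groups are reduced to matched boundary curves,
    the membrane is relaxed over the obstacles, and the converged
    midsurface is extruded by ``spec.thickness`` (symmetric about the
    midsurface) into a closed solid; solid vertices are finally projected
    out of the obstacles.
    """
    origin_curve = attachment_curve(origin_points, n_cols)
    insertion_curve = attachment_curve(insertion_points, n_cols)
    insertion_curve = _align_curves(origin_curve, insertion_curve)
    if len(obstacles):
        # spline resampling between on-surface vertices may dip a hair
        # inside the composite; lift the boundary curves back onto it
        origin_curve, _ = obstacles.project(origin_curve, 0.0)
        insertion_curve, _ = obstacles.project(insertion_curve, 0.0)
    mid = wrap_membrane(origin_curve, insertion_curve, obstacles,
                        n_rows=n_rows, params=params)
    solid = _thicken_grid(mid.nodes, spec.thickness, spec.name, case_id)
    if len(obstacles):
        corrected, _ = obstacles.project_strict(solid.vertices, 0.0)
        solid = solid.with_vertices(corrected)
    return LigamentMesh(midsurface=mid, solid=solid, spec=spec)


def predict_patellar_tendon(origin_loop_points, insertion_loop_points,
                            obstacles: ObstacleSet,
                            n_cols: int = DEFAULT_GRID_COLS,
                            n_rows: int = DEFAULT_GRID_ROWS,
                            params: RelaxParams | None = None,
                            case_id: str = "") -> LigamentMesh:
    """Spline-strip patellar tendon between two closed vertex loops.

    Closed splines are fitted through the origin and insertion loops and
    resampled at ``n_cols`` corresponding parameters (both loops start at
    the parameter nearest the most medial vertex and travel the same way);
    corresponding points are connected by a periodic wrapped membrane.  The
    resulting closed sleeve *is* the tendon — no thickness is assigned.
    """
    origin_loop_points = np.atleast_2d(np.asarray(origin_loop_points, dtype=float))
    insertion_loop_points = np.atleast_2d(np.asarray(insertion_loop_points, dtype=float))
    if len(origin_loop_points) < 3 or len(insertion_loop_points) < 3:
        raise ValueError("attachment loops need at least 3 vertices")

    def loop_curve(pts):
        # order around the loop by polar angle in the best-fit plane
        centroid, normal = best_fit_plane(pts)
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, normal)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = a - np.dot(a, normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        rel = pts - centroid
        ang = np.arctan2(rel @ e2, rel @ e1)
        order = np.argsort(ang, kind="stable")
        spline = fit_spline(pts[order], closed=True)
        return spline.resample(n_cols)

    oc = loop_curve(origin_loop_points)
    ic = loop_curve(insertion_loop_points)

    # correspondence: start both loops at the most medial (-x) sample and
    # travel in the same rotational sense w.r.t. the origin->insertion axis
    def roll_to_start(curve):
        return np.roll(curve, -int(np.argmin(curve[:, 0])), axis=0)

    oc = roll_to_start(oc)
    ic = roll_to_start(ic)
    axis = ic.mean(axis=0) - oc.mean(axis=0)

    def sense(curve):
        rel = curve - curve.mean(axis=0)
        s = np.cross(rel[:-1], rel[1:]).sum(axis=0)
        return np.sign(np.dot(s, axis))

    if sense(oc) != sense(ic):
        ic = np.roll(ic[::-1], 1, axis=0)
    if len(obstacles):
        oc, _ = obstacles.project(oc, 0.0)
        ic, _ = obstacles.project(ic, 0.0)
    mid = wrap_membrane(oc, ic, obstacles, n_rows=n_rows, params=params,
                        periodic=True)
    verts, faces = grid_to_mesh(mid.nodes, periodic=True)
    # cap the sleeve ends (fan around the loop centroids) for watertightness
    rows, cols, _ = mid.nodes.shape
    c0 = mid.nodes[0].mean(axis=0)
    c1 = mid.nodes[-1].mean(axis=0)
    verts = np.vstack([verts, c0, c1])
    i0, i1 = rows * cols, rows * cols + 1
    cap = []
    for j in range(cols):
        j2 = (j + 1) % cols
        cap.append([i0, j2, j])
        cap.append([i1, (rows - 1) * cols + j, (rows - 1) * cols + j2])
    solid = ensure_outward(
        CorrespondedMesh(verts, np.vstack([faces, np.asarray(cap)]),
                         bone_label="patellar_tendon", case_id=case_id)
    )
    if len(obstacles):
        # the cap apices (loop centroids) start inside the attachment bones
        corrected, _ = obstacles.project_strict(solid.vertices, 0.0)
        solid = solid.with_vertices(corrected)
    return LigamentMesh(midsurface=mid, solid=solid,
                        spec=LigamentSpec("PT", "PT_origin", "PT_insertion",
                                          thickness=1.0))
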