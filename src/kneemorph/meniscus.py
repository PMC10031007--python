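"""Static meniscus construction between tibial and femoral cartilage.

The meniscal body is simplified to a wedge with a triangular cross-section
of varying height and width.  Construction runs in three steps: (1) a
centerline is wrapped elastically from the anterior to the posterior root,
enforcing a per-node clearance of half the local meniscal height so the
path is forced around the femoral condyle rather than through it; (2) at
equidistant stations along the path a triangular cross-section is placed —
the thick outer edge of extent height(s) at the outer rim, the apex at
distance width(s) toward the meniscal center — and consecutive triangles
are stitched into a closed wedge mesh; (3) any mesh vertex found inside the
composite osseous-cartilage surface is projected back onto it, fitting the
wedge between the cartilage layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from kneemorph.mesh_core import CorrespondedMesh, best_fit_plane, ensure_outward
from kneemorph.profiles import PolynomialProfile
from kneemorph.wrap_engine import ObstacleSet, RelaxParams, WrapResult, wrap_chain_offset

#: default number of centerline stations per meniscus
DEFAULT_N_NODES = 60


@dataclass
class MeniscusModel:
    """A constructed meniscus: centerline, profiles, wedge surface."""

    side: str
    anterior_root: np.ndarray
    posterior_root: np.ndarray
    centerline: WrapResult
    height_profile: PolynomialProfile
    width_profile: PolynomialProfile
    surface: CorrespondedMesh
    center: np.ndarray


def meniscal_center(centerline, plane: tuple | None = None) -> np.ndarray:
    """Arc-length-weighted centroid of the centerline, projected onto the
    tibial plateau plane.

    ``plane`` is (point_on_plane, unit_normal); when omitted, the best-fit
    plane of the centerline itself is used.  The width direction of every
    cross-section points from the outer rim toward this center.
    """
    pts = np.atleast_2d(np.asarray(centerline, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 centerline nodes")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.sum() == 0:
        raise ValueError("degenerate centerline")
    mid = 0.5 * (pts[:-1] + pts[1:])
    centroid = (mid * seg[:, None]).sum(axis=0) / seg.sum()
    # collinearity check: point spread perpendicular to the chord
    chord = pts[-1] - pts[0]
    nc = np.linalg.norm(chord)
    if nc > 0:
        perp = (pts - pts[0]) - np.outer((pts - pts[0]) @ chord / nc**2, chord)
        if np.linalg.norm(perp, axis=1).max() < 1e-9 * max(nc, 1.0):
            raise ValueError("collinear centerline has no meniscal center")
    if plane is None:
        plane = best_fit_plane(pts)
    origin, normal = plane
    return centroid - np.dot(centroid - origin, normal) * normal


def cross_section_triangle(node, toward_center, up, height: float,
                           width: float) -> np.ndarray:
    """Triangular meniscal cross-section at one centerline station.

    Returns the three wedge points: the apex at ``node + width *
    toward_center`` (inner rim) and the two outer-rim points ``node +/-
    (height/2) * up``.
    """
    node = np.asarray(node, dtype=float)
    toward_center = np.asarray(toward_center, dtype=float)
    up = np.asarray(up, dtype=float)
    for v, name in ((toward_center, "toward_center"), (up, "up")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a unit vector")
    if abs(np.dot(toward_center, up)) > 1e-6:
        raise ValueError("toward_center and up must be orthogonal")
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    apex = node + width * toward_center
    top = node + 0.5 * height * up
    bottom = node - 0.5 * height * up
    return np.vstack([apex, top, bottom])


def _wedge_mesh(sections: np.ndarray, side: str, case_id: str) -> CorrespondedMesh:
    """Stitch per-station triangles (n, 3, 3) into a closed wedge mesh.

    Vertex layout: station i contributes vertices (3i, 3i+1, 3i+2) =
    (apex, top, bottom); consecutive stations are joined by two triangles
    per side of the wedge; the ends are capped by the first/last section
    triangles themselves.
    """
    n = len(sections)
    verts = sections.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        a0, t0, b0 = 3 * i, 3 * i + 1, 3 * i + 2
        a1, t1, b1 = 3 * (i + 1), 3 * (i + 1) + 1, 3 * (i + 1) + 2
        for p, q in ((a0, t0), (t0, b0), (b0, a0)):
            p1 = p + 3
            q1 = q + 3
            faces.append([p, q, q1])
            faces.append([p, q1, p1])
    faces.append([0, 2, 1])                          # anterior cap
    faces.append([3 * (n - 1), 3 * (n - 1) + 1, 3 * (n - 1) + 2])  # posterior cap
    mesh = CorrespondedMesh(verts, np.asarray(faces, dtype=np.int64),
                            bone_label=f"meniscus_{side}", case_id=case_id)
    return ensure_outward(mesh)


def build_meniscus(obstacles: ObstacleSet, anterior_root, posterior_root,
                   height_profile: PolynomialProfile,
                   width_profile: PolynomialProfile,
                   side: str = "medial", n_nodes: int = DEFAULT_N_NODES,
                   tibial_plane: tuple | None = None,
                   params: RelaxParams | None = None,
                   case_id: str = "") -> MeniscusModel:
    """Construct a meniscus between the given root attachments.

    ``obstacles`` holds the composite watertight bone+cartilage surfaces of
    tibia and femur; ``height_profile``/``width_profile`` give the
    triangular cross-section dimensions versus relative position s along
    the outer rim (0 = anterior root, 1 = posterior root).
    """
    anterior_root = np.asarray(anterior_root, dtype=float)
    posterior_root = np.asarray(posterior_root, dtype=float)
    s = np.linspace(0.0, 1.0, n_nodes)
    heights = np.maximum(height_profile(s), 0.0)
    widths = np.maximum(width_profile(s), 0.0)
    if np.mean(heights[1:-1] <= 0) > 0.5 or np.mean(widths[1:-1] <= 0) > 0.5:
        raise ValueError("profiles non-positive over most of the span")
    floor = 1e-3
    if np.any(heights[1:-1] < floor) or np.any(widths[1:-1] < floor):
        warnings.warn("degenerate profile floored; meniscus may be ribbon-like",
                      stacklevel=2)
    heights = np.maximum(heights, floor)
    widths = np.maximum(widths, floor)

    # step 1: offset tube path at clearance h/2
    centerline = wrap_chain_offset(
        anterior_root, posterior_root, obstacles, n_nodes=n_nodes,
        offset_profile=heights / 2.0, params=params,
    )
    pts = centerline.nodes

    # step 2: triangular cross-sections toward the meniscal center
    center = meniscal_center(pts, plane=tibial_plane)
    if tibial_plane is None:
        tibial_plane = best_fit_plane(pts)
    up = np.asarray(tibial_plane[1], dtype=float)
    up = up / np.linalg.norm(up)
    sections = np.empty((n_nodes, 3, 3))
    for i in range(n_nodes):
        toward = center - pts[i]
        toward -= np.dot(toward, up) * up
        nt = np.linalg.norm(toward)
        if nt < 1e-9:
            raise ValueError(f"centerline node {i} coincides with the center")
        sections[i] = cross_section_triangle(pts[i], toward / nt, up,
                                             heights[i], widths[i])
    surface = _wedge_mesh(sections, side, case_id)

    # step 3: project penetrating wedge vertices onto the composite surface
    if len(obstacles):
        corrected, _ = obstacles.project_strict(surface.vertices, 0.0)
        surface = surface.with_vertices(corrected)

    return MeniscusModel(side, anterior_root, posterior_root, centerline,
                         height_profile, width_profile, surface, center)
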