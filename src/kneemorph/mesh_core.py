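"""Mesh data model, I/O, normals, proximity and containment queries, splines.

Everything downstream (thickness maps, elastic wrapping, tube meshes,
validation metrics) is built on the primitives in this module.  Meshes are
triangle surfaces in millimetres with a *stable vertex ordering*: meshes of
the same bone across subjects share vertex count and face array, so vertex
``i`` refers to the same anatomical location on every case.  That
correspondence is what makes index-based landmark transfer and per-vertex
thickness averaging possible, and it is why the readers here never reorder,
merge or otherwise "process" vertices (except for STL, which stores no
connectivity and must be re-welded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

BoneLabel = Literal["femur", "tibia_fibula", "patella", "other"]

#: points closer to the surface than this (mm) count as *outside* in
#: containment queries, so projection onto a surface is idempotent.
SURFACE_TOL = 1e-6


class MeshFormatError(ValueError):
    """Raised for unreadable files, degenerate faces or empty meshes."""


@dataclass
class CorrespondedMesh:
    """Triangle surface mesh with stable vertex ordering.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres, right-handed frame.
    faces : (m, 3) int array of vertex indices (0-based).
    bone_label : which bone (or derived structure) the mesh represents.
    case_id : subject/case identifier within a cohort.
    """

    vertices: np.ndarray
    faces: np.ndarray
    bone_label: str = "other"
    case_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshFormatError("faces must be an (m, 3) array")
        if len(self.vertices) == 0:
            raise MeshFormatError("empty mesh: no vertices")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                bad = int(self.faces.max())
                raise MeshFormatError(
                    f"face index {bad} out of range for {len(self.vertices)} vertices"
                )
            degen = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degen.any():
                raise MeshFormatError(
                    f"degenerate face at index {int(np.nonzero(degen)[0][0])}"
                )
        self._cache: dict = {}

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit face normals following the face winding (may contain NaN
        for zero-area faces; construction forbids index-degenerate faces
        but not geometrically collapsed ones)."""
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return n / norm

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def with_vertices(self, vertices: np.ndarray) -> "CorrespondedMesh":
        """Same connectivity, new coordinates (correspondence preserved)."""
        return CorrespondedMesh(vertices, self.faces.copy(), self.bone_label, self.case_id)

    def translated(self, offset) -> "CorrespondedMesh":
        return self.with_vertices(self.vertices + np.asarray(offset, dtype=float))

    def proximity(self) -> "TriangleProximity":
        """Cached accelerated closest-point structure for this mesh."""
        prox = self._cache.get("proximity")
        if prox is None:
            prox = TriangleProximity(self.vertices, self.faces)
            self._cache["proximity"] = prox
        return prox


@dataclass(frozen=True)
class SurfaceQueryResult:
    """Closest-point query answer: the surface point, its face, the
    unsigned distance (mm) and whether the query point was inside."""

    point: np.ndarray
    face_index: int
    distance: float
    inside: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"PLY": ".ply", "STL": ".stl", "OBJ": ".obj"}

#: weld tolerance for STL input (mm); STL triangles carry no shared indices
STL_MERGE_TOL = 1e-6


def read_mesh(path, fmt: str | None = None, bone_label: str = "other",
              case_id: str = "") -> CorrespondedMesh:
    """Read a PLY/STL/OBJ triangle mesh, preserving vertex order.

    PLY and OBJ keep the stored vertex ordering and are therefore the
    formats of choice for correspondence-bearing meshes.  STL stores bare
    triangles, so vertices are merged at ``STL_MERGE_TOL`` and ordering is
    *not* meaningful across cases.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported format {fmt!r} (PLY/STL/OBJ)")
    try:
        loaded = trimesh.load(path, file_type=fmt.lower(), process=False,
                              maintain_order=True, force="mesh")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if fmt == "STL":
        merged = trimesh.Trimesh(verts, faces, process=True,
                                 merge_tex=True, merge_norm=True)
        merged.merge_vertices(digits_vertex=int(-np.log10(STL_MERGE_TOL)))
        verts, faces = np.asarray(merged.vertices), np.asarray(merged.faces)
    if len(verts) == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    return CorrespondedMesh(verts, faces, bone_label=bone_label, case_id=case_id)


def write_mesh(mesh: CorrespondedMesh, path, fmt: str | None = None) -> None:
    """Write a mesh; PLY (binary) preserves vertex order and precision."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported format {fmt!r} (PLY/STL/OBJ)")
    mesh.to_trimesh().export(path, file_type=fmt.lower())


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def vertex_normals(mesh: CorrespondedMesh, strict: bool = True) -> np.ndarray:
    """Angle-weighted per-vertex unit normals.

    Each incident face contributes its unit normal weighted by the corner
    angle at the vertex; the weighting is robust to the varying triangle
    density of quasi-isometric meshes.  Orientation follows the face
    winding (outward for consistently wound closed meshes).  A vertex whose
    one-ring has zero area raises in strict mode; with ``strict=False``
    (penetration-corrected geometry can collapse triangles) such vertices
    get an arbitrary unit normal instead.
    """
    tri = mesh.triangles
    fn = mesh.face_normals()
    normals = np.zeros_like(mesh.vertices)
    for corner in range(3):
        a = tri[:, corner]
        b = tri[:, (corner + 1) % 3] - a
        c = tri[:, (corner + 2) % 3] - a
        nb = np.linalg.norm(b, axis=1)
        nc = np.linalg.norm(c, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", b, c) / (nb * nc)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        contrib = fn * ang[:, None]
        np.add.at(normals, mesh.faces[:, corner], np.nan_to_num(contrib))
    norm = np.linalg.norm(normals, axis=1)
    bad = norm < 1e-14
    if bad.any():
        if strict:
            raise ValueError(
                f"zero-area one-ring at vertex {int(np.nonzero(bad)[0][0])}"
            )
        normals[bad] = [0.0, 0.0, 1.0]
        norm = np.where(bad, 1.0, norm)
    return normals / norm[:, None]


# ---------------------------------------------------------------------------
# Point-to-triangle proximity
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on triangles ``tri[i]`` to points ``p[i]``.

    Vectorized form of the standard barycentric region test (Ericson,
    *Real-Time Collision Detection*, §5.1.5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    def finite0(x):
        return np.where(np.isfinite(x), x, 0.0)

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0),
           a + finite0(v_ab)[:, None] * ab)          # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0),
           a + finite0(w_ac)[:, None] * ac)          # edge AC

    va = d3 * d6 - d5 * d4
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + finite0(w_bc)[:, None] * (c - b))     # edge BC

    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    interior = a + finite0(v)[:, None] * ab + finite0(w)[:, None] * ac
    settle(np.ones(len(p), dtype=bool), interior)          # face interior
    return out


class TriangleProximity:
    """Accelerated exact closest-point queries against a triangle soup.

    A k-d tree over face centroids prunes candidates; exactness is kept by
    expanding the candidate set until every face whose centroid could beat
    the current best (centroid distance minus the face's circumradius
    bound) has been examined.  Ties are broken by lowest face index.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        tri = self.vertices[self.faces]
        self.tri = tri
        self.centroids = tri.mean(axis=1)
        self.face_radius = np.linalg.norm(
            tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_radius = float(self.face_radius.max()) if len(faces) else 0.0
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray, exact_above: float = np.inf):
        """Return (closest_points, face_indices, distances) for points (n,3).

        Results are exact for every point whose true distance is below
        ``exact_above``; points provably farther than that keep their
        first-stage (possibly slightly overestimated) answer, which saves
        substantial work inside relaxation loops where only distances near
        a clearance threshold matter.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        m = len(self.faces)
        if m == 0:
            raise ValueError("mesh has no faces")
        if m <= 64:
            return self._brute(points)

        k = min(32, m)
        _, idx0 = self.tree.query(points, k=k)
        idx0 = np.atleast_2d(idx0)
        flat_pts = np.repeat(points, k, axis=0)
        flat_idx = idx0.ravel()
        cp = _closest_on_triangles(flat_pts, self.tri[flat_idx])
        d = np.linalg.norm(cp - flat_pts, axis=1).reshape(n, k)
        cp = cp.reshape(n, k, 3)
        # vectorized row-wise argmin, ties to the lowest face index
        dmin = d.min(axis=1, keepdims=True)
        tol = 1e-12 * np.maximum(1.0, dmin)
        masked_idx = np.where(d <= dmin + tol, idx0, np.iinfo(np.int64).max)
        col = np.argmin(masked_idx, axis=1)
        rows = np.arange(n)
        best_dist = d[rows, col]
        best_face = idx0[rows, col].astype(np.int64)
        best_pt = cp[rows, col]
        # exactness: any face whose centroid lies within best + its radius
        # could still be closer; widen the candidate set for those points
        kth = np.linalg.norm(self.centroids[idx0[:, -1]] - points, axis=1)
        lower_bound = np.minimum(best_dist, kth - self.max_radius)
        unsure = np.nonzero((kth < best_dist + self.max_radius)
                            & (lower_bound < exact_above))[0]
        if unsure.size and m > k:
            k2 = min(256, m)
            _, idx2 = self.tree.query(points[unsure], k=k2)
            idx2 = np.atleast_2d(idx2)
            nu = len(unsure)
            fp = np.repeat(points[unsure], k2, axis=0)
            cp2 = _closest_on_triangles(fp, self.tri[idx2.ravel()])
            d2 = np.linalg.norm(cp2 - fp, axis=1).reshape(nu, k2)
            cp2 = cp2.reshape(nu, k2, 3)
            dmin2 = d2.min(axis=1, keepdims=True)
            tol2 = 1e-12 * np.maximum(1.0, dmin2)
            mi2 = np.where(d2 <= dmin2 + tol2, idx2, np.iinfo(np.int64).max)
            col2 = np.argmin(mi2, axis=1)
            ru = np.arange(nu)
            best_dist[unsure] = d2[ru, col2]
            best_face[unsure] = idx2[ru, col2]
            best_pt[unsure] = cp2[ru, col2]
            kth2 = np.linalg.norm(self.centroids[idx2[:, -1]] - points[unsure],
                                  axis=1)
            lb2 = np.minimum(best_dist[unsure], kth2 - self.max_radius)
            unsure = unsure[(kth2 < best_dist[unsure] + self.max_radius)
                            & (lb2 < exact_above)]
        for i in unsure:
            reach = best_dist[i] + self.max_radius
            cand = self.tree.query_ball_point(points[i], reach + 1e-12)
            cand = np.asarray(sorted(cand), dtype=np.int64)
            cpts = _closest_on_triangles(
                np.broadcast_to(points[i], (len(cand), 3)), self.tri[cand]
            )
            dd = np.linalg.norm(cpts - points[i], axis=1)
            bj = _argmin_tiebreak(dd, cand)
            best_dist[i] = dd[bj]
            best_face[i] = cand[bj]
            best_pt[i] = cpts[bj]
        return best_pt, best_face, best_dist

    def _brute(self, points):
        n, m = len(points), len(self.faces)
        flat_pts = np.repeat(points, m, axis=0)
        tri = np.tile(self.tri, (n, 1, 1))
        cp = _closest_on_triangles(flat_pts, tri).reshape(n, m, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        faces = np.arange(m)
        best = np.array([_argmin_tiebreak(d[i], faces) for i in range(n)])
        rows = np.arange(n)
        return cp[rows, best], best.astype(np.int64), d[rows, best]


def _argmin_tiebreak(dist: np.ndarray, indices: np.ndarray, rel: float = 1e-12) -> int:
    """Index into ``dist`` of the minimum, ties (within relative ``rel``)
    resolved toward the lowest value of ``indices``."""
    dmin = dist.min()
    tol = rel * max(1.0, dmin)
    tied = np.nonzero(dist <= dmin + tol)[0]
    return int(tied[np.argmin(indices[tied])])


def closest_point(mesh: CorrespondedMesh, q) -> SurfaceQueryResult:
    """Exact closest point on the mesh surface to ``q``; ties broken by
    lowest face index."""
    pt, face, dist = mesh.proximity().query(np.asarray(q, dtype=float))
    inside = False
    if mesh.is_watertight():
        inside = bool(dist[0] > SURFACE_TOL and winding_numbers(mesh, [q])[0] > 0.5)
    return SurfaceQueryResult(point=pt[0], face_index=int(face[0]),
                              distance=float(dist[0]), inside=inside)


# ---------------------------------------------------------------------------
# Containment
# ---------------------------------------------------------------------------

def winding_numbers(mesh: CorrespondedMesh, points, chunk: int = 2_000_000) -> np.ndarray:
    """Generalized winding number of each point w.r.t. the mesh surface.

    Uses the van Oosterom-Strackee solid-angle formula summed over all
    faces; ~1 inside a watertight outward-oriented surface, ~0 outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    n_pts, n_tri = len(points), len(tri)
    w = np.zeros(n_pts)
    rows = max(1, chunk // max(n_tri, 1))
    for s in range(0, n_pts, rows):
        p = points[s : s + rows]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pij,pij->pi", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pij,pij->pi", a, b) * lc
            + np.einsum("pij,pij->pi", b, c) * la
            + np.einsum("pij,pij->pi", c, a) * lb
        )
        w[s : s + rows] = np.arctan2(det, denom).sum(axis=1) / (2.0 * np.pi)
    return w


def is_inside(mesh: CorrespondedMesh, q, tol: float = SURFACE_TOL) -> bool:
    """True iff ``q`` is strictly inside the closed mesh by more than
    ``tol``; the on-surface band |d| <= tol counts as outside."""
    if not mesh.is_watertight():
        raise ValueError(
            "is_inside requires a watertight mesh; use unsigned closest_point "
            "queries for open surfaces"
        )
    q = np.asarray(q, dtype=float)
    _, _, dist = mesh.proximity().query(q)
    if dist[0] <= tol:
        return False
    return bool(winding_numbers(mesh, [q])[0] > 0.5)


def points_inside(mesh: CorrespondedMesh, points, tol: float = SURFACE_TOL) -> np.ndarray:
    """Vectorized :func:`is_inside` over an (n, 3) array."""
    if not mesh.is_watertight():
        raise ValueError("points_inside requires a watertight mesh")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _, _, dist = mesh.proximity().query(points)
    inside = winding_numbers(mesh, points) > 0.5
    return inside & (dist > tol)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def ray_first_hit(mesh: CorrespondedMesh, origins, directions,
                  max_dist: float = np.inf):
    """First intersection of each ray with the mesh (Moller-Trumbore).

    Returns an array of hit distances (np.nan where no hit within
    ``max_dist``).  Barycentric tests use an inclusive epsilon so rays
    passing exactly through vertices or edges register.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = mesh.triangles
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    eps = 1e-9
    out = np.full(len(origins), np.nan)
    for i in range(len(origins)):
        o, d = origins[i], directions[i]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - tri[:, 0]
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= -eps) & (t <= max_dist)
        if hit.any():
            out[i] = max(float(t[hit].min()), 0.0)
    return out


# ---------------------------------------------------------------------------
# Splines
# ---------------------------------------------------------------------------

@dataclass
class Spline:
    """Interpolating natural cubic spline with chord-length parameter on
    [0, 1]; ``closed=True`` gives a periodic spline."""

    control_points: np.ndarray
    closed: bool = False
    _spline: CubicSpline = field(default=None, repr=False, compare=False)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.closed:
            t = np.mod(t, 1.0)
        return self._spline(t)

    def arc_length(self, t0: float = 0.0, t1: float = 1.0, n: int = 2048) -> float:
        """Arc length between parameters by dense chord summation."""
        ts = np.linspace(t0, t1, n + 1)
        pts = self(ts)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def resample(self, n: int, arc_length: bool = True) -> np.ndarray:
        """``n`` points along the spline, equally spaced in arc length
        (or in parameter when ``arc_length=False``)."""
        dense_t = np.linspace(0.0, 1.0, 4096)
        pts = self(dense_t)
        if not arc_length:
            return self(np.linspace(0, 1, n))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] == 0:
            return np.repeat(pts[:1], n, axis=0)
        targets = np.linspace(0.0, cum[-1], n, endpoint=not self.closed)
        ts = np.interp(targets, cum, dense_t)
        return self(ts)


def fit_spline(points, closed: bool = False) -> Spline:
    """Fit an interpolating cubic spline through ordered 3D points.

    Open splines use natural boundary conditions; closed splines are
    periodic (the first point is appended as the last).  The parameter is
    normalized cumulative chord length.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    minimum = 3 if closed else 2
    if len(points) < minimum:
        raise ValueError(f"need at least {minimum} points ({'closed' if closed else 'open'})")
    if closed and np.allclose(points[0], points[-1]):
        points = points[:-1]
    work = np.vstack([points, points[:1]]) if closed else points
    chords = np.linalg.norm(np.diff(work, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValueError("coincident consecutive control points")
    t = np.concatenate([[0.0], np.cumsum(chords)])
    t /= t[-1]
    if len(points) == 2 and not closed:
        # linear limit: cubic through 2 points with natural BC is the segment
        spl = CubicSpline(t, work, axis=0, bc_type="natural")
    else:
        spl = CubicSpline(t, work, axis=0,
                          bc_type="periodic" if closed else "natural")
    return Spline(control_points=points, closed=closed, _spline=spl)


def ensure_outward(mesh: CorrespondedMesh) -> CorrespondedMesh:
    """Return a copy with consistent outward face winding (vertex order is
    untouched; only face windings may flip).  Constructed solids pass
    through this before serving as obstacles, since containment queries
    assume outward orientation."""
    tm = mesh.to_trimesh()
    tm.fix_normals()
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return CorrespondedMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                            bone_label=mesh.bone_label, case_id=mesh.case_id)


def best_fit_plane(points) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal).

    The normal is the smallest-variance principal direction, with a
    deterministic sign (largest-magnitude component positive).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    normal = vt[-1]
    j = int(np.argmax(np.abs(normal)))
    if normal[j] < 0:
        normal = -normal
    return centroid, normal
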