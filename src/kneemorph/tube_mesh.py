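"""Variable-radius tube surfaces around 3D centerlines.

Generalized-cylinder meshing for the cruciate ligaments: orthonormal frames
are estimated along the centerline (Frenet-Serret where the curve bends,
rotation-minimizing transport where it is locally straight), a ring of
vertices is placed in each node's normal-binormal plane at that node's
radius, adjacent rings are stitched with triangles and the ends are capped
so the tube is watertight and can serve as an obstacle for later wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kneemorph.mesh_core import CorrespondedMesh, ensure_outward

#: below this curvature (1/mm) the Frenet normal is numerically undefined
#: and frames fall back to rotation-minimizing transport
CURVATURE_EPS = 1e-6

#: polynomial radius profiles are floored here (mm) so rings stay valid
MIN_RADIUS = 0.1


@dataclass
class TubeMesh:
    """Closed tube surface around a centerline.

    ``frames`` holds per-node orthonormal (tangent, normal, binormal)
    triads; ``surface`` is the capped triangle mesh;
    ``self_intersecting`` flags (but does not repair) tubes whose radius
    exceeds the local radius of curvature.
    """

    centerline: np.ndarray
    radii: np.ndarray
    frames: np.ndarray
    surface: CorrespondedMesh
    n_circumferential: int
    self_intersecting: bool = False


def _tangents(centerline: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    if np.any(np.linalg.norm(np.diff(centerline, axis=0), axis=1) < 1e-14):
        raise ValueError("duplicated consecutive centerline nodes")
    t = np.empty_like(centerline)
    t[1:-1] = centerline[2:] - centerline[:-2]
    if len(centerline) >= 3:
        # second-order one-sided differences at the ends
        t[0] = -3 * centerline[0] + 4 * centerline[1] - centerline[2]
        t[-1] = 3 * centerline[-1] - 4 * centerline[-2] + centerline[-3]
    else:
        t[0] = centerline[1] - centerline[0]
        t[-1] = centerline[-1] - centerline[-2]
    bad = np.linalg.norm(t, axis=1) < 1e-14
    if bad.any():  # collapsed one-sided stencil; fall back to first order
        t[0] = centerline[1] - centerline[0]
        t[-1] = centerline[-1] - centerline[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms < 1e-14):
        raise ValueError("duplicated consecutive centerline nodes")
    return t / norms


def estimate_frames(centerline) -> np.ndarray:
    """Per-node orthonormal (tangent, normal, binormal) triads.

    Where the discrete curvature is significant the normal is the Frenet
    normal (turn direction of the tangent); on straight stretches it is
    propagated by rotation-minimizing (parallel) transport from the
    previous node, which avoids the undefined/flipping frames of the pure
    Frenet construction.  A sign convention keeps successive normals within
    90 degrees of each other.
    """
    centerline = np.atleast_2d(np.asarray(centerline, dtype=float))
    n = len(centerline)
    if n < 2:
        raise ValueError("need at least 2 centerline nodes")
    tang = _tangents(centerline)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)

    frames = np.empty((n, 3, 3))
    frames[:, 0] = tang

    # curvature vector ~ dT/ds by central differences
    normals = np.zeros((n, 3))
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        ds = seg[max(lo, 0):hi].sum() if hi > lo else 1.0
        dT = tang[hi] - tang[lo]
        kvec = dT / max(ds, 1e-300)
        kvec -= np.dot(kvec, tang[i]) * tang[i]
        k = np.linalg.norm(kvec)
        normals[i] = kvec / k if k > CURVATURE_EPS else 0.0

    # seed: first node with defined Frenet normal, else any perpendicular
    prev = None
    for i in range(n):
        if np.linalg.norm(normals[i]) > 0:
            prev = normals[i]
            break
    if prev is None:
        a = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(a, tang[0])) > 0.9:
            a = np.array([1.0, 0.0, 0.0])
        prev = a - np.dot(a, tang[0]) * tang[0]
        prev /= np.linalg.norm(prev)

    for i in range(n):
        cand = normals[i]
        if np.linalg.norm(cand) == 0:
            # rotation-minimizing transport of the previous normal
            cand = prev - np.dot(prev, tang[i]) * tang[i]
            nc = np.linalg.norm(cand)
            if nc < 1e-12:
                cand = np.cross(tang[i], prev)
            cand = cand / np.linalg.norm(cand)
        elif np.dot(cand, prev) < 0 and i > 0:
            # Frenet normal may flip across inflections; keep continuity
            transported = prev - np.dot(prev, tang[i]) * tang[i]
            nt = np.linalg.norm(transported)
            if nt > 1e-12 and np.dot(cand, transported / nt) < 0:
                cand = -cand
        frames[i, 1] = cand
        frames[i, 2] = np.cross(tang[i], cand)
        prev = frames[i, 1]
    # end normals: the one-sided curvature stencil is only first-order
    # accurate, so transport the adjacent interior normal instead
    if n >= 3:
        for i, j in ((0, 1), (n - 1, n - 2)):
            cand = frames[j, 1] - np.dot(frames[j, 1], tang[i]) * tang[i]
            nc = np.linalg.norm(cand)
            if nc > 1e-12:
                frames[i, 1] = cand / nc
                frames[i, 2] = np.cross(tang[i], frames[i, 1])
    return frames


def build_tube(centerline, radii, n_circumferential: int = 24,
               case_id: str = "", label: str = "other") -> TubeMesh:
    """Closed variable-radius tube mesh around the centerline.

    Each node carries a circumferential ring of ``n_circumferential``
    vertices in its normal-binormal plane; adjacent rings are stitched and
    the ends closed by triangle fans around the end nodes.
    """
    centerline = np.atleast_2d(np.asarray(centerline, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float),
                            (len(centerline),)).copy()
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_circumferential < 3:
        raise ValueError("need at least 3 circumferential segments")
    frames = estimate_frames(centerline)
    n, m = len(centerline), n_circumferential
    ang = 2 * np.pi * np.arange(m) / m
    ring_dirs = (
        np.cos(ang)[None, :, None] * frames[:, None, 1]
        + np.sin(ang)[None, :, None] * frames[:, None, 2]
    )
    rings = centerline[:, None, :] + radii[:, None, None] * ring_dirs
    verts = np.vstack([rings.reshape(-1, 3), centerline[0], centerline[-1]])
    cap0, cap1 = n * m, n * m + 1

    faces = []
    for i in range(n - 1):
        for j in range(m):
            j2 = (j + 1) % m
            a, b = i * m + j, i * m + j2
            c, d = (i + 1) * m + j, (i + 1) * m + j2
            faces.append([a, d, b])
            faces.append([a, c, d])
    for j in range(m):
        j2 = (j + 1) % m
        faces.append([cap0, j, j2])                              # start cap
        faces.append([cap1, (n - 1) * m + j2, (n - 1) * m + j])  # end cap
    surface = ensure_outward(
        CorrespondedMesh(verts, np.asarray(faces, dtype=np.int64),
                         bone_label=label, case_id=case_id)
    )

    # self-intersection heuristic: radius exceeding the turn radius
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    flag = False
    for i in range(1, n - 1):
        dT = frames[i + 1, 0] - frames[i - 1, 0]
        ds = seg[i - 1] + seg[i]
        k = np.linalg.norm(dT) / max(ds, 1e-300)
        if k > CURVATURE_EPS and radii[i] * k >= 1.0:
            flag = True
            break
    return TubeMesh(centerline, radii, frames, surface, m,
                    self_intersecting=flag)


def radius_profile_from_polynomial(profile, n_nodes: int,
                                   min_radius: float = MIN_RADIUS):
    """Evaluate a polynomial radius profile at equidistant arc-length
    parameters in [0, 1], flooring at ``min_radius``.

    Returns (radii, floored_indices); the caller may warn on the latter.
    """
    s = np.linspace(0.0, 1.0, n_nodes)
    vals = profile(s)
    if np.all(vals <= 0):
        raise ValueError("radius profile is non-positive everywhere")
    floored = np.nonzero(vals < min_radius)[0]
    return np.maximum(vals, min_radius), floored
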