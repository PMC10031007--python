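"""Elastic wrapping of node chains and node grids over obstacle surfaces.

The shared engine behind meniscus, ligament, tendon and cruciate modeling:
a chain (or grid) of nodes connected by springs is iteratively released to
minimize the discrete elastic energy (sum of squared spring lengths) while
nodes are never allowed to penetrate the obstacle surfaces — penetrating
nodes are returned to the closest point on the penetrated surface (plus any
required stand-off offset).  The converged chain is the taut-string /
shortest-path course of the structure around the joint surfaces.

Numerics: interior nodes are driven toward the mean of their spring
neighbors with red-black successive over-relaxation; the obstacle
projection runs after every sweep; a sweep is accepted only if it does not
increase the energy (otherwise the relaxation factor is halved and the
sweep retried), which makes the recorded energy trace non-increasing by
construction.  Chains additionally converge coarse-to-fine: the chain is
solved at a low node count first and upsampled, which removes the slow
long-wavelength modes of single-level relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kneemorph.mesh_core import (
    CorrespondedMesh,
    TriangleProximity,
    vertex_normals,
)


@dataclass
class RelaxParams:
    """Relaxation settings.

    ``omega`` is the over-relaxation factor of the red-black sweep;
    ``tol`` the max per-node displacement (mm) below which iteration stops;
    ``max_iter`` the sweep budget per resolution level; ``coarse_to_fine``
    enables hierarchical solving for chains.
    """

    omega: float = 1.9
    tol: float = 1e-4
    max_iter: int = 10_000
    coarse_to_fine: bool = True
    penetration_tol: float = 1e-6


@dataclass
class WrapResult:
    """Converged node path (chain) or node grid (membrane).

    ``nodes`` has shape (n, 3) for chains or (rows, cols, 3) for grids;
    ``contact`` marks nodes lying on an obstacle's offset surface at
    convergence; ``energy_trace`` holds the energy after every accepted
    sweep and is non-increasing.
    """

    nodes: np.ndarray
    iterations: int
    final_max_displacement: float
    energy_trace: np.ndarray
    converged: bool
    contact: np.ndarray

    @property
    def length(self) -> float:
        """Polyline length (chains only)."""
        if self.nodes.ndim != 2:
            raise ValueError("length is defined for chains")
        return float(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1).sum())


class _SurfaceField:
    """Signed distance + projection support for one watertight surface."""

    def __init__(self, mesh: CorrespondedMesh):
        self.mesh = mesh
        self.prox = TriangleProximity(mesh.vertices, mesh.faces)
        # lenient normals: penetration-corrected obstacles may carry
        # collapsed triangles; sign decisions near them are guarded by the
        # winding band and depth bound
        self.vnormals = vertex_normals(mesh, strict=False)
        self.fnormals = mesh.face_normals()
        # a point inside a solid at depth d contains a radius-d ball, so
        # depth can never exceed half the smallest bounding-box extent;
        # this guards the pseudo-normal sign against folded slivers on
        # penetration-corrected surfaces
        extents = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        self.depth_bound = float(extents.min()) / 2.0

    def signed(self, points: np.ndarray, exact_above: float = np.inf):
        """Return (signed_distance, closest_point, outward_direction).

        The sign comes from the angle-weighted pseudo-normal at the closest
        point (positive outside); outward_direction is the unit direction
        in which a point must move to increase its clearance.
        ``exact_above`` bounds the distance range needing exact answers.
        """
        points = np.atleast_2d(points)
        cp, face, dist = self.prox.query(points, exact_above=exact_above)
        tri = self.mesh.vertices[self.mesh.faces[face]]
        # barycentric coordinates of cp in its face
        v0 = tri[:, 1] - tri[:, 0]
        v1 = tri[:, 2] - tri[:, 0]
        v2 = cp - tri[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        u = 1.0 - v - w
        vn = self.vnormals[self.mesh.faces[face]]
        pseudo = (
            u[:, None] * vn[:, 0] + v[:, None] * vn[:, 1] + w[:, None] * vn[:, 2]
        )
        pseudo /= np.maximum(np.linalg.norm(pseudo, axis=1, keepdims=True), 1e-300)
        delta = points - cp
        outside = (np.einsum("ij,ij->i", delta, pseudo) >= 0.0) \
            | (dist > self.depth_bound)
        sd = np.where(outside, dist, -dist)
        with np.errstate(invalid="ignore", divide="ignore"):
            radial = delta / dist[:, None]
        outward = np.where(
            (dist > 1e-12)[:, None],
            np.where(outside[:, None], radial, -radial),
            pseudo,
        )
        return sd, cp, outward


@dataclass
class ObstacleSet:
    """Watertight obstacle surfaces with optional per-surface inflation.

    ``inflation`` (mm, >= 0) grows each surface virtually: clearance is the
    signed distance minus the inflation, so wrapped structures keep that
    stand-off everywhere.
    """

    surfaces: list
    inflation: list | None = None
    _fields: list = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.surfaces = list(self.surfaces)
        if self.inflation is None:
            self.inflation = [0.0] * len(self.surfaces)
        self.inflation = [float(x) for x in self.inflation]
        if any(x < 0 for x in self.inflation):
            raise ValueError("inflation must be >= 0")
        if len(self.inflation) != len(self.surfaces):
            raise ValueError("one inflation value per surface")
        for s in self.surfaces:
            if not s.is_watertight():
                raise ValueError(f"obstacle {s.bone_label}/{s.case_id} is not watertight")
        self._fields = [_SurfaceField(s) for s in self.surfaces]

    def __len__(self) -> int:
        return len(self.surfaces)

    def add(self, mesh: CorrespondedMesh, inflation: float = 0.0) -> None:
        if not mesh.is_watertight():
            raise ValueError("obstacle must be watertight")
        self.surfaces.append(mesh)
        self.inflation.append(float(inflation))
        self._fields.append(_SurfaceField(mesh))

    def clearance(self, points: np.ndarray,
                  exact_above: float = np.inf) -> np.ndarray:
        """Min over obstacles of (signed distance - inflation), per point.

        Values below ``exact_above`` are exact; larger clearances may be
        conservatively overestimated (see TriangleProximity.query).
        """
        points = np.atleast_2d(points)
        if not self.surfaces:
            return np.full(len(points), np.inf)
        out = np.full(len(points), np.inf)
        for f, infl in zip(self._fields, self.inflation):
            sd, _, _ = f.signed(points, exact_above=exact_above + infl)
            out = np.minimum(out, sd - infl)
        return out

    def project_strict(self, points: np.ndarray,
                       required: np.ndarray | float = 0.0,
                       tol: float = 1e-9, max_passes: int = 400):
        """Like :meth:`project`, but containment is decided by generalized
        winding numbers (exact for watertight surfaces) instead of the
        pseudo-normal heuristic.  Used for final penetration correction,
        where the no-penetration guarantee must hold to machine tolerance
        even near folded, penetration-corrected geometry.

        After the first pass only the points that were actually moved stay
        active (unmoved, non-violating points cannot start violating static
        obstacles), so the many passes a crevice between two touching
        obstacles needs are cheap.
        """
        from kneemorph.mesh_core import winding_numbers

        points = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        required = np.broadcast_to(np.asarray(required, dtype=float),
                                   (len(points),))
        if not self.surfaces:
            return points, np.zeros(len(points), dtype=bool)
        first_violated = None
        #: pseudo-normal signs are only ever wrong close to the surface
        #: (folded slivers, region-boundary ridges); within this band the
        #: winding number decides, outside it the fast sign is trusted
        winding_band = 2.0
        active = np.arange(len(points))
        for it in range(max_passes):
            pts = points[active]
            req = required[active]
            depth = np.full(len(pts), -np.inf)
            target = pts.copy()
            shift = np.zeros_like(pts)
            for f, infl in zip(self._fields, self.inflation):
                sd_fast, cp, _ = f.signed(
                    pts, exact_above=float(np.max(required)) + infl
                    + winding_band)
                dist = np.abs(sd_fast)
                inside = sd_fast < 0
                near = dist < winding_band
                if near.any():
                    w = winding_numbers(f.mesh, pts[near])
                    inside[near] = w > 0.5
                sd = np.where(inside, -dist, dist)
                viol = (req + infl) - sd
                with np.errstate(invalid="ignore", divide="ignore"):
                    radial = (pts - cp) / dist[:, None]
                outward = np.where(inside[:, None], -radial, radial)
                outward[dist <= 1e-12] = 0.0
                deeper = viol > depth
                depth = np.where(deeper, viol, depth)
                tgt = cp + outward * (req + infl)[:, None]
                target[deeper] = tgt[deeper]
                shift += np.where((viol > tol)[:, None],
                                  viol[:, None] * outward, 0.0)
            violated = depth > tol
            if first_violated is None:
                first_violated = np.zeros(len(points), dtype=bool)
                first_violated[active[violated]] = True
            if not violated.any():
                break
            if it < 5:
                # deepest-obstacle projection (the usual, single-surface case)
                pts[violated] = target[violated]
            else:
                # conflicting constraints: deepest-first ping-pongs between
                # the surfaces; over-relaxed summed corrections slide the
                # point along the crevice toward the feasible seam
                pts[violated] += 1.5 * shift[violated]
            points[active] = pts
            active = active[violated]
        if active.size:
            # crevice between two near-tangent obstacles: iteration rate
            # degenerates, so march the stragglers out along the bisector of
            # the violated outward normals to the first feasible position
            for i in active:
                points[i] = self._rescue(points[i], required[i])
        return points, first_violated

    def _rescue(self, point: np.ndarray, required: float) -> np.ndarray:
        """Deterministic feasibility rescue for one stuck point.

        Points caught in a crevice between touching obstacles cannot escape
        along the penetration normals (the crevice is closed in that
        direction); the way out is sideways along the seam.  Candidate
        directions — the normal bisector, the seam tangents of every
        violated pair, and a fixed lattice fan — are scanned with a growing
        step ladder and the first (smallest-step) winding-exact feasible
        candidate wins.
        """
        from kneemorph.mesh_core import winding_numbers

        def exact_state(p):
            clear = []
            normals = []
            for f, infl in zip(self._fields, self.inflation):
                cp, _face, dist = f.prox.query(p[None, :])
                inside = False
                if dist[0] <= f.depth_bound + 1e-12:
                    inside = bool(winding_numbers(f.mesh, p[None, :])[0] > 0.5)
                sd = -dist[0] if inside else dist[0]
                clear.append(sd - infl)
                d = p - cp[0]
                n = np.linalg.norm(d)
                normals.append((-d / n if inside else d / n) if n > 1e-12
                               else np.array([0.0, 0.0, 1.0]))
            return np.asarray(clear), normals

        clear, normals = exact_state(point)
        if clear.min() >= required - 1e-9:
            return point
        viol_idx = [j for j, c in enumerate(clear) if c < required]
        dirs = []
        bisector = np.sum([normals[j] for j in viol_idx], axis=0)
        if np.linalg.norm(bisector) > 1e-12:
            dirs.append(bisector / np.linalg.norm(bisector))
        for a in range(len(viol_idx)):
            for b in range(a + 1, len(viol_idx)):
                seam = np.cross(normals[viol_idx[a]], normals[viol_idx[b]])
                n = np.linalg.norm(seam)
                if n > 1e-9:
                    dirs.append(seam / n)
                    dirs.append(-seam / n)
        for v in np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                           [0, 0, 1], [0, 0, -1],
                           [1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1],
                           [-1, -1, 1], [-1, 1, -1], [1, -1, -1],
                           [-1, -1, -1]], dtype=float):
            dirs.append(v / np.linalg.norm(v))
        deficit = max(required - clear.min(), 1e-6)
        ladder = np.concatenate([
            deficit * np.array([1.0, 2.0, 4.0, 8.0]),
            np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0]),
        ])
        for t in ladder:
            for d in dirs:
                cand = point + t * d
                c2, _ = exact_state(cand)
                if c2.min() >= required - 1e-9:
                    return cand
        return point

    def project(self, points: np.ndarray, required: np.ndarray | float = 0.0,
                tol: float = 1e-9, max_passes: int = 10):
        """Move points violating their required clearance onto the offset
        surface of the most deeply penetrated obstacle.

        Iterates until every point satisfies its clearance (overlapping
        obstacles may need several passes), so the operation is idempotent.
        Returns (corrected_points, violated_mask_of_first_pass).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        required = np.broadcast_to(np.asarray(required, dtype=float), (len(points),))
        if not self.surfaces:
            return points, np.zeros(len(points), dtype=bool)
        first_violated = None
        band = float(np.max(required)) + 1e-3
        for _ in range(max_passes):
            depth = np.full(len(points), -np.inf)
            target = points.copy()
            for f, infl in zip(self._fields, self.inflation):
                sd, cp, outward = f.signed(points, exact_above=band + infl)
                viol = (required + infl) - sd  # > 0 where clearance violated
                deeper = viol > depth
                depth = np.where(deeper, viol, depth)
                cand = cp + outward * (required + infl)[:, None]
                target[deeper] = cand[deeper]
            violated = depth > tol
            if first_violated is None:
                first_violated = violated.copy()
            if not violated.any():
                break
            points[violated] = target[violated]
        return points, first_violated


class _ProjectionCache:
    """Single-pass projection with per-node clearance certificates.

    After querying a node against an obstacle, the measured clearance
    margin (signed distance - inflation - required) certifies that the node
    cannot violate that obstacle until it has moved by more than the
    margin.  Inside a relaxation loop most nodes move micrometres per sweep
    while sitting far from most obstacles, so re-querying only nodes whose
    certificate has expired removes almost all proximity work without
    weakening the projection.
    """

    #: distances are resolved exactly up to required + horizon; certificates
    #: are capped there, trading query cost against re-query frequency
    HORIZON = 10.0

    def __init__(self, obstacles: ObstacleSet, required, n_points: int):
        self.obstacles = obstacles
        self.required = np.broadcast_to(
            np.asarray(required, dtype=float), (n_points,)).copy()
        self.band = float(self.required.max()) + self.HORIZON
        m = len(obstacles)
        self.last_pos = [np.full((n_points, 3), np.inf) for _ in range(m)]
        self.margin = [np.full(n_points, -np.inf) for _ in range(m)]

    def project(self, points: np.ndarray) -> np.ndarray:
        points = points.copy()
        depth = np.full(len(points), -np.inf)
        target = points.copy()
        for j, (f, infl) in enumerate(zip(self.obstacles._fields,
                                          self.obstacles.inflation)):
            moved = np.linalg.norm(points - self.last_pos[j], axis=1)
            stale = ~(moved < self.margin[j])
            if not stale.any():
                continue
            idx = np.nonzero(stale)[0]
            sd, cp, outward = f.signed(points[idx],
                                       exact_above=self.band + infl)
            self.last_pos[j][idx] = points[idx]
            # reported distances beyond the exactness band may overestimate;
            # cap the certificate at the band so it stays a lower bound
            self.margin[j][idx] = (np.minimum(sd, self.band + infl)
                                   - infl - self.required[idx])
            viol = (self.required[idx] + infl) - sd
            deeper = viol > depth[idx]
            depth[idx] = np.where(deeper, viol, depth[idx])
            tgt = cp + outward * (self.required[idx] + infl)[:, None]
            target[idx[deeper]] = tgt[deeper]
        violated = depth > 1e-9
        points[violated] = target[violated]
        return points


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def _chain_energy(nodes: np.ndarray) -> float:
    seg = np.diff(nodes, axis=0)
    return float(np.einsum("ij,ij->", seg, seg))


def _relax_chain_level(nodes, obstacles, offsets, params):
    """Red-black SOR with post-sweep projection at one resolution level."""
    nodes = nodes.copy()
    n = len(nodes)
    interior = np.arange(1, n - 1)
    reds = interior[interior % 2 == 1]
    blacks = interior[interior % 2 == 0]
    energy = [_chain_energy(nodes)]
    omega = params.omega
    disp = np.inf
    it = 0
    # one projection pass per sweep: where two offset constraints conflict
    # (joint gap narrower than the offset) multiple passes only ping-pong;
    # later sweeps keep correcting.  The cache re-queries only nodes whose
    # last measured clearance no longer certifies them.
    cache = _ProjectionCache(obstacles, offsets[1:-1], n - 2) \
        if len(obstacles) else None
    while it < params.max_iter:
        it += 1
        trial = nodes.copy()
        for group in (reds, blacks):
            mid = 0.5 * (trial[group - 1] + trial[group + 1])
            trial[group] += omega * (mid - trial[group])
        if cache is not None:
            trial[1:-1] = cache.project(trial[1:-1])
        e_new = _chain_energy(trial)
        if e_new <= energy[-1] * (1 + 1e-12) + 1e-15:
            disp = float(np.abs(trial - nodes).max())
            nodes = trial
            energy.append(min(e_new, energy[-1]))
            omega = min(params.omega, omega * 1.5)
            if disp < params.tol:
                break
        else:
            omega *= 0.5
            if omega < 1e-3:
                break
    return nodes, it, disp, np.asarray(energy)


def _resample_polyline(nodes: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(nodes[:1], n, axis=0)
    t = np.linspace(0, cum[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, cum, nodes[:, k])
    return out


def wrap_chain(start, end, obstacles: ObstacleSet, n_nodes: int = 100,
               params: RelaxParams | None = None,
               initial: np.ndarray | None = None) -> WrapResult:
    """Relax an elastic chain of ``n_nodes`` between fixed anchors around
    the obstacles.  With no obstacle contact the result is the straight
    segment; with contact it approaches the taut-string geodesic."""
    return wrap_chain_offset(start, end, obstacles, n_nodes,
                             offset_profile=0.0, params=params, initial=initial)


def wrap_chain_offset(start, end, obstacles: ObstacleSet, n_nodes: int = 100,
                      offset_profile=0.0, params: RelaxParams | None = None,
                      initial: np.ndarray | None = None) -> WrapResult:
    """Elastic chain whose node ``i`` must keep a clearance of
    ``offset_profile[i]`` (mm) from every obstacle surface.

    This is the offset-tube primitive: enforcing an offset of half the
    meniscal height forces the meniscal centerline to wrap around the
    femoral condyle instead of hugging the cartilage.
    """
    params = params or RelaxParams()
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    offsets = np.broadcast_to(
        np.asarray(offset_profile, dtype=float), (n_nodes,)
    ).copy()
    if np.any(offsets < 0):
        raise ValueError("offsets must be >= 0")
    if len(obstacles):
        anchor_clear = obstacles.clearance(np.vstack([start, end]))
        if anchor_clear[0] < offsets[0] - 1e-9 or anchor_clear[1] < offsets[-1] - 1e-9:
            raise ValueError("anchors violate their obstacle clearance")

    def offsets_for(n):
        s = np.linspace(0, 1, n)
        return np.interp(s, np.linspace(0, 1, n_nodes), offsets)

    if initial is not None:
        nodes = _resample_polyline(np.asarray(initial, dtype=float), n_nodes)
        levels = [n_nodes]
    elif params.coarse_to_fine and n_nodes > 9:
        levels = [n_nodes]
        while levels[-1] > 9:
            levels.append(levels[-1] // 2 + 1)
        levels.reverse()
        nodes = np.linspace(start, end, levels[0])
    else:
        levels = [n_nodes]
        nodes = np.linspace(start, end, n_nodes)

    total_it = 0
    energy_trace = None
    disp = np.inf
    for li, n in enumerate(levels):
        if len(nodes) != n:
            nodes = _resample_polyline(nodes, n)
        nodes[0], nodes[-1] = start, end
        off = offsets_for(n)
        if len(obstacles):
            nodes[1:-1], _ = obstacles.project(nodes[1:-1], off[1:-1],
                                               tol=params.penetration_tol)
        nodes, it, disp, energy = _relax_chain_level(nodes, obstacles, off, params)
        total_it += it
        energy_trace = energy  # keep the finest level's trace
    if len(obstacles):
        # hard guarantee: whatever the offset bookkeeping did, no interior
        # node may remain strictly inside an obstacle
        nodes[1:-1], _ = obstacles.project_strict(nodes[1:-1], 0.0,
                                                  tol=params.penetration_tol)
    contact = np.zeros(len(nodes), dtype=bool)
    if len(obstacles):
        off = offsets_for(len(nodes))
        clr = obstacles.clearance(nodes, exact_above=float(off.max()) + 0.01)
        contact = clr <= off + 10 * params.tol
    return WrapResult(
        nodes=nodes,
        iterations=total_it,
        final_max_displacement=float(disp),
        energy_trace=energy_trace,
        converged=bool(disp < params.tol),
        contact=contact,
    )


# ---------------------------------------------------------------------------
# Membranes (node grids)
# ---------------------------------------------------------------------------

def _row_springs(grid: np.ndarray, periodic: bool):
    """Transverse (row-direction) spring vectors: grid[:, j+1] - grid[:, j],
    including the wrap-around spring when periodic."""
    dc = np.diff(grid, axis=1)
    if periodic:
        wrap = (grid[:, :1] - grid[:, -1:])
        dc = np.concatenate([dc, wrap], axis=1)
    return dc


def _grid_energy(grid: np.ndarray, periodic: bool, row_rest: np.ndarray) -> float:
    """Membrane energy: zero-rest-length fiber (column) springs keep the
    fibers taut; transverse (row) springs carry the rest lengths of the
    initial ruled surface so the membrane does not contract laterally."""
    dr = np.diff(grid, axis=0)
    e = float(np.einsum("ijk,ijk->", dr, dr))
    dc = _row_springs(grid, periodic)
    stretch = np.linalg.norm(dc, axis=2) - row_rest
    e += float(np.einsum("ij,ij->", stretch, stretch))
    return e


def _grid_spring_target(grid: np.ndarray, periodic: bool,
                        row_rest: np.ndarray):
    """Per-node locally optimal position: mean of the zero-rest column
    neighbors and the rest-length row-neighbor targets.

    ``row_rest[i, j]`` is the rest length of the spring between columns
    ``j`` and ``j+1`` (the last entry wraps around when periodic).
    """
    rows, cols, _ = grid.shape
    acc = np.zeros_like(grid)
    cnt = np.zeros((rows, cols, 1))
    acc[1:] += grid[:-1]
    cnt[1:] += 1
    acc[:-1] += grid[1:]
    cnt[:-1] += 1

    def rest_target(node, neighbor, rest):
        d = node - neighbor
        ln = np.linalg.norm(d, axis=2, keepdims=True)
        unit = np.where(ln > 1e-12, d / np.maximum(ln, 1e-300), 0.0)
        return neighbor + unit * rest[..., None]

    if periodic:
        left = np.roll(grid, 1, axis=1)
        right = np.roll(grid, -1, axis=1)
        acc += rest_target(grid, left, np.roll(row_rest, 1, axis=1))
        acc += rest_target(grid, right, row_rest)
        cnt += 2
    else:
        # spring j connects columns j and j+1 with rest row_rest[:, j]
        acc[:, 1:] += rest_target(grid[:, 1:], grid[:, :-1], row_rest)
        cnt[:, 1:] += 1
        acc[:, :-1] += rest_target(grid[:, :-1], grid[:, 1:], row_rest)
        cnt[:, :-1] += 1
    return acc / cnt


def wrap_membrane(origin_curve, insertion_curve, obstacles: ObstacleSet,
                  n_rows: int = 30, params: RelaxParams | None = None,
                  periodic: bool = False) -> WrapResult:
    """Relax an elastic membrane spanning two boundary curves.

    Column ``j`` of the (n_rows x n_cols) node grid connects
    ``origin_curve[j]`` to ``insertion_curve[j]``; the two boundary rows
    stay fixed.  Springs run along both grid directions; ``periodic=True``
    additionally connects the last column back to the first (closed
    sleeves, e.g. the patellar tendon).
    """
    params = params or RelaxParams()
    origin_curve = np.atleast_2d(np.asarray(origin_curve, dtype=float))
    insertion_curve = np.atleast_2d(np.asarray(insertion_curve, dtype=float))
    if len(origin_curve) != len(insertion_curve):
        raise ValueError("boundary curves must have the same point count")
    if len(origin_curve) < 2:
        raise ValueError("boundary curves need at least 2 points")
    if n_rows < 3:
        raise ValueError("need at least 3 rows")
    if len(obstacles):
        clr = obstacles.clearance(np.vstack([origin_curve, insertion_curve]))
        if np.any(clr < -params.penetration_tol):
            raise ValueError("boundary anchors penetrate an obstacle")

    cols = len(origin_curve)
    t = np.linspace(0, 1, n_rows)[:, None, None]
    grid = (1 - t) * origin_curve[None] + t * insertion_curve[None]
    # transverse rest lengths from the ruled surface keep the strip from
    # contracting laterally while the zero-rest fiber springs stay taut
    row_rest = np.linalg.norm(_row_springs(grid, periodic), axis=2)
    if len(obstacles):
        inner = grid[1:-1].reshape(-1, 3)
        proj, _ = obstacles.project(inner, 0.0, tol=params.penetration_tol)
        grid[1:-1] = proj.reshape(n_rows - 2, cols, 3)

    rows_idx, cols_idx = np.meshgrid(np.arange(n_rows), np.arange(cols),
                                     indexing="ij")
    red = ((rows_idx + cols_idx) % 2 == 0)
    black = ~red
    free = np.ones((n_rows, cols), dtype=bool)
    free[0] = free[-1] = False

    energy = [_grid_energy(grid, periodic, row_rest)]
    omega = params.omega
    disp = np.inf
    it = 0
    cache = _ProjectionCache(obstacles, 0.0, int(free.sum())) \
        if len(obstacles) else None
    while it < params.max_iter:
        it += 1
        trial = grid.copy()
        for mask in (red & free, black & free):
            mean = _grid_spring_target(trial, periodic, row_rest)
            trial[mask] += omega * (mean[mask] - trial[mask])
        if cache is not None:
            trial[free] = cache.project(trial[free])
        e_new = _grid_energy(trial, periodic, row_rest)
        if e_new <= energy[-1] * (1 + 1e-12) + 1e-15:
            disp = float(np.abs(trial - grid).max())
            grid = trial
            energy.append(min(e_new, energy[-1]))
            omega = min(params.omega, omega * 1.5)
            if disp < params.tol:
                break
        else:
            omega *= 0.5
            if omega < 1e-3:
                break
    if len(obstacles):
        grid[free], _ = obstacles.project_strict(grid[free], 0.0,
                                                 tol=params.penetration_tol)
    contact = np.zeros((n_rows, cols), dtype=bool)
    if len(obstacles):
        clr = obstacles.clearance(grid.reshape(-1, 3),
                                  exact_above=0.01).reshape(n_rows, cols)
        contact = clr <= 10 * params.tol
    return WrapResult(
        nodes=grid,
        iterations=it,
        final_max_displacement=float(disp),
        energy_trace=np.asarray(energy),
        converged=bool(disp < params.tol),
        contact=contact,
    )


def grid_to_mesh(grid: np.ndarray, periodic: bool = False):
    """Triangulate a (rows, cols, 3) node grid into vertices and faces."""
    rows, cols, _ = grid.shape
    verts = grid.reshape(-1, 3)
    faces = []
    ncols = cols if periodic else cols - 1
    for i in range(rows - 1):
        for j in range(ncols):
            j2 = (j + 1) % cols
            a = i * cols + j
            b = i * cols + j2
            c = (i + 1) * cols + j
            d = (i + 1) * cols + j2
            faces.append([a, b, d])
            faces.append([a, d, c])
    return verts, np.asarray(faces, dtype=np.int64)


def project_out(points, obstacles: ObstacleSet, required=0.0) -> np.ndarray:
    """Move any point inside an obstacle (or violating ``required``
    clearance) to the closest point on the offending surface; points
    already clear are unchanged; idempotent."""
    pts, _ = obstacles.project_strict(
        np.atleast_2d(np.asarray(points, dtype=float)), required)
    return pts
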