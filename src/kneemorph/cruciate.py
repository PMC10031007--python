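"""Cruciate ligaments as variable-radius tubes on spring-chain centerlines.

The ACL centerline runs from its femoral origin to its tibial insertion as
a chain of 15 connected spring elements whose position is optimized as a
shortest path; the connecting nodes are spatially constrained to a minimal
offset from the surrounding surfaces (comparable to the ligament's own
width) so the tube fitted around the centerline does not sink into bone or
cartilage.  Regional variation in thickness along the course comes from a
low-degree polynomial radius profile.  The finished ACL tube then joins the
obstacle set, and the PCL is modeled the same way, wrapping around the ACL
on its way from origin to insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kneemorph.profiles import PolynomialProfile, ProfileSamples
from kneemorph.tube_mesh import TubeMesh, build_tube, radius_profile_from_polynomial
from kneemorph.wrap_engine import ObstacleSet, RelaxParams, WrapResult, wrap_chain_offset

#: number of spring elements forming each cruciate centerline
DEFAULT_N_SEGMENTS = 15

#: polynomial degrees of the radius profiles (sensitivity analysis)
RADIUS_DEGREES = {"ACL": 2, "PCL": 4}


@dataclass
class CruciateModel:
    """One cruciate ligament: spring-chain centerline + fitted tube."""

    name: str
    centerline: WrapResult
    radius_profile: PolynomialProfile
    tube: TubeMesh
    min_offset: float


def default_radius_degrees() -> dict[str, int]:
    """Radius-profile polynomial degrees: ACL 2, PCL 4."""
    return dict(RADIUS_DEGREES)


def radius_degree(name: str) -> int:
    try:
        return RADIUS_DEGREES[name]
    except KeyError:
        raise KeyError(f"unknown cruciate {name!r}; expected ACL or PCL") from None


def thickness_samples_from_slices(positions, thicknesses,
                                  structure_label: str = "") -> ProfileSamples:
    """Convert per-slice MRI thickness measurements to radius samples.

    Slice positions (monotone increasing along the ligament course) are
    normalized to relative position in [0, 1]; radii are thickness / 2.
    """
    positions = np.asarray(positions, dtype=float)
    thicknesses = np.asarray(thicknesses, dtype=float)
    if len(positions) < 2:
        raise ValueError("need at least 2 slices")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("slice positions must be strictly increasing")
    s = (positions - positions[0]) / (positions[-1] - positions[0])
    return ProfileSamples(s, thicknesses / 2.0, structure_label)


def predict_cruciate(name: str, origin, insertion, obstacles: ObstacleSet,
                     radius_profile: PolynomialProfile,
                     n_segments: int = DEFAULT_N_SEGMENTS,
                     min_offset: float | None = None,
                     n_circumferential: int = 24,
                     params: RelaxParams | None = None,
                     case_id: str = "") -> CruciateModel:
    """Build one cruciate ligament tube.

    ``n_segments`` spring elements give ``n_segments + 1`` centerline
    nodes; every node keeps at least ``min_offset`` clearance from all
    obstacles (default: the mean radius of the profile, a stand-in for the
    ligament's own half-width).  For the PCL the caller appends the built
    ACL tube to ``obstacles`` so the PCL wraps around it.
    """
    if name not in RADIUS_DEGREES:
        raise KeyError(f"unknown cruciate {name!r}; expected ACL or PCL")
    n_nodes = n_segments + 1
    radii, _floored = radius_profile_from_polynomial(radius_profile, n_nodes)
    if min_offset is None:
        min_offset = float(radii.mean())
    # the offset constrains the connecting nodes *between* spring elements;
    # the endpoints are the attachments themselves and sit on bone
    offsets = np.full(n_nodes, float(min_offset))
    offsets[0] = offsets[-1] = 0.0
    centerline = wrap_chain_offset(
        np.asarray(origin, dtype=float), np.asarray(insertion, dtype=float),
        obstacles, n_nodes=n_nodes, offset_profile=offsets, params=params,
    )
    tube = build_tube(centerline.nodes, radii,
                      n_circumferential=n_circumferential,
                      case_id=case_id, label=f"cruciate_{name}")
    if len(obstacles):
        # local penetration correction, as for the meniscal wedge: tube
        # vertices found inside an obstacle move to its surface (the tube
        # radius may exceed the centerline offset, e.g. near attachments)
        corrected, _ = obstacles.project_strict(tube.surface.vertices, 0.0)
        tube.surface = tube.surface.with_vertices(corrected)
    return CruciateModel(name, centerline, radius_profile, tube,
                         float(min_offset))
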