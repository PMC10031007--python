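"""Surface-distance metrics and the leave-one-out validation driver.

Predicted geometry is compared with the case's measured geometry by
nearest-neighbor distances from the reference points to the prediction:
RMSE (root of the mean squared distance), ASD (average surface distance,
the plain mean) and HD (Hausdorff distance, the maximum).  The comparison
is one-directional, reference -> predicted, by default.  Leave-one-out
validation builds the model from all cases but one, predicts the held-out
case, and pools the per-case metrics as median with (min-max) range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from kneemorph.cartilage import ThicknessMap
from kneemorph.mesh_core import CorrespondedMesh


@dataclass
class DistanceReport:
    """Per-point distances (mm) with their RMSE / ASD / HD summary.

    For non-negative distances the power-mean inequality guarantees
    asd <= rmse <= hd, which is asserted at construction.
    """

    distances: np.ndarray
    rmse: float
    asd: float
    hd: float
    n: int

    @classmethod
    def from_distances(cls, distances) -> "DistanceReport":
        d = np.asarray(distances, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("no distances to summarize")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        hd = float(np.max(d))
        asd = float(np.mean(d))
        # scale by the max before squaring so extreme magnitudes neither
        # underflow nor overflow
        rmse = hd * float(np.sqrt(np.mean((d / hd) ** 2))) if hd > 0 else 0.0
        assert asd <= rmse * (1 + 1e-12) and rmse <= hd * (1 + 1e-12)
        return cls(distances=d, rmse=rmse, asd=asd, hd=hd, n=int(d.size))


def compare_points_to_surface(predicted, reference_points,
                              symmetric: bool = False) -> DistanceReport:
    """Distance from each reference point to the predicted geometry.

    ``predicted`` may be a :class:`CorrespondedMesh` (exact point-to-surface
    distances) or a point set (nearest-neighbor distances).  With
    ``symmetric=True`` the reverse direction is pooled in as well
    (point-set predictions only need the forward KD-tree swapped).
    """
    reference_points = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if reference_points.size == 0:
        raise ValueError("empty reference point set")
    if isinstance(predicted, CorrespondedMesh):
        _, _, d = predicted.proximity().query(reference_points)
        if symmetric:
            tree = cKDTree(reference_points)
            back, _ = tree.query(predicted.vertices)
            d = np.concatenate([d, back])
        return DistanceReport.from_distances(d)
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if predicted.size == 0:
        raise ValueError("empty predicted point set")
    d, _ = cKDTree(predicted).query(reference_points)
    if symmetric:
        back, _ = cKDTree(reference_points).query(predicted)
        d = np.concatenate([d, back])
    return DistanceReport.from_distances(d)


def compare_thickness_maps(predicted: ThicknessMap,
                           measured: ThicknessMap) -> DistanceReport:
    """Value-space comparison of two thickness maps over the same region:
    per-vertex absolute thickness differences summarized as RMSE/ASD/HD."""
    if not predicted.same_region(measured):
        raise ValueError("maps cover different regions")
    return DistanceReport.from_distances(np.abs(predicted.values - measured.values))


def leave_one_out(cases: list, builder, predictor):
    """Leave-one-out validation over a cohort.

    For each case i, ``builder(cases_without_i)`` constructs the model and
    ``predictor(model, case_i)`` returns a :class:`DistanceReport` for the
    held-out case.  Returns (per_case_reports, pooled) where pooled maps
    each metric to its (median, min, max) across cases.
    """
    if len(cases) < 2:
        raise ValueError("leave-one-out needs at least 2 cases")
    reports = []
    for i in range(len(cases)):
        training = cases[:i] + cases[i + 1:]
        model = builder(training)
        reports.append(predictor(model, cases[i]))
    pooled = {}
    for metric in ("rmse", "asd", "hd"):
        vals = np.array([getattr(r, metric) for r in reports])
        pooled[metric] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return reports, pooled


def pointwise_error_map(per_case_errors) -> np.ndarray:
    """Mean per-vertex error magnitude across corresponded cases (the
    point-dependent error map highlighting high-variation regions)."""
    arrs = [np.asarray(e, dtype=float) for e in per_case_errors]
    if not arrs:
        raise ValueError("no error vectors")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("error vectors are not corresponded (length mismatch)")
    return np.mean(np.stack(arrs), axis=0)
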