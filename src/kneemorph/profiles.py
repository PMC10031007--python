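"""Polynomial profiles of anatomy versus relative position.

Meniscal height and width are measured repeatedly along the meniscus from
the anterior to the posterior root, cruciate thickness along the ligament
course from origin to insertion; each series is summarized as a polynomial
of the relative position s in [0, 1].  The polynomial degree is selected by
a sensitivity analysis against a deliberately over-fitted 20th-degree
reference: the RMSE between the degree-d fit and the reference, evaluated
on a dense grid, drops steeply until d reaches the structure's intrinsic
complexity and flattens after; the selected degree is the elbow of that
curve.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as P

STRUCTURE_LABELS = ("MM_height", "MM_width", "LM_height", "LM_width",
                    "ACL_radius", "PCL_radius")

#: degrees selected by the sensitivity analysis on the study cohort:
#: medial meniscus height/width 6/4, lateral meniscus height/width 4/4,
#: ACL radius 2, PCL radius 4.
DEFAULT_DEGREES = {
    "MM_height": 6,
    "MM_width": 4,
    "LM_height": 4,
    "LM_width": 4,
    "ACL_radius": 2,
    "PCL_radius": 4,
}


@dataclass
class ProfileSamples:
    """Measured (relative position, value) pairs for one structure."""

    s: np.ndarray
    values: np.ndarray
    structure_label: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.s) != len(self.values):
            raise ValueError("s and values must have equal length")
        if len(self.s) < 2:
            raise ValueError("need at least 2 samples")
        if self.s.min() < 0 or self.s.max() > 1:
            raise ValueError("relative positions must lie in [0, 1]")
        if np.any(self.values < 0):
            raise ValueError("negative measurement")

    @classmethod
    def from_csv(cls, path, structure_label: str | None = None) -> "ProfileSamples":
        s, values, label = [], [], structure_label
        with open(path) as fh:
            for row in csv.DictReader(fh):
                if label is not None and row.get("label", label) != label:
                    continue
                s.append(float(row["s"]))
                values.append(float(row["value_mm"]))
                label = label or row.get("label", "")
        return cls(np.asarray(s), np.asarray(values), label or "")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s", "value_mm", "label"])
            for si, vi in zip(self.s, self.values):
                w.writerow([repr(float(si)), repr(float(vi)), self.structure_label])


@dataclass
class PolynomialProfile:
    """Power-basis polynomial value(s) in mm over s in [0, 1].

    ``coefficients`` are ascending-degree; ``fit_rmse`` is the residual of
    the fit; ``reference_rmse`` the RMSE against the over-fitted reference
    polynomial used by degree selection (NaN when not computed).
    """

    coefficients: np.ndarray
    fit_rmse: float = float("nan")
    reference_rmse: float = float("nan")
    structure_label: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, s) -> np.ndarray:
        return P.polyval(np.asarray(s, dtype=float), self.coefficients)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "coefficients": list(map(float, self.coefficients)),
            "fit_rmse": self.fit_rmse,
            "reference_rmse": self.reference_rmse,
            "structure_label": self.structure_label,
        }))

    @classmethod
    def from_json(cls, path) -> "PolynomialProfile":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["coefficients"]), d.get("fit_rmse", float("nan")),
                   d.get("reference_rmse", float("nan")),
                   d.get("structure_label", ""))


def fit_polynomial(samples: ProfileSamples, degree: int) -> PolynomialProfile:
    """Least-squares polynomial of the given degree through the samples.

    The fit runs in a Chebyshev basis (mapped to [0, 1]) for conditioning
    and is converted back to power-basis coefficients.
    """
    distinct = len(np.unique(samples.s))
    if degree >= distinct:
        raise ValueError(
            f"degree {degree} underdetermined by {distinct} distinct positions"
        )
    x = 2.0 * samples.s - 1.0  # map [0,1] -> [-1,1]
    cheb = np.polynomial.chebyshev.Chebyshev.fit(x, samples.values, degree,
                                                 domain=[-1, 1])
    power_in_x = cheb.convert(kind=np.polynomial.polynomial.Polynomial)
    # substitute x = 2 s - 1
    shifted = power_in_x(np.polynomial.polynomial.Polynomial([-1.0, 2.0]))
    coeffs = np.zeros(degree + 1)
    coeffs[: len(shifted.coef)] = shifted.coef
    resid = P.polyval(samples.s, coeffs) - samples.values
    rmse = float(np.sqrt(np.mean(resid**2)))
    return PolynomialProfile(coeffs, fit_rmse=rmse,
                             structure_label=samples.structure_label)


def select_degree(samples: ProfileSamples, max_degree: int = 10,
                  reference_degree: int = 20,
                  improvement_tol: float = 0.05,
                  grid_n: int = 1000) -> int:
    """Pick the lowest adequate polynomial degree by sensitivity analysis.

    A deliberately over-fitted ``reference_degree`` polynomial stands in
    for ground truth.  For every degree d the RMSE between the degree-d fit
    and the reference on a dense grid is computed; the selected degree is
    the first d whose improvement over d-1 falls below ``improvement_tol``
    times the degree-0 RMSE (an explicit elbow rule).  If the samples
    cannot support the reference degree it is lowered to n_distinct - 1.
    """
    distinct = len(np.unique(samples.s))
    ref_deg = min(reference_degree, distinct - 1)
    max_degree = min(max_degree, ref_deg - 1)
    if max_degree < 0:
        raise ValueError("too few samples for any comparison fit")
    reference = fit_polynomial(samples, ref_deg)
    grid = np.linspace(samples.s.min(), samples.s.max(), grid_n)
    ref_vals = reference(grid)

    rmses = []
    for d in range(max_degree + 1):
        fit = fit_polynomial(samples, d)
        rmses.append(float(np.sqrt(np.mean((fit(grid) - ref_vals) ** 2))))
    scale = rmses[0]
    if scale <= 1e-12:
        return 0
    for d in range(1, max_degree + 1):
        improvement = rmses[d - 1] - rmses[d]
        if improvement < improvement_tol * scale:
            return d - 1
    return max_degree


def default_profiles() -> dict[str, int]:
    """Default polynomial degrees per structure (from the cohort
    sensitivity analysis): ACL 2, PCL 4, medial meniscus height/width 6/4,
    lateral meniscus height/width 4/4."""
    return dict(DEFAULT_DEGREES)
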