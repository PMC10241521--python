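"""Cleavage-plane angle and symmetric/asymmetric division classification.

In a neural-rosette section, each mitotic cell contributes a pair of
centrosome points outside the lumen. The cleavage angle θ is measured
against the tangent of the lumen boundary at the boundary point nearest
the pair midpoint:

    a = perpendicular distance of the farthest centrosome from the tangent
    b = distance from that centrosome to the intersection of the
        centrosome line with the tangent
    θ = arccos(a / b)                       (degrees)

arccos(a/b) lives in [0, 90]; the full [0, 180) range is recovered by a
directed convention: the centrosome axis is directed from the tangent
intersection toward the farthest centrosome and measured from the
outward lumen normal, signed by the counter-clockwise tangent direction.
arccos(a/b) then equals min(θ, 180−θ), and θ also equals the angle
between the centrosome axis and the lumen-surface normal.

Divisions with 45° ≤ θ ≤ 135° are vertical/symmetric; the rest
(0°–45°, 135°–180°) are horizontal/asymmetric. The stated intervals are
open at 45°/135°, leaving the boundaries unassigned; they are assigned
to symmetric here (configurable).

All 2D points in this module are ``(x, y)`` physical µm (the shapely
convention); note this is the reverse of the ``(y, x)`` image-axis
order used for raster data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "TangentLine",
    "DivisionRecord",
    "RosetteScene",
    "lumen_tangent",
    "cleavage_angle",
    "classify_division",
    "measure_rosette",
    "division_contingency",
    "ContingencyResult",
]

SYMMETRIC = "symmetric"
ASYMMETRIC = "asymmetric"


@dataclass(frozen=True)
class TangentLine:
    """Tangent to the lumen boundary at a boundary point.

    ``direction`` follows the counter-clockwise boundary orientation;
    ``normal`` points outward (away from the lumen interior).
    """

    point: tuple[float, float]
    direction: tuple[float, float]
    normal: tuple[float, float]


@dataclass(frozen=True)
class DivisionRecord:
    mitosis_id: int | str
    a_um: float
    b_um: float
    theta_deg: float
    division_class: str


@dataclass
class RosetteScene:
    """A 2D rosette section: lumen polygon plus per-mitosis centrosome pairs."""

    lumen_xy_um: np.ndarray  # (N, 2) polygon vertices, µm
    pairs: list[tuple[tuple[float, float], tuple[float, float]]]
    section_id: str = ""

    def __post_init__(self):
        self.lumen_xy_um = np.asarray(self.lumen_xy_um, dtype=float)
        poly = Polygon(self.lumen_xy_um)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("lumen polygon must be simple, closed and non-degenerate")


def _ccw_vertices(lumen_xy_um: np.ndarray) -> np.ndarray:
    verts = np.asarray(lumen_xy_um, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("lumen polygon needs >= 3 (x, y) vertices")
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    poly = Polygon(verts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate lumen polygon")
    # shoelace signed area: positive = counter-clockwise
    x, y = verts[:, 0], verts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        verts = verts[::-1]
    return verts


def lumen_tangent(
    lumen_xy_um: np.ndarray, at: Sequence[float], window: int = 11
) -> TangentLine:
    """Tangent of the lumen boundary at the vertex nearest to ``at``.

    The direction is smoothed over ``window`` vertices (symmetric
    central differences), which makes it exact on regularly discretised
    circles and robust to vertex jitter otherwise; it is invariant
    under re-indexing (rotation) of the vertex list.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    verts = _ccw_vertices(lumen_xy_um)
    at = np.asarray(at, dtype=float)
    n = len(verts)
    i = int(np.argmin(((verts - at) ** 2).sum(axis=1)))
    m = min(window // 2, (n - 1) // 2)
    # smoothed local direction: sum of symmetric chords through vertex i
    direction = np.zeros(2)
    for k in range(1, m + 1):
        direction += verts[(i + k) % n] - verts[(i - k) % n]
    norm = float(np.hypot(*direction))
    if norm == 0:
        raise ValueError("degenerate boundary: zero tangent direction")
    direction /= norm
    normal = np.array([direction[1], -direction[0]])  # outward for CCW boundary
    return TangentLine(
        point=(float(verts[i, 0]), float(verts[i, 1])),
        direction=(float(direction[0]), float(direction[1])),
        normal=(float(normal[0]), float(normal[1])),
    )


def cleavage_angle(
    p1: Sequence[float],
    p2: Sequence[float],
    tangent: TangentLine,
    mitosis_id: int | str = -1,
    boundary_to_symmetric: bool = True,
) -> DivisionRecord:
    """Compute a, b, θ for one centrosome pair and classify the division.

    When the centrosome line is parallel to the tangent, a/b → 0 and
    θ = 90° by continuity (b is reported as ``inf``).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.array_equal(p1, p2):
        raise ValueError("coincident centrosome points")
    t0 = np.asarray(tangent.point)
    t_hat = np.asarray(tangent.direction)
    n_hat = np.asarray(tangent.normal)

    s1 = float(np.dot(p1 - t0, n_hat))  # signed distances from the tangent
    s2 = float(np.dot(p2 - t0, n_hat))
    if s1 == 0.0 and s2 == 0.0:
        raise ValueError("both centrosomes lie on the tangent: geometry undefined")
    far, s_far = (p2, s2) if abs(s2) >= abs(s1) else (p1, s1)
    a = abs(s_far)

    u = p2 - p1
    un = float(np.dot(u, n_hat))
    if math.isclose(un, 0.0, abs_tol=1e-15 * float(np.linalg.norm(u))) or un == 0.0:
        theta = 90.0
        b = math.inf
    else:
        t_star = -s1 / un  # line(p1,p2) meets the tangent at p1 + t_star*u
        crossing = p1 + t_star * u
        v = far - crossing
        b = float(np.linalg.norm(v))
        vt = float(np.dot(v, t_hat))
        vn = float(np.dot(v, n_hat))
        theta = math.degrees(math.atan2(vt, vn))
        if theta < 0.0:
            theta += 180.0
        # identity: arccos(a/b) == min(theta, 180 - theta)
        assert abs(math.degrees(math.acos(min(a / b, 1.0))) - min(theta, 180.0 - theta)) < 1e-6
    return DivisionRecord(
        mitosis_id=mitosis_id,
        a_um=a,
        b_um=b,
        theta_deg=theta,
        division_class=classify_division(theta, boundary_to_symmetric),
    )


def classify_division(theta_deg: float, boundary_to_symmetric: bool = True) -> str:
    """Classify a cleavage angle as symmetric (vertical) or asymmetric.

    Symmetric for 45° < θ < 135°; asymmetric for 0° ≤ θ < 45° and
    135° < θ < 180°. The boundaries 45°/135° go to symmetric by default.
    """
    theta = float(theta_deg)
    if not (0.0 <= theta < 180.0):
        raise ValueError(f"theta_deg must lie in [0, 180), got {theta}")
    if boundary_to_symmetric:
        return SYMMETRIC if 45.0 <= theta <= 135.0 else ASYMMETRIC
    return SYMMETRIC if 45.0 < theta < 135.0 else ASYMMETRIC


def measure_rosette(
    scene: RosetteScene,
    window: int = 11,
    boundary_to_symmetric: bool = True,
) -> list[DivisionRecord]:
    """Measure every centrosome pair in a rosette scene."""
    records = []
    for k, (q1, q2) in enumerate(scene.pairs):
        mid = 0.5 * (np.asarray(q1, dtype=float) + np.asarray(q2, dtype=float))
        tangent = lumen_tangent(scene.lumen_xy_um, mid, window=window)
        records.append(
            cleavage_angle(
                q1, q2, tangent, mitosis_id=k,
                boundary_to_symmetric=boundary_to_symmetric,
            )
        )
    return records


@dataclass
class ContingencyResult:
    counts: pd.DataFrame       # rows: groups; columns: symmetric, asymmetric
    percentages: pd.DataFrame
    chi2: float
    p_value: float
    dof: int


def division_contingency(
    records_by_group: Mapping[str, Sequence[DivisionRecord]]
) -> ContingencyResult:
    """Per-group symmetric/asymmetric contingency with Pearson chi-square.

    The chi-square is computed on the raw counts without continuity
    correction (two or more groups required, each non-empty).
    """
    if len(records_by_group) < 2:
        raise ValueError("contingency requires >= 2 groups")
    rows = {}
    for group, records in records_by_group.items():
        records = list(records)
        if not records:
            raise ValueError(f"group {group!r} has zero records")
        n_sym = sum(r.division_class == SYMMETRIC for r in records)
        rows[group] = {SYMMETRIC: n_sym, ASYMMETRIC: len(records) - n_sym}
    counts = pd.DataFrame.from_dict(rows, orient="index")[[SYMMETRIC, ASYMMETRIC]]
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    chi2, p, dof, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return ContingencyResult(
        counts=counts, percentages=percentages,
        chi2=float(chi2), p_value=float(p), dof=int(dof),
    )
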