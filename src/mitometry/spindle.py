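"""Mitotic spindle angle and inter-centrosomal distance.

The spindle axis is the line through the two spindle-pole (centrosome)
spots. With ``D`` the in-plane (xy) separation and ``h`` the axial (z)
separation of the poles, the spindle angle relative to the culture-dish
plane is

    alpha = arctan(h / D)        (degrees, in [0, 90])

and the inter-centrosomal distance is

    ICD = D / cos(alpha) = sqrt(D^2 + h^2),

i.e. the 3D Euclidean separation of the poles. ICD is computed as the
Euclidean norm; the trigonometric identity is asserted for alpha < 90.

Points are 3D physical coordinates in µm, ordered ``(z, y, x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import SpotSet

__all__ = [
    "CentrosomePair",
    "spindle_angle",
    "intercentrosomal_distance",
    "measure_spindles",
]


def _separations(p1, p2) -> tuple[float, float]:
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != (3,) or p2.shape != (3,):
        raise ValueError("points must be 3D (z, y, x) in µm")
    if np.array_equal(p1, p2):
        raise ValueError("coincident centrosome points: spindle axis undefined")
    dz, dy, dx = p2 - p1
    d = math.hypot(dy, dx)
    h = abs(dz)
    return d, h


def spindle_angle(p1, p2) -> float:
    """Spindle angle alpha = arctan(h/D) in degrees, in [0, 90].

    ``D = 0`` with ``h > 0`` (a spindle standing perpendicular to the
    dish) gives 90° by continuity via atan2, not an error.
    """
    d, h = _separations(p1, p2)
    return math.degrees(math.atan2(h, d))


def intercentrosomal_distance(p1, p2) -> float:
    """Inter-centrosomal distance in µm (3D Euclidean separation).

    Identical to D/cos(alpha); the identity is asserted to 1e-9 µm
    whenever alpha < 90°.
    """
    d, h = _separations(p1, p2)
    icd = math.hypot(d, h)
    if d > 0.0:
        alpha = math.atan2(h, d)
        assert abs(d / math.cos(alpha) - icd) < 1e-9
    return icd


@dataclass(frozen=True)
class CentrosomePair:
    """A spindle-pole pair with its derived geometry.

    Attributes
    ----------
    p1, p2 : tuple of float
        Pole positions, (z, y, x) µm.
    cell_id : int or str
        Source cell identifier (``-1`` when unknown).
    d_um : float
        In-plane (xy) separation D.
    h_um : float
        Axial (z) separation h.
    alpha_deg : float
        Spindle tilt, arctan(h/D), in [0, 90].
    icd_um : float
        3D pole separation, >= D.
    """

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    cell_id: int | str = -1
    d_um: float = 0.0
    h_um: float = 0.0
    alpha_deg: float = 0.0
    icd_um: float = 0.0

    @classmethod
    def from_points(cls, p1, p2, cell_id: int | str = -1) -> "CentrosomePair":
        d, h = _separations(p1, p2)
        return cls(
            p1=tuple(float(v) for v in p1),
            p2=tuple(float(v) for v in p2),
            cell_id=cell_id,
            d_um=d,
            h_um=h,
            alpha_deg=spindle_angle(p1, p2),
            icd_um=intercentrosomal_distance(p1, p2),
        )


def measure_spindles(
    spots: SpotSet,
    pairing: str = "mutual_nn",
    max_pair_distance_um: float = 10.0,
    cell_ids=None,
) -> tuple[list[CentrosomePair], list[int]]:
    """Pair detected centrosome spots and derive per-pair geometry.

    Parameters
    ----------
    spots
        Detected spot set (physical centroids).
    pairing
        ``"annotation"`` — pair spots sharing a value in ``cell_ids``
        (the per-cell annotation route; exactly two spots per id are
        paired, other ids are reported unmatched).
        ``"mutual_nn"`` — fallback: mutual-nearest-neighbour pairs whose
        separation is <= ``max_pair_distance_um``.
    cell_ids
        Per-spot cell annotation, required for ``pairing="annotation"``.

    Returns
    -------
    pairs, unmatched
        The accepted pairs and the indices of spots left unpaired.
    """
    pts = np.asarray([s.centroid_um for s in spots.spots], dtype=float)
    n = len(pts)
    if n < 2:
        return [], list(range(n))

    pairs: list[CentrosomePair] = []
    unmatched: list[int] = []

    if pairing == "annotation":
        if cell_ids is None:
            raise ValueError("pairing='annotation' requires cell_ids")
        cell_ids = list(cell_ids)
        if len(cell_ids) != n:
            raise ValueError("one cell id per spot required")
        by_cell: dict = {}
        for i, cid in enumerate(cell_ids):
            by_cell.setdefault(cid, []).append(i)
        for cid in sorted(by_cell, key=str):
            idx = by_cell[cid]
            if len(idx) == 2:
                i, j = idx
                pairs.append(CentrosomePair.from_points(pts[i], pts[j], cell_id=cid))
            else:
                unmatched.extend(idx)
        return pairs, unmatched

    if pairing != "mutual_nn":
        raise ValueError(f"unknown pairing rule {pairing!r}")

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    nn = dist.argmin(axis=1)
    used = np.zeros(n, dtype=bool)
    for i in range(n):
        j = nn[i]
        if used[i] or used[j]:
            continue
        if nn[j] == i and dist[i, j] <= max_pair_distance_um:
            pairs.append(
                CentrosomePair.from_points(pts[i], pts[j], cell_id=len(pairs))
            )
            used[i] = used[j] = True
    unmatched = [i for i in range(n) if not used[i]]
    return pairs, unmatched
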