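"""Synthetic confocal phantoms with exact ground truth.

Every generator returns ``(data, GroundTruthManifest)``; the manifest
records each planted parameter (angles, distances, overlap counts,
lengths, counts) in continuous physical coordinates, so planted truth
is recoverable without any image processing. Rasterisation error is a
property of the image, never of the manifest.

Optics and noise model (shared by all 3D generators):

* point sources render as anisotropic Gaussians (σz > σxy), the total
  width combining the planted source width with a Gaussian stand-in for
  the confocal PSF;
* noise is Poisson shot noise on the clean signal (at a fixed photon
  gain) plus additive Gaussian read noise; the peak signal-to-noise
  ratio ``snr`` is the peak planted amplitude over the read-noise σ;
  ``snr=None`` produces a noise-free image.

Default voxel spacing is (0.3, 0.1, 0.1) µm (z, y, x), i.e. a 300 nm
z-step. Seeds fully determine every output: a fixed seed gives
byte-identical arrays and manifests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .stack_io import VoxelGrid

__all__ = [
    "GENERATOR_VERSION",
    "GroundTruthManifest",
    "SpindleSimParams",
    "ColocSimParams",
    "RosetteSimParams",
    "make_spindle_stack",
    "make_coloc_stack",
    "make_rosette_section",
    "make_cilium_stack",
    "make_neurite_field",
]

GENERATOR_VERSION = "1.0"

DEFAULT_VOXEL_UM = (0.3, 0.1, 0.1)  # (z, y, x) µm, 300 nm z-step
DEFAULT_PSF_SIGMA_UM = (0.35, 0.13, 0.13)  # anisotropic Gaussian PSF stand-in
_PHOTON_GAIN = 50.0  # photons per unit planted amplitude for shot noise


class SizingError(ValueError):
    """Planted geometry does not fit the requested stack extent."""


@dataclass
class GroundTruthManifest:
    """Record of every planted parameter of one synthetic scene."""

    kind: str
    seed: int
    params: dict
    entities: list[dict] = field(default_factory=list)
    version: str = GENERATOR_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthManifest":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(**payload)


# --------------------------------------------------------------------------
# rendering helpers

def _add_gaussian(image: np.ndarray, center_vox: np.ndarray,
                  sigma_vox: np.ndarray, amplitude: float) -> None:
    """Accumulate an anisotropic Gaussian into ``image`` (window ±4σ)."""
    center_vox = np.asarray(center_vox, dtype=float)
    sigma_vox = np.asarray(sigma_vox, dtype=float)
    lo = np.maximum(np.floor(center_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1,
                    image.shape)
    if np.any(lo >= hi):
        return
    axes = [np.arange(a, b, dtype=float) for a, b in zip(lo, hi)]
    prof = [
        np.exp(-0.5 * ((ax - c) / s) ** 2)
        for ax, c, s in zip(axes, center_vox, sigma_vox)
    ]
    bump = amplitude * np.einsum(
        "i,j,k->ijk" if image.ndim == 3 else "i,j->ij", *prof
    )
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    image[sl] += bump.astype(image.dtype)


def _apply_noise(clean: np.ndarray, snr: float | None,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise at the stated peak SNR."""
    if snr is None:
        return clean
    if snr <= 0:
        raise ValueError("snr must be positive (or None for noise-free)")
    peak = float(clean.max())
    if peak <= 0:
        peak = 1.0
    shot = rng.poisson(np.clip(clean, 0, None) * _PHOTON_GAIN)
    noisy = shot.astype(np.float32) / _PHOTON_GAIN
    read_sigma = peak / snr
    noisy += rng.normal(0.0, read_sigma, size=clean.shape).astype(np.float32)
    return np.clip(noisy, 0.0, None)


def _combined_sigma_um(spot_sigma_um, psf_sigma_um) -> np.ndarray:
    spot = np.broadcast_to(np.asarray(spot_sigma_um, dtype=float), (3,))
    psf = np.broadcast_to(np.asarray(psf_sigma_um, dtype=float), (3,))
    return np.sqrt(spot**2 + psf**2)


def _per_cell_values(value, value_range, n, rng, name) -> np.ndarray:
    """Resolve a scalar / per-cell sequence / uniform range into n values."""
    if value_range is not None:
        lo, hi = value_range
        return rng.uniform(lo, hi, size=n)
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, float(arr[0]))
    if arr.size != n:
        raise ValueError(f"{name}: expected scalar or {n} per-cell values")
    return arr.astype(float)


# --------------------------------------------------------------------------
# spindle phantom

@dataclass
class SpindleSimParams:
    """Parameters of the mitotic-spindle phantom.

    ``icd_um`` and ``alpha_deg`` may be scalars, per-cell sequences, or
    drawn uniformly from ``icd_range_um`` / ``alpha_range_deg``. The
    planted pole pair of each cell separates by ``icd_um`` in 3D with
    the pole axis tilted ``alpha_deg`` out of the xy (dish) plane, so
    h = ICD·sin α and D = ICD·cos α.
    """

    n_cells: int = 1
    icd_um: float | Sequence[float] = 5.0
    alpha_deg: float | Sequence[float] = 20.0
    icd_range_um: tuple[float, float] | None = None
    alpha_range_deg: tuple[float, float] | None = None
    spot_sigma_um: tuple[float, float, float] = (0.25, 0.12, 0.12)
    plate_radius_um: float = 3.0
    snr: float | None = 8.0
    voxel_um: tuple[float, float, float] = DEFAULT_VOXEL_UM
    psf_sigma_um: tuple[float, float, float] = DEFAULT_PSF_SIGMA_UM
    cell_box_xy_um: float = 18.0
    margin_z_um: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if np.any(np.atleast_1d(self.icd_um) <= 0) or (
            self.icd_range_um is not None and self.icd_range_um[0] <= 0
        ):
            raise ValueError("icd_um must be positive")
        alphas = (
            np.asarray(self.alpha_range_deg)
            if self.alpha_range_deg is not None
            else np.atleast_1d(self.alpha_deg)
        )
        if np.any(alphas < 0) or np.any(alphas >= 90):
            raise ValueError("alpha_deg must lie in [0, 90)")
        if any(s <= 0 for s in self.voxel_um):
            raise ValueError("voxel spacing must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or None")


def make_spindle_stack(
    params: SpindleSimParams,
) -> tuple[VoxelGrid, GroundTruthManifest]:
    """Render a two-channel spindle stack (chromatin + centrosome marker).

    Each cell contributes a metaphase chromatin plate and two Gaussian
    pole spots whose 3D separation equals the planted ICD and whose axis
    makes the planted α with the xy plane. Cells are laid out on a
    non-overlapping grid.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_cells
    icds = _per_cell_values(p.icd_um, p.icd_range_um, n, rng, "icd_um")
    alphas = _per_cell_values(p.alpha_deg, p.alpha_range_deg, n, rng, "alpha_deg")

    box = float(p.cell_box_xy_um)
    max_icd = float(icds.max())
    if max_icd + 4.0 > box:
        raise SizingError(
            f"pole separation {max_icd:.2f} µm does not fit the "
            f"{box:.1f} µm cell box; enlarge cell_box_xy_um"
        )
    max_h = float((icds * np.sin(np.radians(alphas))).max())
    z_extent = max_h + 2 * p.margin_z_um

    n_cols = int(math.ceil(math.sqrt(n)))
    n_rows = int(math.ceil(n / n_cols))
    vz, vy, vx = p.voxel_um
    shape = (
        max(int(round(z_extent / vz)) + 1, 5),
        int(round(n_rows * box / vy)),
        int(round(n_cols * box / vx)),
    )
    chromatin = np.zeros(shape, dtype=np.float32)
    centrosome = np.zeros(shape, dtype=np.float32)
    spacing = np.array(p.voxel_um)
    sigma_spot_vox = _combined_sigma_um(p.spot_sigma_um, p.psf_sigma_um) / spacing
    z_mid = (shape[0] - 1) * vz / 2.0

    entities = []
    for i in range(n):
        row, col = divmod(i, n_cols)
        cy = (row + 0.5) * box + rng.uniform(-0.5, 0.5)
        cx = (col + 0.5) * box + rng.uniform(-0.5, 0.5)
        cz = z_mid + rng.uniform(-0.2, 0.2)
        phi = rng.uniform(0.0, 2 * math.pi)
        alpha = math.radians(alphas[i])
        half = 0.5 * icds[i]
        dvec = np.array([  # (z, y, x) half-separation
            half * math.sin(alpha),
            half * math.cos(alpha) * math.sin(phi),
            half * math.cos(alpha) * math.cos(phi),
        ])
        center = np.array([cz, cy, cx])
        p1 = center - dvec
        p2 = center + dvec
        for point in (p1, p2):
            if np.any(point < 0) or np.any(
                point > (np.array(shape) - 1) * spacing
            ):
                raise SizingError("planted pole falls outside the stack")
            _add_gaussian(centrosome, point / spacing, sigma_spot_vox, 1.0)
        plate_sigma_vox = (
            np.array([0.5, p.plate_radius_um / 2, p.plate_radius_um / 2]) / spacing
        )
        _add_gaussian(chromatin, center / spacing, plate_sigma_vox, 0.8)
        entities.append({
            "cell_id": i,
            "alpha_deg": float(alphas[i]),
            "icd_um": float(icds[i]),
            "d_um": float(icds[i] * math.cos(alpha)),
            "h_um": float(icds[i] * math.sin(alpha)),
            "center_zyx_um": [float(v) for v in center],
            "p1_zyx_um": [float(v) for v in p1],
            "p2_zyx_um": [float(v) for v in p2],
        })

    chromatin = _apply_noise(chromatin, p.snr, rng)
    centrosome = _apply_noise(centrosome, p.snr, rng)
    grid = VoxelGrid(
        np.stack([chromatin, centrosome]),
        ("chromatin", "centrosome"),
        p.voxel_um,
    )
    manifest = GroundTruthManifest(
        kind="spindle",
        seed=p.seed,
        params={
            "n_cells": n,
            "snr": p.snr,
            "voxel_um": list(p.voxel_um),
            "spot_sigma_um": list(p.spot_sigma_um),
            "psf_sigma_um": list(p.psf_sigma_um),
            "cell_box_xy_um": box,
        },
        entities=entities,
    )
    return grid, manifest


# --------------------------------------------------------------------------
# co-localization phantom

@dataclass
class ColocSimParams:
    """Parameters of the two-channel object-overlap phantom.

    A objects are uniform-intensity boxes of half-extent
    ``object_radius_um``; each is planted fully inside a B object, fully
    away from all B, or (for at most one object) partially inside so the
    total planted overlap count hits ``target_m1`` exactly up to one
    voxel's intensity share.
    """

    n_objects_a: int = 4
    n_objects_b: int = 4
    target_m1: float = 0.5
    object_radius_um: float = 0.6
    snr: float | None = None
    voxel_um: tuple[float, float, float] = DEFAULT_VOXEL_UM
    psf_sigma_um: tuple[float, float, float] = DEFAULT_PSF_SIGMA_UM
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.target_m1 <= 1.0):
            raise ValueError("target_m1 must lie in [0, 1]")
        if self.n_objects_a < 1 or self.n_objects_b < 0:
            raise ValueError("need >= 1 A object and >= 0 B objects")
        if self.object_radius_um <= 0:
            raise ValueError("object_radius_um must be positive")


def _raster_prefix_boxes(origin, dims, k):
    """First ``k`` voxels of a box in raster (z, y, x) order as <=3 boxes.

    Returns a list of (lo, hi) voxel-index boxes whose union has exactly
    k voxels.
    """
    dz, dy, dx = dims
    oz, oy, ox = origin
    layer = dy * dx
    boxes = []
    q_z, rem = divmod(k, layer)
    if q_z:
        boxes.append(((oz, oy, ox), (oz + q_z, oy + dy, ox + dx)))
    if rem:
        q_y, r_x = divmod(rem, dx)
        if q_y:
            boxes.append(((oz + q_z, oy, ox), (oz + q_z + 1, oy + q_y, ox + dx)))
        if r_x:
            boxes.append(
                ((oz + q_z, oy + q_y, ox), (oz + q_z + 1, oy + q_y + 1, ox + r_x))
            )
    return boxes


def make_coloc_stack(
    params: ColocSimParams,
) -> tuple[VoxelGrid, GroundTruthManifest]:
    """Render channels A and B with an exactly controlled planted M1.

    With uniform A intensity, M1 equals (planted A voxels inside B) /
    (total A voxels); the planted count is ``round(target_m1 · N_A)``
    and is recorded exactly in the manifest.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    spacing = np.asarray(p.voxel_um, dtype=float)
    half_vox = np.maximum(np.round(p.object_radius_um / spacing).astype(int), 1)
    dims = tuple(2 * half_vox + 1)  # identical A-object voxel dimensions
    size_a = int(np.prod(dims))
    n_a = p.n_objects_a
    total_a = n_a * size_a
    k_total = int(round(p.target_m1 * total_a))

    n_full, rem = divmod(k_total, size_a)
    n_partial = 1 if rem else 0
    n_b_needed = n_full + n_partial
    if n_full + n_partial > n_a:
        raise ValueError("target_m1 unreachable with the given A object count")
    if n_b_needed > p.n_objects_b:
        raise ValueError(
            f"target_m1={p.target_m1} needs {n_b_needed} B objects, "
            f"got {p.n_objects_b}"
        )

    # slot layout along x: one slot per A object plus one per spare B object
    n_spare_b = p.n_objects_b - n_b_needed
    margin_vox = np.ceil(4.0 * np.asarray(p.psf_sigma_um) / spacing).astype(int) + 2
    pitch = 2 * (half_vox + 2 * margin_vox + 1)
    n_slots = n_a + n_spare_b
    shape = tuple(
        int(v)
        for v in (pitch[0] + 2 * margin_vox[0],
                  pitch[1] + 2 * margin_vox[1],
                  n_slots * pitch[2] + 2 * margin_vox[2])
    )
    chan_a = np.zeros(shape, dtype=np.float32)
    chan_b = np.zeros(shape, dtype=np.float32)

    slot_order = rng.permutation(n_slots)
    roles = (
        ["full"] * n_full + ["partial"] * n_partial
        + ["outside"] * (n_a - n_full - n_partial)
        + ["spare_b"] * n_spare_b
    )

    entities = []
    a_id = b_id = 0
    for slot, role in zip(slot_order, roles):
        center = np.array([
            shape[0] // 2,
            shape[1] // 2,
            margin_vox[2] + slot * pitch[2] + pitch[2] // 2,
        ])
        lo = center - half_vox
        hi = center + half_vox + 1
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        if role == "spare_b":
            chan_b[box] = 1.0
            entities.append({"object": "B", "b_id": b_id, "role": "spare"})
            b_id += 1
            continue
        chan_a[box] = 1.0
        if role == "full":
            # B must stay supra-threshold everywhere the blurred A support
            # reaches, so the containing B box is dilated beyond the PSF reach
            blo = lo - margin_vox
            bhi = hi + margin_vox
            chan_b[tuple(slice(a, b) for a, b in zip(blo, bhi))] = 1.0
            n_inside = size_a
            b_id += 1
        elif role == "partial":
            for plo, phi_ in _raster_prefix_boxes(lo, dims, rem):
                chan_b[tuple(slice(a, b) for a, b in zip(plo, phi_))] = 1.0
            n_inside = rem
            b_id += 1
        else:
            n_inside = 0
        entities.append({
            "object": "A",
            "a_id": a_id,
            "role": role,
            "n_voxels": size_a,
            "n_inside_b": int(n_inside),
        })
        a_id += 1

    planted_m1 = k_total / total_a
    if p.snr is not None:
        import scipy.ndimage as ndi

        sigma_vox = np.asarray(p.psf_sigma_um) / spacing
        chan_a = ndi.gaussian_filter(chan_a, sigma_vox)
        chan_b = ndi.gaussian_filter(chan_b, sigma_vox)
        chan_a = _apply_noise(chan_a, p.snr, rng)
        chan_b = _apply_noise(chan_b, p.snr, rng)

    grid = VoxelGrid(np.stack([chan_a, chan_b]), ("A", "B"), p.voxel_um)
    manifest = GroundTruthManifest(
        kind="coloc",
        seed=p.seed,
        params={
            "n_objects_a": n_a,
            "n_objects_b": p.n_objects_b,
            "target_m1": p.target_m1,
            "object_radius_um": p.object_radius_um,
            "snr": p.snr,
            "voxel_um": list(p.voxel_um),
            "total_a_voxels": total_a,
            "planted_inside_voxels": k_total,
            "planted_m1": planted_m1,
        },
        entities=entities,
    )
    return grid, manifest


# --------------------------------------------------------------------------
# rosette phantom

@dataclass
class RosetteSimParams:
    """Parameters of the 2D neural-rosette section phantom.

    Cleavage angles are either given explicitly (``theta_list_deg``, one
    per mitosis, in [0, 180)) or allocated deterministically from
    ``asym_fraction``: exactly ``round(asym_fraction · n_mitoses)``
    cells receive asymmetric angles (uniform in [5°, 40°] ∪ [140°,
    175°]) and the rest symmetric angles (uniform in [50°, 130°]),
    keeping every planted angle ≥ 5° from the 45°/135° class boundaries.
    """

    lumen_radius_um: float = 15.0
    n_mitoses: int = 10
    theta_list_deg: Sequence[float] | None = None
    asym_fraction: float | None = None
    jitter_deg: float = 0.0
    pair_separation_um: float = 3.0
    standoff_um: float = 4.0
    pixel_um: tuple[float, float] = (0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.lumen_radius_um <= 0:
            raise ValueError("lumen_radius_um must be positive")
        if self.theta_list_deg is not None:
            thetas = np.asarray(self.theta_list_deg, dtype=float)
            if np.any(thetas < 0) or np.any(thetas >= 180):
                raise ValueError("theta_list_deg values must lie in [0, 180)")
            if len(thetas) != self.n_mitoses:
                raise ValueError("one theta per mitosis required")
        elif self.asym_fraction is not None:
            if not (0.0 <= self.asym_fraction <= 1.0):
                raise ValueError("asym_fraction must lie in [0, 1]")
        else:
            raise ValueError("give either theta_list_deg or asym_fraction")
        if self.jitter_deg < 0:
            raise ValueError("jitter_deg must be >= 0")


def make_rosette_section(
    params: RosetteSimParams,
) -> tuple[VoxelGrid, GroundTruthManifest]:
    """Render a rosette section: lumen ring, nuclei, centrosome pairs.

    Pair midpoints sit ``standoff_um`` outside the lumen boundary at
    evenly spaced angular slots; each pair's axis makes the planted θ
    with the local lumen tangent under the shared directed convention
    (θ from the outward normal, signed by the CCW tangent).
    """
    from .cleavage import classify_division

    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_mitoses
    r_mid = p.lumen_radius_um + p.standoff_um
    slot_arc = p.pair_separation_um + 3.0
    if n * slot_arc > 2 * math.pi * r_mid:
        raise ValueError(
            f"{n} mitoses do not pack on a radius-{r_mid:.1f} µm ring"
        )

    if p.theta_list_deg is not None:
        thetas = np.asarray(p.theta_list_deg, dtype=float)
        if p.jitter_deg > 0:
            thetas = np.clip(
                thetas + rng.uniform(-p.jitter_deg, p.jitter_deg, n), 0.0, 179.9
            )
    else:
        n_asym = int(round(p.asym_fraction * n))
        vals = np.empty(n)
        low_side = rng.random(n_asym) < 0.5
        vals[:n_asym] = np.where(
            low_side,
            rng.uniform(5.0, 40.0, n_asym),
            rng.uniform(140.0, 175.0, n_asym),
        )
        vals[n_asym:] = rng.uniform(50.0, 130.0, n - n_asym)
        thetas = vals[rng.permutation(n)]
        if p.jitter_deg > 0:
            jit = rng.uniform(-p.jitter_deg, p.jitter_deg, n)
            thetas = np.clip(thetas + jit, 0.0, 179.9)

    field_half = r_mid + p.pair_separation_um + 6.0
    py, px = p.pixel_um
    shape = (int(round(2 * field_half / py)), int(round(2 * field_half / px)))
    lumen_ch = np.zeros(shape, dtype=np.float32)
    dapi_ch = np.zeros(shape, dtype=np.float32)
    centro_ch = np.zeros(shape, dtype=np.float32)
    center_xy = np.array([field_half, field_half])  # (x, y) µm

    # lumen ring
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * py, np.arange(shape[1]) * px, indexing="ij"
    )
    rr = np.hypot(xx - center_xy[0], yy - center_xy[1])
    lumen_ch[np.abs(rr - p.lumen_radius_um) <= 0.5] = 1.0

    phi0 = rng.uniform(0.0, 2 * math.pi)
    entities = []
    pixel = np.asarray(p.pixel_um)
    spot_sigma_vox = np.array([0.3, 0.3]) / pixel
    for i in range(n):
        phi = phi0 + 2 * math.pi * i / n
        radial = np.array([math.cos(phi), math.sin(phi)])        # outward normal
        tangent = np.array([-math.sin(phi), math.cos(phi)])      # CCW tangent
        mid = center_xy + r_mid * radial
        th = math.radians(thetas[i])
        axis = math.cos(th) * radial + math.sin(th) * tangent
        half_sep = 0.5 * p.pair_separation_um
        q1 = mid - half_sep * axis
        q2 = mid + half_sep * axis
        for q in (q1, q2):
            _add_gaussian(
                centro_ch, np.array([q[1] / py, q[0] / px]), spot_sigma_vox, 1.0
            )
        nuc = mid + 2.5 * radial
        _add_gaussian(
            dapi_ch, np.array([nuc[1] / py, nuc[0] / px]),
            np.array([2.5, 2.5]) / pixel, 0.8,
        )
        entities.append({
            "mitosis_id": i,
            "theta_deg": float(thetas[i]),
            "division_class": classify_division(float(thetas[i])),
            "midpoint_xy_um": [float(v) for v in mid],
            "p1_xy_um": [float(v) for v in q1],
            "p2_xy_um": [float(v) for v in q2],
        })

    angles = np.linspace(0.0, 2 * math.pi, 360, endpoint=False)
    lumen_poly = np.column_stack([
        center_xy[0] + p.lumen_radius_um * np.cos(angles),
        center_xy[1] + p.lumen_radius_um * np.sin(angles),
    ])
    grid = VoxelGrid(
        np.stack([lumen_ch, dapi_ch, centro_ch]),
        ("lumen", "dapi", "centrosome"),
        p.pixel_um,
    )
    manifest = GroundTruthManifest(
        kind="rosette",
        seed=p.seed,
        params={
            "lumen_radius_um": p.lumen_radius_um,
            "n_mitoses": n,
            "asym_fraction": p.asym_fraction,
            "jitter_deg": p.jitter_deg,
            "pair_separation_um": p.pair_separation_um,
            "center_xy_um": [float(v) for v in center_xy],
            "lumen_polygon_xy_um": lumen_poly.tolist(),
            "pixel_um": list(p.pixel_um),
        },
        entities=entities,
    )
    return grid, manifest


# --------------------------------------------------------------------------
# cilium phantom

def make_cilium_stack(
    length_um: float,
    tortuosity: float = 0.0,
    voxel_um: tuple[float, float, float] = DEFAULT_VOXEL_UM,
    seed: int = 0,
    step_um: float = 0.2,
    shape_um: tuple[float, float, float] | None = None,
) -> tuple[VoxelGrid, GroundTruthManifest]:
    """Render a bright curvilinear cilium of exactly known arc length.

    The path bends with a smoothly varying random curvature (primary
    cilia are gently curved arcs, not jagged walks): the local direction
    rotates at ``tortuosity × 0.5`` rad/µm around a slowly drifting
    axis, so ``tortuosity = 0`` gives a straight segment and
    ``tortuosity ≈ 1`` a curvature radius of about 2 µm. Steps have
    fixed length (plus one final partial step), so the polyline arc
    length equals ``length_um`` exactly. The manifest stores the
    polyline.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if tortuosity < 0:
        raise ValueError("tortuosity must be >= 0")
    if shape_um is not None:
        diag = math.sqrt(sum(s**2 for s in shape_um))
        if length_um > diag:
            raise SizingError(
                f"cilium length {length_um} µm exceeds the stack diagonal "
                f"{diag:.2f} µm"
            )
    rng = np.random.default_rng(seed)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    # rotation axis drifts slowly; curvature magnitude is fixed by tortuosity
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    curvature = tortuosity * 0.5  # rad per µm of arc
    n_full, last = divmod(length_um, step_um)
    steps = [step_um] * int(n_full)
    if last > 1e-12:
        steps.append(last)
    pts = [np.zeros(3)]
    for ds in steps:
        if tortuosity > 0:
            axis = axis + 0.1 * rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            omega = curvature * ds * np.cross(axis, direction)
            direction = direction + omega
            direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + ds * direction)
    pts = np.asarray(pts)

    margin = 1.5
    lo = pts.min(axis=0) - margin
    pts_shifted = pts - lo
    extent = pts_shifted.max(axis=0) + margin
    spacing = np.asarray(voxel_um, dtype=float)
    if shape_um is not None:
        if np.any(extent > np.asarray(shape_um)):
            raise SizingError("cilium path does not fit the requested stack")
        extent = np.asarray(shape_um, dtype=float)
    shape = tuple(int(math.ceil(e / s)) + 1 for e, s in zip(extent, spacing))
    image = np.zeros(shape, dtype=np.float32)
    sigma_vox = _combined_sigma_um((0.1, 0.1, 0.1), DEFAULT_PSF_SIGMA_UM) / spacing
    # densely sample the polyline so the tube renders continuously
    for a, b in zip(pts_shifted[:-1], pts_shifted[1:]):
        seg = np.linalg.norm(b - a)
        n_sub = max(int(math.ceil(seg / (0.25 * spacing.min()))), 1)
        for t in np.linspace(0.0, 1.0, n_sub, endpoint=False):
            _add_gaussian(image, ((1 - t) * a + t * b) / spacing, sigma_vox, 1.0)
    _add_gaussian(image, pts_shifted[-1] / spacing, sigma_vox, 1.0)

    arc = float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())
    grid = VoxelGrid(image[np.newaxis], ("cilium",), tuple(voxel_um))
    manifest = GroundTruthManifest(
        kind="cilium",
        seed=seed,
        params={
            "length_um": float(length_um),
            "tortuosity": float(tortuosity),
            "step_um": float(step_um),
            "voxel_um": list(voxel_um),
        },
        entities=[{
            "cilium_id": 0,
            "polyline_zyx_um": pts_shifted.tolist(),
            "arc_length_um": arc,
        }],
    )
    return grid, manifest


# --------------------------------------------------------------------------
# neurite-field phantom

def make_neurite_field(
    area_um2: float,
    n_tubb3_cells: int,
    n_total_cells: int,
    pixel_um: tuple[float, float] = (0.5, 0.5),
    nucleus_radius_um: float = 3.0,
    perinuclear_radius_um: float = 2.0,
    seed: int = 0,
) -> tuple[VoxelGrid, GroundTruthManifest]:
    """Render a neurite-mask + nucleus field with exact planted counts.

    The TUBB3 (neurite) mask contains exactly
    ``round(area_um2 / pixel_area)`` foreground pixels grown as
    random-walk strands from the TUBB3⁺ nuclei; nuclei are planted as
    non-overlapping disks. The manifest records the voxel-quantised
    planted area, all counts and the perinuclear disks.
    """
    if area_um2 <= 0:
        raise ValueError("area_um2 must be positive")
    if n_total_cells < 1:
        raise ValueError("n_total_cells must be >= 1")
    if not (0 <= n_tubb3_cells <= n_total_cells):
        raise ValueError("need 0 <= n_tubb3_cells <= n_total_cells")
    rng = np.random.default_rng(seed)
    py, px = (float(v) for v in pixel_um)
    pixel_area = py * px
    n_px = int(round(area_um2 / pixel_area))

    # field sized to hold nuclei lattice and the neurite area comfortably
    n_cols = int(math.ceil(math.sqrt(n_total_cells)))
    n_rows = int(math.ceil(n_total_cells / n_cols))
    cell_pitch_um = 4.0 * nucleus_radius_um
    side_um = max(n_cols, n_rows) * cell_pitch_um + 2 * cell_pitch_um
    side_um = max(side_um, 2.0 * math.sqrt(area_um2 + pixel_area))
    shape = (int(math.ceil(side_um / py)), int(math.ceil(side_um / px)))
    if n_px > shape[0] * shape[1]:
        raise SizingError("planted neurite area exceeds the field")

    dapi = np.zeros(shape, dtype=np.float32)
    tubb3_mask = np.zeros(shape, dtype=bool)
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * py, np.arange(shape[1]) * px, indexing="ij"
    )

    centers = []
    for i in range(n_total_cells):
        row, col = divmod(i, n_cols)
        cy = (row + 1.0) * cell_pitch_um + rng.uniform(-1.0, 1.0)
        cx = (col + 1.0) * cell_pitch_um + rng.uniform(-1.0, 1.0)
        centers.append((cy, cx))
        dapi[np.hypot(yy - cy, xx - cx) <= nucleus_radius_um] = 1.0

    # grow neurite strands from the TUBB3+ nuclei to an exact pixel count
    seeds_px = [
        (int(round(cy / py)), int(round(cx / px)))
        for cy, cx in centers[:n_tubb3_cells]
    ] or [(shape[0] // 2, shape[1] // 2)]
    moves = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
    cursors = [np.array(s) for s in seeds_px]
    count = 0
    guard = 0
    while count < n_px:
        guard += 1
        if guard > 200 * n_px:
            raise SizingError("could not grow the requested neurite area")
        ci = guard % len(cursors)
        pos = cursors[ci]
        step = moves[rng.integers(0, 4)]
        nxt = np.clip(pos + step, 0, np.array(shape) - 1)
        cursors[ci] = nxt
        if not tubb3_mask[tuple(nxt)]:
            tubb3_mask[tuple(nxt)] = True
            count += 1

    planted_area = n_px * pixel_area
    grid = VoxelGrid(
        np.stack([tubb3_mask.astype(np.float32), dapi]),
        ("tubb3", "dapi"),
        (py, px),
    )
    manifest = GroundTruthManifest(
        kind="neurite",
        seed=seed,
        params={
            "area_um2_requested": float(area_um2),
            "area_um2_planted": planted_area,
            "n_foreground_px": n_px,
            "n_tubb3_cells": n_tubb3_cells,
            "n_total_cells": n_total_cells,
            "pixel_um": [py, px],
            "nucleus_radius_um": nucleus_radius_um,
            "perinuclear_radius_um": perinuclear_radius_um,
            "tubb3_density_um2_per_cell": planted_area / n_total_cells,
        },
        entities=[
            {"cell_id": i, "center_yx_um": [cy, cx],
             "tubb3_positive": i < n_tubb3_cells}
            for i, (cy, cx) in enumerate(centers)
        ],
    )
    return grid, manifest
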