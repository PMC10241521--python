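"""Image-stack, mask, manifest and table I/O.

Conventions used throughout the package:

* Arrays are indexed ``(channel, z, y, x)`` for 3D stacks and
  ``(channel, y, x)`` for 2D sections.
* Voxel spacing is a ``(z, y, x)`` triple in micrometres.
* Physical coordinates use the voxel-centre convention: the centre of
  voxel ``i`` along an axis sits at ``i * spacing`` µm (0-based indices).
  All geometry downstream is computed in physical µm, never in voxel
  units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelGrid",
    "RoiMask",
    "ResultTable",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "load_config",
]


class SpacingError(ValueError):
    """Raised when a stack carries no usable voxel-spacing metadata."""


@dataclass(frozen=True)
class VoxelGrid:
    """A named multi-channel intensity array with physical voxel spacing.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(C, Z, Y, X)`` (or ``(C, Y, X)`` for
        a 2D section).
    channel_names
        One unique name per channel.
    voxel_um
        Per-axis spacing in µm: ``(z, y, x)`` for 3D, ``(y, x)`` for 2D.
    """

    intensities: np.ndarray
    channel_names: tuple[str, ...]
    voxel_um: tuple[float, ...]

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        object.__setattr__(self, "intensities", arr)
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        spacing = tuple(float(s) for s in self.voxel_um)
        object.__setattr__(self, "voxel_um", spacing)
        if arr.ndim not in (3, 4):
            raise ValueError(f"expected (C,Z,Y,X) or (C,Y,X) array, got ndim={arr.ndim}")
        if len(names) != arr.shape[0]:
            raise ValueError("one channel name per channel required")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if len(spacing) != arr.ndim - 1:
            raise ValueError("spacing must have one entry per spatial axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.intensities.shape[1:]

    @property
    def is_3d(self) -> bool:
        return self.intensities.ndim == 4

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's spatial array by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.intensities[idx]

    def physical_extent_um(self) -> tuple[float, ...]:
        """Extent spanned by voxel centres along each spatial axis (µm)."""
        return tuple(
            (n - 1) * s for n, s in zip(self.spatial_shape, self.voxel_um)
        )

    def voxel_volume_um3(self) -> float:
        """Physical volume (3D) or area (2D) of a single voxel."""
        return float(np.prod(self.voxel_um))


@dataclass(frozen=True)
class RoiMask:
    """A binary mask aligned to a grid (or standalone 2D/3D section)."""

    mask: np.ndarray
    voxel_um: tuple[float, ...]
    label: str = "roi"

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        spacing = tuple(float(s) for s in self.voxel_um)
        object.__setattr__(self, "voxel_um", spacing)
        if len(spacing) != m.ndim:
            raise ValueError("spacing must have one entry per mask axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def area_um2(self) -> float:
        """Physical foreground area (2D) or volume (3D)."""
        return self.n_voxels * float(np.prod(self.voxel_um))


@dataclass
class ResultTable:
    """Rows of named measurements with units and provenance.

    Wraps a :class:`pandas.DataFrame`; the ``units`` mapping gives a unit
    string per column (empty string for dimensionless / id columns).
    Round-trips losslessly to delimited text via :func:`write_table` /
    :func:`read_table`.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.units) - set(self.data.columns)
        if unknown:
            raise ValueError(f"units given for unknown columns: {sorted(unknown)}")


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as OME-TIFF with explicit physical pixel sizes."""
    path = Path(path)
    axes = "CZYX" if grid.is_3d else "CYX"
    if grid.is_3d:
        sz, sy, sx = grid.voxel_um
    else:
        sy, sx = grid.voxel_um
        sz = None
    metadata = {
        "axes": axes,
        "Channel": {"Name": list(grid.channel_names)},
        "PhysicalSizeX": sx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": sy,
        "PhysicalSizeYUnit": "µm",
    }
    if sz is not None:
        metadata["PhysicalSizeZ"] = sz
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, grid.intensities, ome=True, metadata=metadata)
    return path


def _spacing_from_ome(path: Path, ndim_spatial: int) -> tuple[float, ...] | None:
    with tifffile.TiffFile(path) as tf:
        if tf.ome_metadata is None:
            return None
        meta = tifffile.xml2dict(tf.ome_metadata)
    try:
        pixels = meta["OME"]["Image"]["Pixels"]
        if isinstance(pixels, list):  # multi-series: use the first
            pixels = pixels[0]
        sx = float(pixels["PhysicalSizeX"])
        sy = float(pixels["PhysicalSizeY"])
        if ndim_spatial == 3:
            sz = float(pixels["PhysicalSizeZ"])
            return (sz, sy, sx)
        return (sy, sx)
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VoxelGrid:
    """Read a multi-page TIFF / OME-TIFF into a :class:`VoxelGrid`.

    Spacing is taken from OME metadata; ``spacing_override`` wins if
    given. A file with no spacing metadata and no override raises
    :class:`SpacingError` — geometry must never silently default to
    voxel units.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata
    # normalise to (C, Z, Y, X) / (C, Y, X)
    if axes in ("CZYX", "CYX"):
        pass
    elif axes in ("ZYX", "QYX"):  # 'Q' = unlabeled third axis
        arr = arr[np.newaxis]
        axes = "CZYX"
    elif axes == "YX":
        arr = arr[np.newaxis]
        axes = "CYX"
    elif axes == "ZCYX":
        arr = np.moveaxis(arr, 1, 0)
        axes = "CZYX"
    else:
        raise ValueError(f"unsupported TIFF axis layout {axes!r}")
    ndim_spatial = arr.ndim - 1

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    else:
        spacing = _spacing_from_ome(path, ndim_spatial) if ome else None
        if spacing is None:
            raise SpacingError(
                f"{path} carries no voxel-spacing metadata; pass spacing_override"
            )

    names: tuple[str, ...] | None = None
    if channel_names is not None:
        names = tuple(channel_names)
    elif ome is not None:
        meta = tifffile.xml2dict(ome)
        try:
            chans = meta["OME"]["Image"]["Pixels"]["Channel"]
            if isinstance(chans, dict):
                chans = [chans]
            got = [c.get("Name") for c in chans]
            if all(isinstance(n, str) for n in got) and len(got) == arr.shape[0]:
                names = tuple(got)
        except (KeyError, TypeError):
            names = None
    if names is None:
        names = tuple(f"ch{i}" for i in range(arr.shape[0]))
    return VoxelGrid(arr, names, spacing)


_UNITS_PREFIX = "# units:"
_PROV_PREFIX = "# provenance:"


def write_table(table: ResultTable, path: str | Path) -> Path:
    """Write a :class:`ResultTable` as CSV with a units header comment.

    The layout is: one ``# provenance:`` comment line (JSON), one
    ``# units:`` comment line (JSON), then a standard CSV header + rows.
    Floats are written with :func:`repr` precision (17 significant
    digits), so numeric round-trips are exact.
    """
    import json

    path = Path(path)
    units = {c: table.units.get(c, "") for c in table.data.columns}
    with open(path, "w", newline="") as fh:
        fh.write(_PROV_PREFIX + json.dumps(table.provenance, sort_keys=True) + "\n")
        fh.write(_UNITS_PREFIX + json.dumps(units) + "\n")
        table.data.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_table(path: str | Path) -> ResultTable:
    """Read a table written by :func:`write_table`."""
    import json

    path = Path(path)
    with open(path) as fh:
        prov_line = fh.readline()
        units_line = fh.readline()
        if not prov_line.startswith(_PROV_PREFIX) or not units_line.startswith(
            _UNITS_PREFIX
        ):
            raise ValueError(f"{path} is not a mitometry result table")
        provenance = json.loads(prov_line[len(_PROV_PREFIX):])
        units = json.loads(units_line[len(_UNITS_PREFIX):])
        data = pd.read_csv(fh, float_precision="round_trip")
    units = {c: u for c, u in units.items() if c in data.columns}
    return ResultTable(data=data, units=units, provenance=provenance)


def load_config(
    path: str | Path | None, overrides: Mapping[str, object] | None = None
) -> dict:
    """Load a YAML run configuration and merge CLI overrides (CLI wins)."""
    config: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            config.update(loaded)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    return config
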