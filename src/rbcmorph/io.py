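"""Core data types and file I/O.

Tomograms are stored as multi-page 32-bit float TIFF stacks (plane order = z)
with a JSON sidecar carrying the physical metadata::

    {"voxel_size": [dz, dy, dx], "medium_ri": 1.337}

Arrays are indexed ``(z, y, x)`` with z the optical axis; all geometry is
reported in physical micrometres.  Volumes use 1 fL == 1 um^3 throughout,
with no unit factor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Tomogram",
    "LabelVolume",
    "CellRecord",
    "MetadataError",
    "read_tomogram",
    "write_tomogram",
    "write_label_volume",
    "read_label_volume",
    "write_cell_table",
    "read_cell_table",
    "records_to_frame",
    "CELL_TABLE_COLUMNS",
]


class MetadataError(ValueError):
    """A required metadata field is missing or invalid in a sidecar file."""


@dataclass
class Tomogram:
    """A 3D refractive-index grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Refractive-index values (dimensionless, typically 1.33-1.42).
    voxel_size : tuple of float
        Per-axis spacing ``(dz, dy, dx)`` in micrometres.
    medium_ri : float
        Refractive index of the suspension medium (background).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    medium_ri: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or 0 in self.values.shape:
            raise ValueError(
                f"tomogram grid must be 3D and non-empty, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.medium_ri = float(self.medium_ri)
        if not 1.30 <= self.medium_ri <= 1.40:
            raise ValueError(f"medium_ri {self.medium_ri} outside plausible range [1.30, 1.40]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_fl(self) -> float:
        """Volume of one voxel in fL (== um^3)."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class LabelVolume:
    """Integer cell labels on the tomogram grid (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


#: stable column order of the per-cell CSV
CELL_TABLE_COLUMNS = [
    "cell_id",
    "volume_fl",
    "surface_area_um2",
    "sphericity",
    "long_axis_um",
    "short_axis_um",
    "aspect_ratio",
    "mean_ri",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "touches_border",
]


@dataclass
class CellRecord:
    """Morphometry of one segmented cell.

    ``sphericity`` must be internally consistent with the stored volume and
    surface area through Wadell's formula pi^(1/3) (6V)^(2/3) / A.
    """

    cell_id: int
    volume_fl: float
    surface_area_um2: float
    sphericity: float
    long_axis_um: float
    short_axis_um: float
    aspect_ratio: float
    mean_ri: float
    centroid_um: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.volume_fl <= 0 or self.surface_area_um2 <= 0:
            raise ValueError("volume and surface area must be positive")
        if self.short_axis_um > self.long_axis_um * (1 + 1e-12):
            raise ValueError("short axis exceeds long axis")
        expected = self.short_axis_um / self.long_axis_um
        if abs(self.aspect_ratio - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("aspect_ratio inconsistent with stored axes")
        psi = np.pi ** (1 / 3) * (6.0 * self.volume_fl) ** (2 / 3) / self.surface_area_um2
        if abs(self.sphericity - psi) > 1e-9 * psi:
            raise ValueError(
                f"sphericity {self.sphericity} inconsistent with V, A (expected {psi})"
            )


def _sidecar_path(path_tiff: str | Path, path_meta: str | Path | None) -> Path:
    if path_meta is not None:
        return Path(path_meta)
    return Path(path_tiff).with_suffix(".json")


def write_tomogram(
    tomogram: Tomogram, path_tiff: str | Path, path_meta: str | Path | None = None
) -> None:
    """Write a tomogram as float32 multi-page TIFF + JSON sidecar (lossless)."""
    path_tiff = Path(path_tiff)
    tifffile.imwrite(path_tiff, tomogram.values.astype(np.float32))
    meta = {"voxel_size": list(tomogram.voxel_size), "medium_ri": tomogram.medium_ri}
    _sidecar_path(path_tiff, path_meta).write_text(json.dumps(meta, indent=1))


def read_tomogram(path_tiff: str | Path, path_meta: str | Path | None = None) -> Tomogram:
    """Read a TIFF stack + JSON sidecar pair written by :func:`write_tomogram`.

    Raises
    ------
    MetadataError
        If the sidecar lacks ``voxel_size`` or ``medium_ri`` — there is no
        silent default for physical calibration.
    """
    values = tifffile.imread(Path(path_tiff))
    if values.ndim == 2:  # single-page stack
        values = values[None]
    meta = json.loads(_sidecar_path(path_tiff, path_meta).read_text())
    for key in ("voxel_size", "medium_ri"):
        if key not in meta:
            raise MetadataError(f"sidecar missing required key {key!r}")
    return Tomogram(values=values, voxel_size=tuple(meta["voxel_size"]), medium_ri=meta["medium_ri"])


def write_label_volume(
    labelvol: LabelVolume, path_tiff: str | Path, path_meta: str | Path | None = None
) -> None:
    tifffile.imwrite(Path(path_tiff), labelvol.labels.astype(np.int32))
    meta = {"voxel_size": list(labelvol.voxel_size)}
    _sidecar_path(path_tiff, path_meta).write_text(json.dumps(meta, indent=1))


def read_label_volume(path_tiff: str | Path, path_meta: str | Path | None = None) -> LabelVolume:
    labels = tifffile.imread(Path(path_tiff))
    if labels.ndim == 2:
        labels = labels[None]
    meta = json.loads(_sidecar_path(path_tiff, path_meta).read_text())
    if "voxel_size" not in meta:
        raise MetadataError("sidecar missing required key 'voxel_size'")
    return LabelVolume(labels=labels, voxel_size=tuple(meta["voxel_size"]))


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        cz, cy, cx = r.centroid_um
        rows.append(
            {
                "cell_id": r.cell_id,
                "volume_fl": r.volume_fl,
                "surface_area_um2": r.surface_area_um2,
                "sphericity": r.sphericity,
                "long_axis_um": r.long_axis_um,
                "short_axis_um": r.short_axis_um,
                "aspect_ratio": r.aspect_ratio,
                "mean_ri": r.mean_ri,
                "centroid_z_um": cz,
                "centroid_y_um": cy,
                "centroid_x_um": cx,
                "touches_border": r.touches_border,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(records: Sequence[CellRecord], path_csv: str | Path) -> None:
    """Write per-cell morphometry as CSV (header mandatory, >=8 sig digits).

    Booleans serialize as ``true``/``false``.  An empty record list writes a
    header-only file and logs a warning.
    """
    if len(records) == 0:
        logger.warning("writing header-only cell table to %s (no records)", path_csv)
    df = records_to_frame(records)
    df["touches_border"] = df["touches_border"].map({True: "true", False: "false"})
    df.to_csv(Path(path_csv), index=False, float_format="%.8g")


def read_cell_table(path_csv: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path_csv))
    if "touches_border" in df.columns and df["touches_border"].dtype == object:
        df["touches_border"] = df["touches_border"].map({"true": True, "false": False})
    return df
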