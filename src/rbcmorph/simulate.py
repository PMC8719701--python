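"""Synthetic tomogram fields of RBC populations.

Emulates the measurement setting: blood diluted ~200-fold so cells sit
sparse and non-overlapping in the dish, imaged as a 3D refractive-index
volume.  Cells settle near a common focal plane, nearly flat, with small
random tilt; per-cell volume, sphering index, and cytoplasmic RI are i.i.d.
draws from the condition preset; the field gets additive Gaussian RI noise.

Not emulated: the optical transfer function (missing cone, diffraction),
RI inhomogeneity within the cytoplasm, echinocyte spicules, and cell motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .io import Tomogram
from .solutions import ConditionPreset

__all__ = ["GroundTruthCell", "ground_truth_frame", "simulate_field", "PlacementError"]

#: default isotropic voxel spacing, um
DEFAULT_VOXEL = 0.1
#: minimum clearance between cell bounding spheres, um
CLEARANCE_UM = 0.8
#: rejection-sampling cap per cell
MAX_ATTEMPTS = 10_000
#: SD of the settling tilt of the symmetry axis, radians (~5 degrees)
TILT_SD = np.deg2rad(5.0)


class PlacementError(RuntimeError):
    """Could not place all cells without overlap; use a larger field."""


@dataclass
class GroundTruthCell:
    """True (analytic) geometry of one generated cell."""

    cell_index: int
    volume_fl: float
    surface_area_um2: float
    sphericity: float
    s: float
    cell_ri: float
    center_um: tuple[float, float, float]
    tilt_rad: float


def ground_truth_frame(cells: list[GroundTruthCell]) -> pd.DataFrame:
    rows = [
        {
            "cell_index": c.cell_index,
            "volume_fl": c.volume_fl,
            "surface_area_um2": c.surface_area_um2,
            "sphericity": c.sphericity,
            "s": c.s,
            "cell_ri": c.cell_ri,
            "center_z_um": c.center_um[0],
            "center_y_um": c.center_um[1],
            "center_x_um": c.center_um[2],
            "tilt_rad": c.tilt_rad,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)


def _draw_cell_params(preset: ConditionPreset, n: int, rng: np.random.Generator):
    volumes = rng.normal(preset.volume_mean_fl, preset.volume_sd_fl, size=n)
    volumes = np.clip(volumes, 25.0, 195.0)
    s = np.clip(rng.normal(preset.s_mean, preset.s_sd, size=n), 0.0, 1.0)
    cell_ri = rng.normal(preset.cell_ri_mean, preset.cell_ri_sd, size=n)
    cell_ri = np.clip(cell_ri, preset.medium_ri + 0.02, 1.45)
    tilt = np.abs(rng.normal(0.0, TILT_SD, size=n))
    azimuth = rng.uniform(0.0, 2.0 * np.pi, size=n)
    spin = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return volumes, s, cell_ri, tilt, azimuth, spin


def simulate_field(
    preset: ConditionPreset,
    n_cells: int | None = None,
    seed: int | np.random.Generator = 0,
    voxel_size: float = DEFAULT_VOXEL,
    supersample: int = 3,
) -> tuple[Tomogram, list[GroundTruthCell]]:
    """Generate one sparse field of RBCs under a solution condition.

    Returns the noisy tomogram and the exact per-cell ground truth (analytic
    volume/area/sphericity of each placed shape).  Deterministic for a fixed
    integer ``seed``.

    Raises
    ------
    PlacementError
        If non-overlapping placement fails within the attempt cap.
    """
    if n_cells is None:
        n_cells = preset.cells_per_field
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    volumes, s_draws, cell_ri, tilt, azimuth, spin = _draw_cell_params(preset, n_cells, rng)

    base = geometry.default_discocyte()
    specs = []
    for i in range(n_cells):
        spec = geometry.ShapeSpec(
            kind="morph" if s_draws[i] > 0 else "discocyte",
            s=float(s_draws[i]),
            target_volume_fl=float(volumes[i]),
            orientation=geometry.tilt_rotation(float(tilt[i]), float(azimuth[i]), float(spin[i])),
        )
        specs.append(spec)

    radii = np.array([geometry.bounding_radius(sp) for sp in specs])
    rmax = float(radii.max())

    # field sized for sparse, dish-settled cells: one layer in z, lateral
    # extent from a per-cell footprint with ~30% slack
    pitch = 2.0 * rmax + CLEARANCE_UM
    side = float(np.ceil(np.sqrt(n_cells)) * pitch * 1.3 + 2.0 * rmax)
    height = 2.0 * rmax + 3.0
    shape = (
        int(np.ceil(height / voxel_size)),
        int(np.ceil(side / voxel_size)),
        int(np.ceil(side / voxel_size)),
    )

    # rejection-sample non-overlapping lateral positions
    centers = np.zeros((n_cells, 3))
    z_mid = height / 2.0
    for i in range(n_cells):
        ri = radii[i]
        placed = False
        for _ in range(MAX_ATTEMPTS):
            y = rng.uniform(ri + CLEARANCE_UM, side - ri - CLEARANCE_UM)
            x = rng.uniform(ri + CLEARANCE_UM, side - ri - CLEARANCE_UM)
            z = z_mid + rng.normal(0.0, 0.2)
            if i > 0:
                d = np.hypot(centers[:i, 1] - y, centers[:i, 2] - x)
                if np.any(d < radii[:i] + ri + CLEARANCE_UM):
                    continue
            centers[i] = (z, y, x)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"failed to place cell {i + 1}/{n_cells} after {MAX_ATTEMPTS} attempts; "
                "increase the field size or reduce the cell count"
            )

    field = np.full(shape, preset.medium_ri, dtype=np.float32)
    truth: list[GroundTruthCell] = []
    for i, spec in enumerate(specs):
        patch = geometry.rasterize_cell(
            spec, voxel_size, float(cell_ri[i]), preset.medium_ri, supersample=supersample
        )
        pz, py, px = patch.shape
        # voxel index of the patch origin so the patch center lands on the cell center
        z0 = int(round(centers[i, 0] / voxel_size - pz / 2.0))
        y0 = int(round(centers[i, 1] / voxel_size - py / 2.0))
        x0 = int(round(centers[i, 2] / voxel_size - px / 2.0))
        z0 = max(0, min(z0, shape[0] - pz))
        y0 = max(0, min(y0, shape[1] - py))
        x0 = max(0, min(x0, shape[2] - px))
        field[z0 : z0 + pz, y0 : y0 + py, x0 : x0 + px] += patch.values - preset.medium_ri
        center = (
            (z0 + pz / 2.0) * voxel_size,
            (y0 + py / 2.0) * voxel_size,
            (x0 + px / 2.0) * voxel_size,
        )
        truth.append(
            GroundTruthCell(
                cell_index=i + 1,
                volume_fl=geometry.shape_volume_analytic(spec),
                surface_area_um2=geometry.shape_surface_area_analytic(spec),
                sphericity=geometry.shape_sphericity_analytic(spec),
                s=float(s_draws[i]),
                cell_ri=float(cell_ri[i]),
                center_um=center,
                tilt_rad=float(tilt[i]),
            )
        )

    if preset.noise_sd > 0:
        field += preset.noise_sd * rng.standard_normal(shape, dtype=np.float32)

    tomo = Tomogram(values=field, voxel_size=(voxel_size,) * 3, medium_ri=preset.medium_ri)
    return tomo, truth


def match_ground_truth(
    records_frame: pd.DataFrame, truth: list[GroundTruthCell], max_dist_um: float = 2.0
) -> pd.DataFrame:
    """Join measured records to ground-truth cells by nearest centroid.

    Returns the records frame with ``true_*`` columns appended; raises if any
    measured cell has no ground-truth partner within ``max_dist_um``.
    """
    tdf = ground_truth_frame(truth)
    tc = tdf[["center_z_um", "center_y_um", "center_x_um"]].to_numpy()
    out = records_frame.copy()
    idx = []
    for _, row in records_frame.iterrows():
        c = np.array([row["centroid_z_um"], row["centroid_y_um"], row["centroid_x_um"]])
        d = np.linalg.norm(tc - c, axis=1)
        j = int(np.argmin(d))
        if d[j] > max_dist_um:
            raise ValueError(f"measured cell {row['cell_id']} has no ground-truth match")
        idx.append(j)
    for col in ("volume_fl", "surface_area_um2", "sphericity", "s"):
        out[f"true_{col}" if not col == "s" else "true_s"] = tdf[col].to_numpy()[idx]
    return out
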