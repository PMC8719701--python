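"""Threshold-based single-cell isolation from RI tomograms.

Cells are brighter (higher RI) than the medium, so a global RI threshold
separates foreground; connected components become cell candidates, and a
volume gate plus border exclusion removes specks, clumps and clipped cells.
Fields are sparse (the assay dilutes blood ~200-fold), so no watershed
splitting of touching cells is attempted — doublets fall to the volume gate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import LabelVolume, Tomogram

logger = logging.getLogger(__name__)

__all__ = [
    "binarize",
    "label_components",
    "filter_cells",
    "select_random_cells",
    "midpoint_threshold",
    "auto_threshold",
    "DEFAULT_MIN_VOLUME_FL",
    "DEFAULT_MAX_VOLUME_FL",
]

#: default volume gate, fL — brackets physiological RBC volumes
DEFAULT_MIN_VOLUME_FL = 30.0
DEFAULT_MAX_VOLUME_FL = 180.0


def midpoint_threshold(medium_ri: float, cell_ri: float) -> float:
    """Midpoint between medium and expected cytoplasmic RI.

    With partial-volume rasterization/imaging, the half-contrast level is
    where the voxel-counted volume is unbiased.
    """
    return medium_ri + 0.5 * (cell_ri - medium_ri)


def auto_threshold(tomogram: Tomogram) -> float:
    """Two-class variance-maximizing (Otsu) threshold fallback for use when
    the expected cell RI is unknown."""
    return float(threshold_otsu(tomogram.values))


def binarize(tomogram: Tomogram, ri_threshold: float) -> np.ndarray:
    """Foreground mask: voxels with RI >= threshold."""
    if ri_threshold <= tomogram.medium_ri:
        logger.warning(
            "threshold %.4f <= medium RI %.4f: foreground/background inversion likely",
            ri_threshold, tomogram.medium_ri,
        )
    vmin, vmax = float(tomogram.values.min()), float(tomogram.values.max())
    if not vmin <= ri_threshold <= vmax:
        logger.warning(
            "threshold %.4f outside value range [%.4f, %.4f]; mask will be empty or full",
            ri_threshold, vmin, vmax,
        )
    return tomogram.values >= ri_threshold


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(
    mask: np.ndarray, voxel_size: Sequence[float], connectivity: int = 26
) -> LabelVolume:
    """Label maximal connected foreground components 1..K.

    Labels are assigned in scan order of each component's first voxel
    (smallest flat index), so labeling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labeled, k = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if k > 1:
        # enforce first-occurrence ordering explicitly
        flat = labeled.ravel()
        ids, first = np.unique(flat, return_index=True)
        order = [int(i) for i in ids[np.argsort(first)] if i != 0]
        remap = np.zeros(k + 1, dtype=labeled.dtype)
        for new, old in enumerate(order, start=1):
            remap[old] = new
        labeled = remap[labeled]
    return LabelVolume(labels=labeled, voxel_size=tuple(voxel_size))


def _border_labels(labels: np.ndarray) -> set[int]:
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def filter_cells(
    labelvol: LabelVolume,
    min_volume_fl: float = DEFAULT_MIN_VOLUME_FL,
    max_volume_fl: float = DEFAULT_MAX_VOLUME_FL,
    exclude_border: bool = True,
) -> LabelVolume:
    """Drop components outside the volume gate and, optionally, components
    touching any face of the volume; relabel survivors 1..K' in order."""
    if not 0 < min_volume_fl < max_volume_fl:
        raise ValueError("need 0 < min_volume_fl < max_volume_fl")
    labels = labelvol.labels
    k = int(labels.max())
    if k == 0:
        return labelvol
    voxvol = float(np.prod(labelvol.voxel_size))
    counts = np.bincount(labels.ravel(), minlength=k + 1)
    volumes = counts * voxvol
    keep = (volumes >= min_volume_fl) & (volumes <= max_volume_fl)
    keep[0] = False
    if exclude_border:
        for b in _border_labels(labels):
            keep[b] = False
    survivors = np.nonzero(keep)[0]
    if survivors.size == 0:
        logger.warning("all %d components removed by filtering", k)
    remap = np.zeros(k + 1, dtype=labels.dtype)
    remap[survivors] = np.arange(1, survivors.size + 1, dtype=labels.dtype)
    return LabelVolume(labels=remap[labels], voxel_size=labelvol.voxel_size)


def select_random_cells(records: Sequence, n: int, seed: int) -> list:
    """Uniform sample of n records without replacement (fixed-seed reproducible),
    mirroring the protocol of measuring a fixed number of randomly chosen cells."""
    if n > len(records):
        raise ValueError(f"requested {n} cells but only {len(records)} are available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[int(i)] for i in idx]
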