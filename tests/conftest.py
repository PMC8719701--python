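"""Shared fixtures: small synthetic volumes reused across test modules.

The expensive artifacts (a rasterized sphere and a small noiseless
simulated field, both segmented) are session-scoped so each is built once.
"""

import numpy as np
import pytest

from rbcmorph import geometry, segmentation, simulate
from rbcmorph.solutions import named_preset

CELL_RI = 1.40
MEDIUM_RI = 1.337
MIDPOINT = MEDIUM_RI + 0.5 * (CELL_RI - MEDIUM_RI)


@pytest.fixture(scope="session")
def sphere_setup():
    """A 3 um sphere rasterized at 0.1 um, thresholded at the midpoint."""
    tomo = geometry.rasterize_cell(
        geometry.spherocyte(3.0), 0.1, CELL_RI, MEDIUM_RI, supersample=3
    )
    mask = segmentation.binarize(tomo, MIDPOINT)
    labels = segmentation.label_components(mask, tomo.voxel_size)
    return tomo, labels, MIDPOINT


@pytest.fixture(scope="session")
def pbs_field():
    """Noiseless 5-cell spherical field with ground truth, segmented."""
    preset = named_preset("PBS", noise_sd=0.0)
    tomo, truth = simulate.simulate_field(preset, n_cells=5, seed=1)
    mask = segmentation.binarize(tomo, MIDPOINT)
    labels = segmentation.filter_cells(segmentation.label_components(mask, tomo.voxel_size))
    return tomo, truth, labels, MIDPOINT


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
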