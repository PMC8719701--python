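"""Morphometry estimators against closed forms and quadrature oracles.

The printed-group-mean sphericity checks use the reported PBS and AS means
(V = 81.77 fL, A = 128.11 um^2 and V = 89.27 fL, A = 166.10 um^2), which
round to 0.71 and 0.58 through Wadell's formula.
"""

import numpy as np
import pytest

from rbcmorph import geometry
from rbcmorph.io import LabelVolume, records_to_frame
from rbcmorph.morphometry import (
    MeasurementError,
    aspect_ratio,
    cell_surface_area,
    cell_volume,
    fit_axes,
    measure_all,
    mesh_enclosed_volume,
    principal_axes_3d,
    sphericity,
)
from rbcmorph.segmentation import binarize, label_components
from rbcmorph.simulate import match_ground_truth

SPHERE_V = 4.0 / 3.0 * np.pi * 27.0
SPHERE_A = 4.0 * np.pi * 9.0


class TestCellVolume:
    def test_voxel_count_arithmetic(self):
        labels = np.zeros((20, 20, 20), np.int32)
        labels[:10, :10, :10] = 1  # 1000 voxels
        lv = LabelVolume(labels=labels, voxel_size=(0.1, 0.1, 0.1))
        assert cell_volume(lv, 1) == pytest.approx(1.0)

    def test_anisotropic_voxels(self):
        labels = np.ones((10, 10, 10), np.int32)
        lv = LabelVolume(labels=labels, voxel_size=(0.2, 0.1, 0.1))
        assert cell_volume(lv, 1) == pytest.approx(1000 * 0.002)

    def test_absent_id_raises(self):
        lv = LabelVolume(labels=np.zeros((4, 4, 4), np.int32), voxel_size=(0.1,) * 3)
        with pytest.raises(KeyError):
            cell_volume(lv, 3)

    def test_fine_sphere_within_1pct(self):
        patch = geometry.rasterize_cell(geometry.spherocyte(3.0), 0.05, 1.40, 1.337, supersample=2)
        mask = binarize(patch, 1.3685)
        lv = label_components(mask, patch.voxel_size)
        assert cell_volume(lv, 1) == pytest.approx(SPHERE_V, rel=0.01)


class TestSurfaceArea:
    def test_sphere_within_2pct(self, sphere_setup):
        tomo, labels, thr = sphere_setup
        assert cell_surface_area(tomo, labels, 1, thr) == pytest.approx(SPHERE_A, rel=0.02)

    def test_error_halves_with_voxel_size(self):
        errs = []
        for voxel in (0.4, 0.2):
            patch = geometry.rasterize_cell(
                geometry.spherocyte(3.0), voxel, 1.40, 1.337, supersample=3
            )
            mask = binarize(patch, 1.3685)
            lv = label_components(mask, patch.voxel_size)
            a = cell_surface_area(patch, lv, 1, 1.3685)
            errs.append(abs(a - SPHERE_A) / SPHERE_A)
        assert errs[1] < 0.6 * errs[0]  # observed order ~1-2

    def test_discocyte_area_matches_quadrature(self):
        d = geometry.default_discocyte()
        a_true = geometry.shape_surface_area_analytic(d)  # 134.09 um^2
        patch = geometry.rasterize_cell(d, 0.05, 1.40, 1.337, supersample=2)
        mask = binarize(patch, 1.3685)
        lv = label_components(mask, patch.voxel_size)
        assert cell_surface_area(patch, lv, 1, 1.3685) == pytest.approx(a_true, rel=0.03)

    def test_tiny_cell_rejected(self):
        from rbcmorph.io import Tomogram

        vals = np.full((6, 6, 6), 1.337, np.float32)
        vals[2:3, 2:3, 2:4] = 1.40
        tomo = Tomogram(values=vals, voxel_size=(0.1,) * 3, medium_ri=1.337)
        labels = (vals > 1.3685).astype(np.int32)
        lv = LabelVolume(labels=labels, voxel_size=(0.1,) * 3)
        with pytest.raises(MeasurementError, match="need >= 8"):
            cell_surface_area(tomo, lv, 1, 1.3685)

    def test_mesh_enclosed_volume_close_to_voxel_count(self, sphere_setup):
        tomo, labels, thr = sphere_setup
        v_mesh = mesh_enclosed_volume(tomo, labels, 1, thr)
        assert v_mesh == pytest.approx(SPHERE_V, rel=0.02)


class TestSphericity:
    def test_sphere_is_exactly_one(self):
        for r in (1.0, 2.823, 5.0):
            v = 4.0 / 3.0 * np.pi * r**3
            a = 4.0 * np.pi * r**2
            assert sphericity(v, a) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "v, a, expected3, printed",
        [(81.77, 128.11, 0.711, 0.71), (89.27, 166.10, 0.582, 0.58)],
    )
    def test_printed_group_means(self, v, a, expected3, printed):
        psi = sphericity(v, a)
        assert round(psi, 3) == expected3
        assert round(psi, 2) == printed

    def test_above_one_unclipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            psi = sphericity(113.097, 100.0)
        assert psi > 1.0
        assert any("exceeds 1" in r.message for r in caplog.records)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 100.0)


def _projected_label(mask2d, nz=6, voxel=(0.1, 0.1, 0.1)):
    labels = np.zeros((nz,) + mask2d.shape, np.int32)
    labels[2:4] = mask2d[None].astype(np.int32)
    return LabelVolume(labels=labels, voxel_size=voxel)


class TestFitAxes:
    def test_disk_diameters(self):
        yy, xx = np.mgrid[:101, :101]
        disk = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2  # r = 3 um at 0.1 um pixels
        lv = _projected_label(disk)
        long_, short = fit_axes(lv, 1)
        assert long_ == pytest.approx(6.0, rel=0.02)
        assert short == pytest.approx(6.0, rel=0.02)

    def test_ellipse_diameters(self):
        yy, xx = np.mgrid[:121, :121]
        ell = ((yy - 60) / 40.0) ** 2 + ((xx - 60) / 20.0) ** 2 <= 1.0  # semi-axes 4, 2 um
        lv = _projected_label(ell)
        long_, short = fit_axes(lv, 1)
        assert long_ == pytest.approx(8.0, rel=0.02)
        assert short == pytest.approx(4.0, rel=0.02)

    def test_rotation_invariance(self):
        yy, xx = np.mgrid[:141, :141]
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        u = c * (yy - 70) + s * (xx - 70)
        v = -s * (yy - 70) + c * (xx - 70)
        ell = (u / 40.0) ** 2 + (v / 20.0) ** 2 <= 1.0
        lv = _projected_label(ell)
        long_, short = fit_axes(lv, 1)
        assert long_ == pytest.approx(8.0, rel=0.02)
        assert short == pytest.approx(4.0, rel=0.02)

    def test_collinear_projection_rejected(self):
        line = np.zeros((50, 50), bool)
        line[10, 5:25] = True
        with pytest.raises(MeasurementError, match="collinear"):
            fit_axes(_projected_label(line), 1)

    def test_too_few_pixels_rejected(self):
        dots = np.zeros((50, 50), bool)
        dots[10, 10] = True
        with pytest.raises(MeasurementError, match=">= 4"):
            fit_axes(_projected_label(dots), 1)


class TestAspectRatio:
    def test_basic_ratio(self):
        assert aspect_ratio(8.0, 4.0) == pytest.approx(0.5)

    def test_circle_is_one(self):
        assert aspect_ratio(6.0, 6.0) == 1.0

    def test_printed_pbs_axes(self):
        assert aspect_ratio(6.44, 5.74) == pytest.approx(0.891, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aspect_ratio(4.0, 8.0)
        with pytest.raises(ValueError):
            aspect_ratio(8.0, 0.0)


class TestMeasureAll:
    def test_recovers_ground_truth(self, pbs_field):
        tomo, truth, labels, thr = pbs_field
        records, errors = measure_all(tomo, labels, thr)
        assert len(records) == 5 and not errors
        matched = match_ground_truth(records_to_frame(records), truth)
        np.testing.assert_allclose(matched["volume_fl"], matched["true_volume_fl"], rtol=0.02)
        np.testing.assert_allclose(
            matched["surface_area_um2"], matched["true_surface_area_um2"], rtol=0.02
        )

    def test_spherical_population_sphericity(self, pbs_field):
        tomo, truth, labels, thr = pbs_field
        records, _ = measure_all(tomo, labels, thr)
        psi = np.array([r.sphericity for r in records])
        assert ((psi >= 0.95) & (psi <= 1.02)).all()

    def test_mean_ri_and_centroid_populated(self, pbs_field):
        tomo, truth, labels, thr = pbs_field
        records, _ = measure_all(tomo, labels, thr)
        for r in records:
            assert 1.37 < r.mean_ri < 1.45
            assert not r.touches_border

    def test_per_cell_error_collected_not_fatal(self, pbs_field):
        tomo, truth, labels, thr = pbs_field
        # graft a sub-8-voxel speck as an extra label
        bad = labels.labels.copy()
        k = labels.n_cells + 1
        bad[0:1, 0:1, 0:3] = k
        lv = LabelVolume(labels=bad, voxel_size=labels.voxel_size)
        records, errors = measure_all(tomo, lv, thr)
        assert len(records) == 5
        assert len(errors) == 1 and errors[0].cell_id == k


def test_principal_axes_of_flat_discocyte():
    d = geometry.default_discocyte()
    patch = geometry.rasterize_cell(d, 0.1, 1.40, 1.337, supersample=2)
    mask = binarize(patch, 1.3685)
    lv = label_components(mask, patch.voxel_size)
    a, b, c = principal_axes_3d(lv, 1)
    assert a == pytest.approx(b, rel=0.02)  # axisymmetric
    assert c < a  # flat along the symmetry axis
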