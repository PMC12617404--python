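import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from phenoprofiler.features import (
    ASPECT_CAP,
    center_of_mass_distance,
    centrosomal_intensity,
    ellipse_aspect,
    intensity_features,
    mask_shape_features,
    nuclear_marker_intensity,
)


def disk_mask(radius, pad=10):
    side = 2 * (radius + pad)
    mask = np.zeros((side, side), bool)
    rr, cc = draw_disk((side // 2, side // 2), radius)
    mask[rr, cc] = True
    return mask


class TestMaskShapeFeatures:
    def test_disk_circularity_near_one(self):
        out = mask_shape_features(disk_mask(50))
        assert out["circularity"] >= 0.99

    def test_square_circularity(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        out = mask_shape_features(mask)
        assert out["mask_area"] == 10000
        assert out["circularity"] == pytest.approx(math.pi / 4, abs=0.02)

    def test_thin_bar_low_circularity(self):
        mask = np.zeros((10, 120), bool)
        mask[5, 10:110] = True
        assert mask_shape_features(mask)["circularity"] < 0.1

    def test_empty_mask_missing(self):
        out = mask_shape_features(np.zeros((5, 5), bool))
        assert math.isnan(out["mask_area"])

    def test_centroid(self):
        mask = np.zeros((20, 20), bool)
        mask[4:7, 10:13] = True
        assert mask_shape_features(mask)["centroid"] == (5.0, 11.0)

    def test_rotation_90_invariant(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage as ndi

        mask = ndi.binary_dilation(rng.random((40, 60)) > 0.9, iterations=3)
        a = mask_shape_features(mask)
        b = mask_shape_features(np.rot90(mask))
        assert a["mask_area"] == b["mask_area"]
        # contour simplification restarts at a different vertex after
        # rotation, so equality holds only to a small tolerance
        assert a["circularity"] == pytest.approx(b["circularity"], abs=0.02)

    def test_upscale_area_and_circularity(self):
        mask = disk_mask(25)
        big = np.kron(mask, np.ones((2, 2), bool))
        a = mask_shape_features(mask)
        b = mask_shape_features(big)
        assert b["mask_area"] == pytest.approx(4 * a["mask_area"], rel=0.02)
        assert b["circularity"] == pytest.approx(a["circularity"], abs=0.02)


class TestEllipseAspect:
    def test_disk(self):
        assert ellipse_aspect(disk_mask(30)) == pytest.approx(1.0, abs=0.02)

    def test_rectangle_60x20(self):
        mask = np.zeros((80, 40), bool)
        mask[10:70, 10:30] = True
        assert ellipse_aspect(mask) == pytest.approx(3.0, abs=0.05)

    def test_degenerate_line_capped(self):
        mask = np.zeros((5, 40), bool)
        mask[2, 5:35] = True
        assert ellipse_aspect(mask) == ASPECT_CAP


class TestIntensityFeatures:
    def test_constant_region(self):
        plane = np.full((10, 10), 100.0)
        mask = np.ones((10, 10), bool)
        out = intensity_features(plane, mask, mask)
        assert out == {"mean": 100.0, "cv": 0.0, "area": 100}

    def test_two_value_cv(self):
        plane = np.array([[50.0, 150.0]] * 2)
        mask = np.ones((2, 2), bool)
        out = intensity_features(plane, mask, mask)
        assert out["mean"] == pytest.approx(100.0)
        assert out["cv"] == pytest.approx(0.5)

    def test_empty_intersection_missing(self):
        plane = np.ones((4, 4))
        a = np.zeros((4, 4), bool)
        a[0, 0] = True
        b = np.zeros((4, 4), bool)
        b[3, 3] = True
        out = intensity_features(plane, a, b)
        assert all(math.isnan(v) for v in out.values())


class TestCenterOfMassDistance:
    def test_identical_masks_zero(self):
        plane = np.random.default_rng(0).uniform(1, 10, (20, 20))
        mask = disk_mask(5, pad=5)
        assert center_of_mass_distance(plane, mask, plane, mask) == 0.0

    def test_point_masses_3_4_5(self):
        plane = np.ones((10, 10))
        a = np.zeros((10, 10), bool)
        a[0, 0] = True
        b = np.zeros((10, 10), bool)
        b[3, 4] = True
        assert center_of_mass_distance(plane, a, plane, b) == pytest.approx(5.0)

    def test_shifted_disk(self):
        plane = np.ones((60, 80))
        mask = np.zeros((60, 80), bool)
        rr, cc = draw_disk((30, 30), 10)
        mask[rr, cc] = True
        shifted = np.roll(mask, 10, axis=1)
        d = center_of_mass_distance(plane, mask, plane, shifted)
        assert d == pytest.approx(10.0, abs=0.01)

    def test_empty_mask_missing(self):
        plane = np.ones((5, 5))
        assert math.isnan(
            center_of_mass_distance(plane, np.zeros((5, 5), bool), plane, plane > 0)
        )


class TestNuclearMarkerIntensity:
    def test_background_subtraction(self):
        plane = np.full((20, 20), 100.0)
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:10, 5:10] = True
        plane[nucleus] = 500.0
        background = ~nucleus
        assert nuclear_marker_intensity(plane, nucleus, background) == pytest.approx(400.0)

    def test_uniform_image_zero(self):
        plane = np.full((10, 10), 77.0)
        nucleus = np.zeros((10, 10), bool)
        nucleus[2:5, 2:5] = True
        assert nuclear_marker_intensity(plane, nucleus, ~nucleus) == pytest.approx(0.0)

    def test_empty_background_warns(self):
        plane = np.full((6, 6), 10.0)
        nucleus = np.ones((6, 6), bool)
        with pytest.warns(UserWarning, match="background"):
            out = nuclear_marker_intensity(plane, nucleus, np.zeros((6, 6), bool))
        assert out == pytest.approx(10.0)


class TestCentrosomalIntensity:
    def _scene(self, amp):
        H = W = 64
        yy, xx = np.mgrid[:H, :W]
        centriole = 2000 * np.exp(-((yy - 30) ** 2 + (xx - 34) ** 2) / (2 * 1.2**2))
        marker = 100 + amp * np.exp(-((yy - 30) ** 2 + (xx - 34) ** 2) / (2 * 2.0**2))
        cell = np.ones((H, W), bool)
        return marker, centriole, cell

    def test_monotone_in_amplitude(self):
        values = []
        for amp in (0, 300, 600, 900):
            marker, centriole, cell = self._scene(amp)
            v, focus = centrosomal_intensity(marker, centriole, cell)
            assert focus is not None
            assert math.hypot(focus[0] - 30, focus[1] - 34) < 1.0
            values.append(v)
        assert values == sorted(values)
        assert values[0] == pytest.approx(0.0, abs=1e-6)

    def test_no_centriole_signal_missing(self):
        marker = np.full((32, 32), 100.0)
        centriole = np.zeros((32, 32))
        v, focus = centrosomal_intensity(marker, centriole, np.ones((32, 32), bool))
        assert math.isnan(v) and focus is None

    def test_uniform_marker_zero(self):
        marker = np.full((64, 64), 100.0)
        _, centriole, cell = self._scene(0)
        v, _ = centrosomal_intensity(marker, centriole, cell)
        assert v == pytest.approx(0.0, abs=1e-9)


class TestComputeProfile:
    def test_fully_populated_interphase(self, small_profile):
        table, truth = small_profile
        interphase = [t.cell_id for t in truth.cells if t.phase == "interphase"
                      and t.golgi_state in ("packed", "dispersed")]
        rows = table[table.cell_id.isin(interphase)]
        core = ["mask_area", "circularity", "area_nuc", "aspect_nuc", "mean_nuc",
                "mean_Golgi", "peaks_num_Golgi", "dist_nuc_Golgi", "mean_EdU",
                "mean_ki67", "cv_ki67", "objects_num_golgi"]
        assert not rows[core].isna().any().any()

    def test_mitotic_smaller_and_rounder(self, small_profile):
        table, truth = small_profile
        phase = {t.cell_id: t.phase for t in truth.cells}
        table = table.assign(phase=[phase[c] for c in table.cell_id])
        med = table.groupby("phase")[["mask_area", "circularity"]].median()
        assert med.loc["mitotic", "mask_area"] < med.loc["interphase", "mask_area"]
        assert med.loc["mitotic", "circularity"] > med.loc["interphase", "circularity"]

    def test_unmapped_role_missing_not_dropped(self, small_scene):
        from phenoprofiler.features import profile_image
        from phenoprofiler.image_io import ChannelMap

        image, mask, _, _ = small_scene
        cm = ChannelMap(roles={"nucleus": "dapi", "golgi": "gm130"})
        table = profile_image(image, mask, cm)
        assert "peaks_num_atubulin" in table.columns
        assert table["peaks_num_atubulin"].isna().all()
        assert table["peaks_num_Golgi"].notna().any()
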