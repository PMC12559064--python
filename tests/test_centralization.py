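import numpy as np
import pytest

from perfmosaic.centralization import (CentralizationMap, RadialProfile,
                                       centralization_map,
                                       centralization_metric,
                                       detect_hilar_point,
                                       distance_map_hilum,
                                       distance_map_periphery, fit_slope,
                                       radial_profile)
from perfmosaic.imaging import CTVolume, SegmentationSet
from perfmosaic.phantom import PhantomSpec, generate_chest_phantom

from conftest import make_two_box_seg


def quiet_seg(left, right, veins, shape):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SegmentationSet(lung_left=left, lung_right=right, veins=veins,
                               grid_shape=shape)


class TestHilarPoint:
    def test_centroid_of_listed_points(self):
        shape = (24, 24, 24)
        left = np.zeros(shape, bool); left[2:8, 8:16, 8:16] = True
        right = np.zeros(shape, bool); right[16:22, 8:16, 8:16] = True
        veins = np.zeros(shape, bool)
        # voxel centers at (10,10,10), (12,10,10), (14,10,10) with 2mm voxels
        for i in (4, 5, 6):
            veins[i, 4, 4] = True
        seg = quiet_seg(left, right, veins, shape)
        h = detect_hilar_point(seg, "left", (2.0, 2.0, 2.0))
        np.testing.assert_allclose(h.position_mm, [11.0, 9.0, 9.0])
        assert h.n_vein_voxels_used == 3

    def test_intrapulmonary_only_veins_error(self):
        seg0 = make_two_box_seg()
        veins = np.zeros(seg0.grid_shape, bool)
        veins[2, 3, 3] = True   # inside the left lung
        seg = quiet_seg(seg0.lung_left, seg0.lung_right, veins, seg0.grid_shape)
        with pytest.raises(ValueError, match="no extrapulmonary vein voxels"):
            detect_hilar_point(seg, "left", (1.0, 1.0, 1.0))

    def test_phantom_entry_detection(self, default_phantom):
        spec, vol, seg, truth = default_phantom
        diag = np.linalg.norm(vol.spacing)
        for side in ("left", "right"):
            h = detect_hilar_point(seg, side, vol.spacing)
            assert np.linalg.norm(h.position_mm - truth.vein_entry_mm[side]) \
                <= diag


class TestDistanceMaps:
    def test_single_voxel_lung(self):
        shape = (9, 9, 9)
        m = np.zeros(shape, bool); m[4, 4, 4] = True
        d = distance_map_periphery(m, (1.0, 2.0, 3.0))
        assert 0 < d[4, 4, 4] <= 1.0   # one voxel along the finest axis

    def test_digital_ball_center_distance(self):
        shape = (31, 31, 31)
        idx = np.indices(shape).reshape(3, -1).T
        ball = (np.linalg.norm((idx - 15) * 1.0, axis=1) <= 10.0).reshape(shape)
        d = distance_map_periphery(ball, (1.0, 1.0, 1.0))
        assert d[15, 15, 15] == pytest.approx(10.0, abs=np.sqrt(3) / 2 + 1.0)
        # boundary voxels sit within one voxel diagonal of the background
        boundary = ball & ~np.all(
            [np.roll(ball, s, a) for a in range(3) for s in (1, -1)], axis=0)
        assert d[boundary].max() <= np.sqrt(3) + 1e-9

    def test_hilum_distance_is_pythagorean(self):
        from perfmosaic.centralization import HilarPoint
        shape = (10, 10, 10)
        m = np.ones(shape, bool)
        h = HilarPoint(side="left", position_mm=np.array([0.5, 1.0, 1.5]),
                       n_vein_voxels_used=1)
        d = distance_map_hilum(m, h, (1.0, 2.0, 3.0))
        assert d[0, 0, 0] == pytest.approx(0.0)
        assert d[3, 0, 0] == pytest.approx(3.0)     # 3 voxels * 1 mm along x
        idx = np.array([[2, 3, 4], [7, 1, 6]])
        expect = np.linalg.norm((idx + 0.5) * [1, 2, 3] - h.position_mm, axis=1)
        np.testing.assert_allclose([d[2, 3, 4], d[7, 1, 6]], expect)


class TestCentralizationMap:
    def test_analytic_spot_values(self):
        shape = (3, 3, 3)
        m = np.ones(shape, bool)
        dh = np.zeros(shape); dp = np.zeros(shape)
        dh[0, 0, 0], dp[0, 0, 0] = 0.0, 20.0     # at the hilum
        dh[1, 1, 1], dp[1, 1, 1] = 20.0, 0.0     # on the pleura
        dh[2, 2, 2], dp[2, 2, 2] = 30.0, 10.0
        cm = centralization_map(dh, dp, m, "left")
        assert cm.values[0, 0, 0] == 0.0
        assert cm.values[1, 1, 1] == 1.0
        assert cm.values[2, 2, 2] == pytest.approx(0.75)
        assert cm.values[0, 1, 0] == 0.5          # 0/0 convention

    def test_bounded_on_phantom(self, default_phantom):
        _, vol, seg, truth = default_phantom
        for side in ("left", "right"):
            lung = seg.lung(side)
            h = detect_hilar_point(seg, side, vol.spacing)
            cm = centralization_map(distance_map_hilum(lung, h, vol.spacing),
                                    distance_map_periphery(lung, vol.spacing),
                                    lung, side)
            vals = cm.values[lung]
            assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestRadialProfile:
    @staticmethod
    def _uniform_case(value=-800.0):
        shape = (24, 24, 24)
        lung = np.zeros(shape, bool); lung[4:20, 4:20, 4:20] = True
        vol = CTVolume(data=np.full(shape, value, dtype=np.float32),
                       spacing=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(0)
        rel = np.zeros(shape)
        rel[lung] = rng.uniform(0, 1, size=int(lung.sum()))
        cm = CentralizationMap(values=rel, mask=lung, side="left")
        return vol, lung, cm

    def test_uniform_lung_flat_profile(self):
        vol, lung, cm = self._uniform_case()
        prof = radial_profile(vol, lung, cm)
        assert np.all(prof.n_voxels.sum() == int(lung.sum()))
        nz = prof.n_voxels > 0
        np.testing.assert_allclose(prof.mean_hu[nz], -800.0)

    def test_exact_linear_field_recovered(self):
        vol, lung, cm = self._uniform_case()
        data = vol.data.copy()
        data[lung] = -800.0 + 100.0 * cm.values[lung]
        vol2 = CTVolume(data=data, spacing=vol.spacing)
        prof = radial_profile(vol2, lung, cm)
        nz = prof.n_voxels > 0
        # bin means sit at the bin-center value within the within-bin spread
        half_bin = 100.0 / 21 / 2
        assert np.all(np.abs(prof.mean_hu[nz]
                             - (-800.0 + 100.0 * prof.bin_centers[nz]))
                      <= half_bin)
        slope, intercept, r2 = fit_slope(prof)
        assert slope == pytest.approx(100.0, abs=2.0)
        assert r2 > 0.99

    def test_rel_one_falls_in_last_bin(self):
        vol, lung, cm = self._uniform_case()
        vals = cm.values.copy()
        vals[lung] = 1.0
        cm2 = CentralizationMap(values=vals, mask=lung, side="left")
        prof = radial_profile(vol, lung, cm2)
        assert prof.n_voxels[20] == int(lung.sum())
        assert prof.n_voxels[:20].sum() == 0


class TestFitSlope:
    def test_exact_line(self):
        centers = (np.arange(21) + 0.5) / 21
        prof = RadialProfile(bin_centers=centers,
                             mean_hu=-800.0 + 100.0 * centers,
                             n_voxels=np.full(21, 10), side="left")
        slope, intercept, r2 = fit_slope(prof)
        assert slope == pytest.approx(100.0)
        assert intercept == pytest.approx(-800.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_profile_zero_slope(self):
        centers = (np.arange(21) + 0.5) / 21
        prof = RadialProfile(bin_centers=centers, mean_hu=np.full(21, -750.0),
                             n_voxels=np.full(21, 10), side="left")
        slope, _, _ = fit_slope(prof)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(8)
        centers = (np.arange(21) + 0.5) / 21
        y = -780.0 - 120.0 * centers + rng.normal(0, 5, 21)
        n = np.full(21, 50); n[3] = 0; y[3] = np.nan   # one empty bin dropped
        prof = RadialProfile(bin_centers=centers, mean_hu=y, n_voxels=n,
                             side="left")
        slope, intercept, _ = fit_slope(prof)
        keep = n > 0
        x = centers[keep]; yy = y[keep]
        sl = (np.mean(x * yy) - x.mean() * yy.mean()) / (np.mean(x * x) - x.mean() ** 2)
        assert slope == pytest.approx(sl, rel=1e-10)
        assert intercept == pytest.approx(yy.mean() - sl * x.mean(), rel=1e-10)

    def test_too_few_regions_error(self):
        centers = (np.arange(21) + 0.5) / 21
        n = np.zeros(21, int); n[:2] = 5
        prof = RadialProfile(bin_centers=centers, mean_hu=np.full(21, -800.0),
                             n_voxels=n, side="left")
        with pytest.raises(ValueError, match="3 nonempty"):
            fit_slope(prof)


class TestEndToEnd:
    def test_mirror_symmetric_phantom_equal_slopes(self):
        spec = PhantomSpec(seed=13, radial_gradient=-100.0)
        vol, seg, truth = generate_chest_phantom(spec)
        nx = vol.shape[0]
        data = vol.data.copy(); data[nx // 2:] = data[:nx // 2][::-1]
        left = seg.lung_left.copy()
        right = left[::-1].copy()
        veins = seg.veins.copy()
        veins[nx // 2:] = veins[:nx // 2][::-1]
        vol2 = CTVolume(data=data, spacing=vol.spacing)
        seg2 = quiet_seg(left, right, veins, vol.shape)
        res = centralization_metric(vol2, seg2)
        assert abs(res.slope_left - res.slope_right) <= 1e-6
        assert res.slope_mean == pytest.approx(res.slope_left, abs=1e-6)

    def test_imposed_gradient_recovered(self):
        spec = PhantomSpec(grid_shape=(96, 120, 96), blob_scale=2.0,
                           means=(-840.0, -780.0, -700.0),
                           sds=(40.0, 40.0, 40.0),
                           radial_gradient=-150.0, seed=0)
        vol, seg, truth = generate_chest_phantom(spec)
        res = centralization_metric(vol, seg)
        assert res.slope_mean == pytest.approx(-150.0, abs=15.0)

    def test_gradient_free_mosaic_near_zero(self):
        spec = PhantomSpec(grid_shape=(96, 120, 96), blob_scale=2.0,
                           means=(-840.0, -780.0, -700.0),
                           sds=(40.0, 40.0, 40.0),
                           radial_gradient=0.0, seed=0)
        vol, seg, truth = generate_chest_phantom(spec)
        res = centralization_metric(vol, seg)
        assert abs(res.slope_mean) <= 5.0
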