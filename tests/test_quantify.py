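"""ROI statistics, ratio metrics, isocontour VOIs and threshold calibration."""

import numpy as np
import pytest

from ra223spect.phantoms import GeometryError, VoxelGrid
from ra223spect.projection import PlanarImage
from ra223spect.quantify import (
    DegenerateRegionError,
    MetricSet,
    RoiSpec,
    calibrate_threshold,
    hot_metrics,
    isocontour_voi,
    lbr,
    linearity,
    roi_mask,
    roi_stats,
    sbr,
    uptake_ratio,
)

#: Measured isocontour-VOI volumes (cm^3) of the 28-mm sphere at candidate
#: thresholds, per collimator, from the physical phantom measurement.
MEASURED_VOLUMES = {
    "MEGP": {50.0: 15.8, 60.0: 9.0, 70.0: 6.2, 80.0: 1.4},
    "HEGP": {50.0: 17.9, 60.0: 12.4, 70.0: 11.0, 80.0: 9.0},
}
TRUE_SPHERE_VOLUME = 11.5


def _planar(values, pixel=8.8):
    values = np.asarray(values, dtype=float)
    origin = -np.array(values.shape) * pixel / 2.0
    return PlanarImage(values, pixel, origin)


class TestRoiStats:
    def test_constant_image(self):
        img = _planar(np.full((32, 32), 7.0))
        mean, sd, n = roi_stats(img, RoiSpec("circle", (0.0, 0.0), 45.0))
        assert mean == 7.0 and sd == 0.0 and n > 0

    def test_circle_mask_matches_pixel_center_oracle(self):
        img = _planar(np.zeros((32, 32)))
        roi = RoiSpec("circle", (10.0, -17.6), 45.0)
        mask = roi_mask(img, roi)
        # exhaustive double-loop pixel-centre membership
        expect = np.zeros((32, 32), dtype=bool)
        for i in range(32):
            for j in range(32):
                cx = img.origin[0] + (i + 0.5) * 8.8
                cz = img.origin[1] + (j + 0.5) * 8.8
                expect[i, j] = (cx - 10.0) ** 2 + (cz + 17.6) ** 2 <= 22.5**2
        assert np.array_equal(mask, expect)

    def test_roi_outside_image_raises(self):
        img = _planar(np.zeros((16, 16)))
        with pytest.raises(GeometryError):
            roi_stats(img, RoiSpec("circle", (200.0, 0.0), 45.0))

    def test_empty_roi_raises(self):
        img = _planar(np.zeros((16, 16)), pixel=10.0)
        # 1-mm circle centred on a pixel corner captures no pixel centre
        with pytest.raises(DegenerateRegionError):
            roi_stats(img, RoiSpec("circle", (0.0, 0.0), 1.0))

    def test_sphere_voi_on_volume(self):
        g = VoxelGrid.centered((20, 20, 20), 5.0)
        g.values[:] = 3.0
        mean, sd, n = roi_stats(g, RoiSpec("sphere", (0.0, 0.0, 0.0), 30.0))
        assert mean == 3.0 and sd == 0.0
        # voxel-centre count oracle for a 15-mm-radius sphere on 5-mm voxels
        centers = (np.arange(20) - 9.5) * 5.0
        d2 = (
            centers[:, None, None] ** 2
            + centers[None, :, None] ** 2
            + centers[None, None, :] ** 2
        )
        assert n == int((d2 <= 15.0**2).sum())


class TestHotMetrics:
    def _image_with_rois(self, rod_value, bkg_values):
        g = VoxelGrid.centered((40, 40, 3), 8.8)
        k = 1
        z = float(g.axis_centers(2)[k])
        rod = RoiSpec("circle", (0.0, 0.0, z), 45.0, k)
        g.values[roi_mask(g, rod)] = rod_value
        bkg = []
        for b, val in enumerate(bkg_values):
            a = 2 * np.pi * b / len(bkg_values)
            spec = RoiSpec(
                "circle", (110.0 * np.cos(a), 110.0 * np.sin(a), z), 45.0, k
            )
            g.values[roi_mask(g, spec)] = val
            bkg.append(spec)
        return g, rod, bkg

    def test_hand_computed_example(self):
        values = [90.0, 95.0, 100.0, 105.0, 110.0, 100.0, 95.0, 105.0]
        g, rod, bkg = self._image_with_rois(300.0, values)
        m = hot_metrics(g, rod, bkg)
        assert m.BKG == pytest.approx(100.0)
        assert m.HBR == pytest.approx(3.0)
        assert m.SD == pytest.approx(np.std(values, ddof=1))
        assert m.CNR == pytest.approx(200.0 / np.std(values, ddof=1))

    def test_degenerate_sd_makes_cnr_undefined(self):
        g, rod, bkg = self._image_with_rois(300.0, [100.0] * 8)
        m = hot_metrics(g, rod, bkg)
        assert m.HBR == pytest.approx(3.0) and m.SD == 0.0
        with pytest.raises(DegenerateRegionError):
            m.CNR

    def test_equal_rod_and_background_gives_zero_cnr(self):
        g, rod, bkg = self._image_with_rois(100.0, [90.0, 110.0, 95.0, 105.0])
        assert hot_metrics(g, rod, bkg).CNR == pytest.approx(0.0)

    def test_needs_two_background_rois(self):
        g, rod, bkg = self._image_with_rois(1.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            hot_metrics(g, rod, bkg[:1])


def _brute_force_isocontour(values, region, frac):
    """Exhaustive threshold + flood-fill (6-connectivity) oracle."""
    vmax = values[region].max()
    above = region & (values >= frac * vmax)
    peak = np.unravel_index(np.argmax(np.where(region, values, -np.inf)), values.shape)
    seen = {peak}
    stack = [peak]
    while stack:
        i, j, k = stack.pop()
        for di, dj, dk in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
            q = (i + di, j + dj, k + dk)
            if (
                all(0 <= q[a] < values.shape[a] for a in range(3))
                and q not in seen
                and above[q]
            ):
                seen.add(q)
                stack.append(q)
    return seen


class TestIsocontour:
    def test_constructed_3x3x3_example(self):
        g = VoxelGrid.centered((3, 3, 3), 10.0)
        g.values[:] = 10.0
        g.values[1, 1, 1] = 100.0
        for d in ((0,1,1),(2,1,1),(1,0,1),(1,2,1),(1,1,0),(1,1,2)):
            g.values[d] = 60.0
        mask, vol = isocontour_voi(g, np.ones((3, 3, 3), bool), 0.6)
        assert mask.sum() == 7
        assert vol == pytest.approx(7.0)  # 1 cm^3 voxels

    def test_full_threshold_keeps_only_maximum(self):
        g = VoxelGrid.centered((5, 5, 5), 10.0)
        g.values = np.arange(125, dtype=float).reshape(5, 5, 5)
        mask, _ = isocontour_voi(g, np.ones((5, 5, 5), bool), 1.0)
        assert mask.sum() == 1 and mask[4, 4, 4]

    def test_matches_flood_fill_oracle_on_blurred_sphere(self, rng):
        from scipy.ndimage import gaussian_filter

        g = VoxelGrid.centered((24, 24, 24), 4.0)
        c = (np.arange(24) - 11.5) * 4.0
        d2 = c[:, None, None]**2 + c[None, :, None]**2 + c[None, None, :]**2
        g.values = gaussian_filter((d2 <= 20.0**2).astype(float), 2.0)
        g.values += rng.normal(0, 1e-4, g.dims)  # break exact ties
        g.values = np.abs(g.values)
        region = np.ones(g.dims, bool)
        for frac in (0.4, 0.6, 0.8):
            mask, _ = isocontour_voi(g, region, frac)
            oracle = _brute_force_isocontour(g.values, region, frac)
            assert {tuple(p) for p in np.argwhere(mask)} == oracle

    def test_volume_nonincreasing_in_threshold(self):
        from scipy.ndimage import gaussian_filter

        g = VoxelGrid.centered((24, 24, 24), 4.0)
        c = (np.arange(24) - 11.5) * 4.0
        d2 = c[:, None, None]**2 + c[None, :, None]**2 + c[None, None, :]**2
        g.values = gaussian_filter((d2 <= 16.0**2).astype(float), 1.5)
        vols = [
            isocontour_voi(g, np.ones(g.dims, bool), f)[1]
            for f in (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_flat_zero_region_raises(self):
        g = VoxelGrid.centered((4, 4, 4), 10.0)
        with pytest.raises(DegenerateRegionError):
            isocontour_voi(g, np.ones((4, 4, 4), bool), 0.6)

    def test_threshold_fraction_validated(self):
        g = VoxelGrid.centered((4, 4, 4), 10.0)
        g.values[1, 1, 1] = 1.0
        with pytest.raises(ValueError):
            isocontour_voi(g, np.ones((4, 4, 4), bool), 0.0)


class TestCalibrateThreshold:
    def test_megp_table_alone_selects_60(self):
        chosen = calibrate_threshold(
            {"MEGP": MEASURED_VOLUMES["MEGP"]}, TRUE_SPHERE_VOLUME
        )
        assert chosen == 60.0

    def test_combined_tables_select_60(self):
        """Summed absolute volume errors across both collimators:
        50%: 10.7, 60%: 3.4, 70%: 5.8, 80%: 12.6 -> 60% wins."""
        chosen = calibrate_threshold(MEASURED_VOLUMES, TRUE_SPHERE_VOLUME)
        assert chosen == 60.0

    def test_tie_prefers_lower_threshold(self):
        sets = {"A": {50.0: 9.0, 60.0: 13.0, 70.0: 20.0, 80.0: 25.0}}
        assert calibrate_threshold(sets, 11.0) == 50.0  # errors 2, 2, 9, 14

    def test_missing_candidate_raises(self):
        with pytest.raises(ValueError):
            calibrate_threshold({"A": {50.0: 9.0}}, 11.5)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            calibrate_threshold({}, 11.5)


class TestRatioMetrics:
    def test_sbr_arithmetic(self):
        g = VoxelGrid.centered((30, 30, 30), 8.0)
        sphere = RoiSpec("sphere", (0.0, 0.0, 0.0), 30.0)
        g.values[roi_mask(g, sphere)] = 90.0
        bkgs = []
        for i, (c, v) in enumerate(zip(((80, 0, 0), (-80, 0, 0), (0, 80, 0)), (2, 3, 4))):
            spec = RoiSpec("sphere", tuple(float(x) for x in c), 30.0)
            g.values[roi_mask(g, spec)] = v
            bkgs.append(spec)
        assert sbr(g, sphere, bkgs) == pytest.approx(30.0)

    def test_sbr_of_uniform_image_is_one(self):
        g = VoxelGrid.centered((30, 30, 30), 8.0)
        g.values[:] = 5.0
        sphere = RoiSpec("sphere", (0.0, 0.0, 0.0), 30.0)
        bkg = [RoiSpec("sphere", (80.0, 0.0, 0.0), 30.0)]
        assert sbr(g, sphere, bkg) == pytest.approx(1.0)

    def test_zero_background_raises(self):
        g = VoxelGrid.centered((30, 30, 30), 8.0)
        sphere = RoiSpec("sphere", (0.0, 0.0, 0.0), 30.0)
        g.values[roi_mask(g, sphere)] = 9.0
        with pytest.raises(DegenerateRegionError):
            sbr(g, sphere, [RoiSpec("sphere", (80.0, 0.0, 0.0), 30.0)])

    def test_uptake_ratio_identity(self):
        g = VoxelGrid.centered((20, 20, 20), 8.0)
        g.values[:] = 3.3
        r = RoiSpec("sphere", (0.0, 0.0, 0.0), 30.0)
        assert uptake_ratio(g, r, r, method="roi") == pytest.approx(1.0)

    def test_scale_invariance_of_all_ratio_metrics(self, rng):
        """Multiplying an image by c > 0 leaves HBR, CNR, SBR, the uptake
        ratio and LBR unchanged."""
        g = VoxelGrid.centered((32, 32, 32), 8.0)
        g.values = rng.uniform(1.0, 2.0, g.dims)
        hot = RoiSpec("sphere", (0.0, 0.0, 0.0), 40.0)
        g.values[roi_mask(g, hot)] += 30.0
        bkgs = [
            RoiSpec("sphere", (90.0, 0.0, 0.0), 40.0),
            RoiSpec("sphere", (-90.0, 0.0, 0.0), 40.0),
            RoiSpec("sphere", (0.0, 90.0, 0.0), 40.0),
        ]
        rod_roi = RoiSpec("circle", (0.0, 0.0, 0.0), 40.0)
        bkg_rois = [RoiSpec("circle", (90.0 * np.cos(a), 90.0 * np.sin(a), 0.0), 40.0)
                    for a in np.linspace(0, 2 * np.pi, 5)[:-1]]

        def all_metrics(grid):
            m = hot_metrics(grid, rod_roi, bkg_rois)
            return (
                m.HBR,
                m.CNR,
                sbr(grid, hot, bkgs),
                uptake_ratio(grid, hot, bkgs[0], method="roi"),
                lbr(grid, hot, bkgs[0]).value,
            )

        base = all_metrics(g)
        for c in (0.25, 7.0):
            scaled = g.like(g.values * c)
            assert all_metrics(scaled) == pytest.approx(base, rel=1e-12)


class TestLbr:
    def _volume(self, lesion_peak, bkg_value=10.0):
        g = VoxelGrid.centered((32, 32, 32), 6.0)
        g.values[:] = bkg_value
        lesion = RoiSpec("sphere", (0.0, 0.0, 0.0), 24.0)
        g.values[roi_mask(g, lesion)] = lesion_peak
        return g

    def test_ratio_of_means(self):
        g = self._volume(50.0)
        res = lbr(
            g,
            RoiSpec("sphere", (0.0, 0.0, 0.0), 40.0),
            RoiSpec("sphere", (60.0, 0.0, 0.0), 45.8),
        )
        assert res.included and res.value == pytest.approx(5.0)

    def test_inclusion_rule_excludes_faint_lesion(self):
        g = self._volume(15.0)  # max = 1.5 x reference mean
        res = lbr(
            g,
            RoiSpec("sphere", (0.0, 0.0, 0.0), 40.0),
            RoiSpec("sphere", (60.0, 0.0, 0.0), 45.8),
        )
        assert not res.included and res.value is None

    def test_matches_mask_replay(self, rng):
        g = self._volume(80.0)
        g.values += rng.uniform(0, 1, g.dims)
        search = RoiSpec("sphere", (0.0, 0.0, 0.0), 40.0)
        bkg = RoiSpec("sphere", (60.0, 0.0, 0.0), 45.8)
        res = lbr(g, search, bkg)
        mask, _ = isocontour_voi(g, search, 0.60)
        replay = g.values[mask].mean() / g.values[roi_mask(g, bkg)].mean()
        assert res.value == pytest.approx(replay, rel=1e-12)


class TestLinearity:
    def test_exact_line(self):
        fit = linearity([3.75, 7.5, 15.0], [7.5, 15.0, 30.0])
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_concentration_degenerate(self):
        with pytest.raises(DegenerateRegionError):
            linearity([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            linearity([1.0, 2.0], [1.0, 2.0])
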