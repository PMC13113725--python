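import numpy as np
import pytest

from aortaquant.quantify import (CrossSectionProfile, SegmentSpec, slice_area,
                                 slice_max_diameter, smooth_profile,
                                 subdivide_segments, summarize_segments,
                                 detect_dilation, calibrate_measurements,
                                 profile_from_straightened)


def random_blob(rng, size=40):
    """Random connected 2D blob via thresholded smoothed noise."""
    from scipy.ndimage import gaussian_filter, label

    field = gaussian_filter(rng.normal(size=(size, size)), 4.0)
    mask = field > np.percentile(field, 70)
    lab, n = label(mask)
    if n == 0:
        mask = np.zeros((size, size), bool)
        mask[size // 2, size // 2] = True
        return mask
    counts = np.bincount(lab.ravel())[1:]
    return lab == (np.argmax(counts) + 1)


def brute_force_max_diameter(mask, pixel_mm=1.0):
    """O(n^2) oracle over boundary pixel centers."""
    from scipy.ndimage import binary_erosion, generate_binary_structure, label

    lab, n = label(mask, structure=generate_binary_structure(2, 1))
    if n == 0:
        return 0.0
    counts = np.bincount(lab.ravel())[1:]
    comp = lab == (np.argmax(counts) + 1)
    er = binary_erosion(comp, structure=generate_binary_structure(2, 1),
                        border_value=0)
    pts = np.argwhere(comp & ~er).astype(float)
    best = 0.0
    for i in range(len(pts)):
        d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
        if len(d):
            best = max(best, d.max())
    return best * pixel_mm


class TestSliceArea:
    def test_empty_is_zero(self):
        assert slice_area(np.zeros((5, 5), dtype=bool), 1.0) == 0.0

    def test_solid_square(self):
        assert slice_area(np.ones((10, 10), dtype=bool), 1.0) == 100.0

    def test_disc_oracle(self):
        x, y = np.meshgrid(np.arange(25), np.arange(25), indexing="ij")
        disc = (x - 12) ** 2 + (y - 12) ** 2 <= 100
        assert slice_area(disc, 1.0) == pytest.approx(np.pi * 100, rel=0.02)

    def test_pixel_scaling(self):
        sq = np.ones((4, 4), dtype=bool)
        assert slice_area(sq, 0.5) == pytest.approx(4.0)

    def test_largest_component_only(self):
        m = np.zeros((20, 20), dtype=bool)
        m[1:10, 1:10] = True
        m[15:17, 15:17] = True
        assert slice_area(m, 1.0) == 81.0


class TestSliceMaxDiameter:
    def test_single_pixel_is_zero(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert slice_max_diameter(m, 1.0) == 0.0

    def test_collinear_row(self):
        m = np.zeros((3, 15), dtype=bool)
        m[1, 2:13] = True  # 11 pixels -> 10 mm between end centers
        assert slice_max_diameter(m, 1.0) == pytest.approx(10.0)

    def test_empty_is_zero(self):
        assert slice_max_diameter(np.zeros((4, 4), dtype=bool), 1.0) == 0.0

    def test_matches_bruteforce_on_200_blobs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            mask = random_blob(rng)
            assert slice_max_diameter(mask, 1.0) == pytest.approx(
                brute_force_max_diameter(mask), abs=1e-9)

    def test_convex_isoperimetric_bound(self):
        # max diameter >= equivalent-disc diameter, convex shapes only
        x, y = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        for shape in [(x - 15) ** 2 + (y - 15) ** 2 <= 120,
                      (np.abs(x - 15) <= 8) & (np.abs(y - 15) <= 5)]:
            d = slice_max_diameter(shape, 1.0)
            a = slice_area(shape, 1.0)
            assert d >= 2 * np.sqrt(a / np.pi) - 1.0  # 1 px center bias


class TestSmoothProfile:
    def test_constant_unchanged(self):
        x = np.full(50, 30.0)
        np.testing.assert_allclose(smooth_profile(x), x, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(41.0) ** 2
        np.testing.assert_allclose(smooth_profile(x, 11, 2), x, atol=1e-9)

    def test_window5_kernel_recovered(self):
        from aortaquant.quantify import _savgol_kernel

        np.testing.assert_allclose(
            _savgol_kernel(5, 2),
            np.array([-3, 12, 17, 12, -3]) / 35.0, atol=1e-12)

    def test_matches_scipy_interp_mode(self):
        from scipy.signal import savgol_filter

        rng = np.random.default_rng(7)
        x = rng.normal(size=80).cumsum()
        np.testing.assert_allclose(smooth_profile(x, 11, 2),
                                   savgol_filter(x, 11, 2, mode="interp"),
                                   atol=1e-9)

    def test_even_window_raises(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_profile(np.zeros(30), window=10)

    def test_order_ge_window_raises(self):
        with pytest.raises(ValueError, match="order"):
            smooth_profile(np.zeros(30), window=5, order=5)

    def test_short_sequence_warns_and_passes_through(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="window"):
            out = smooth_profile(x, 11, 2)
        np.testing.assert_array_equal(out, x)

    def test_max_shift_bounded_by_local_variation(self):
        rng = np.random.default_rng(3)
        x = 30 + rng.normal(scale=0.5, size=100)
        sm = smooth_profile(x, 11, 2)
        # smoothing never moves the max further than one window's local range
        i = int(np.argmax(x))
        lo, hi = max(0, i - 5), min(len(x), i + 6)
        local_var = x[lo:hi].max() - x[lo:hi].min()
        assert x.max() - sm.max() <= local_var + 1e-9


class TestSegments:
    def make_profile(self, n=301, diam=30.0):
        s = np.arange(n, dtype=float)
        d = np.full(n, diam)
        a = np.full(n, np.pi * (diam / 2) ** 2)
        trunc = np.zeros(n, dtype=bool)
        trunc[:3] = trunc[-3:] = True
        return CrossSectionProfile(s, d, d.copy(), a, a.copy(), trunc)

    def test_stated_convention(self):
        prof = self.make_profile()
        ranges = subdivide_segments(prof, SegmentSpec(100.0, 150.0))
        s = prof.arclength
        assert s[ranges["ascending"]].max() < 100.0
        assert s[ranges["arch"]].min() >= 100.0
        assert s[ranges["arch"]].max() <= 150.0
        assert s[ranges["descending"]].min() > 150.0

    def test_partition_of_nontruncated(self):
        prof = self.make_profile()
        ranges = subdivide_segments(prof, SegmentSpec(100.0, 150.0))
        merged = np.sort(np.concatenate(list(ranges.values())))
        np.testing.assert_array_equal(merged, np.flatnonzero(~prof.truncated))

    def test_equal_landmarks_raise(self):
        with pytest.raises(ValueError):
            SegmentSpec(100.0, 100.0)

    def test_landmark_beyond_length_raises(self):
        prof = self.make_profile(n=120)
        with pytest.raises(ValueError, match="total length"):
            subdivide_segments(prof, SegmentSpec(100.0, 150.0))

    def test_summary_constant_tube(self):
        prof = self.make_profile(diam=30.0)
        report = summarize_segments(prof, SegmentSpec(100.0, 150.0))
        for seg in ("whole", "ascending", "arch", "descending"):
            for stat in ("max", "mean", "median"):
                assert report.segments[seg]["diameter"][stat] == pytest.approx(
                    30.0, abs=2.0)

    def test_whole_max_equals_max_of_segments(self):
        rng = np.random.default_rng(0)
        prof = self.make_profile()
        prof.diameter_smooth += rng.normal(size=len(prof))
        report = summarize_segments(prof, SegmentSpec(100.0, 150.0))
        seg_max = max(report.segments[s]["diameter"]["max"]
                      for s in ("ascending", "arch", "descending"))
        assert report.segments["whole"]["diameter"]["max"] == pytest.approx(
            seg_max, abs=1e-12)


class TestDilation:
    def make_report(self, asc, arch, desc):
        prof = TestSegments().make_profile()
        report = summarize_segments(prof, SegmentSpec(100.0, 150.0))
        for name, val in (("ascending", asc), ("arch", arch),
                          ("descending", desc)):
            report.segments[name]["diameter"]["max"] = val
        return report

    def test_above_threshold_flagged(self):
        flags = detect_dilation(self.make_report(41.0, 30.0, 25.0))
        assert flags == {"ascending": True, "arch": False,
                         "descending": False, "any": True}

    def test_all_below(self):
        flags = detect_dilation(self.make_report(39.9, 34.0, 29.0))
        assert not flags["any"]

    def test_strict_inequality_at_boundary(self):
        flags = detect_dilation(self.make_report(40.0, 35.0, 30.0))
        assert not flags["any"]

    def test_missing_threshold_raises(self):
        with pytest.raises(KeyError, match="arch"):
            detect_dilation(self.make_report(10, 10, 10),
                            thresholds={"ascending": 40, "descending": 30})


class TestCalibration:
    def test_identity(self):
        cal = calibrate_measurements([(10, 10), (20, 20), (30, 30)])
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset(self):
        cal = calibrate_measurements([(10, 12), (20, 22), (30, 32)])
        assert cal.intercept == pytest.approx(2.0, abs=1e-12)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        m = rng.uniform(10, 50, size=50)
        ref = 1.5 + 0.9 * m + rng.normal(scale=0.5, size=50)
        cal = calibrate_measurements(np.column_stack([m, ref]))
        slope_o, icept_o = np.polyfit(m, ref, 1)
        assert cal.slope == pytest.approx(slope_o, abs=1e-9)
        assert cal.intercept == pytest.approx(icept_o, abs=1e-9)
        np.testing.assert_allclose(cal.apply(m), icept_o + slope_o * m,
                                   atol=1e-9)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_measurements([(5, 1), (5, 2), (5, 3)])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            calibrate_measurements([(1, 1), (2, 2)])


@pytest.fixture(scope="module")
def tube_profile(straight_tube):
    from aortaquant.centerline import Centerline
    from aortaquant.straighten import compute_frames, curved_planar_reformat

    mask, _ = straight_tube
    n = 99
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.arange(1.0, 100.0)])
    cl = Centerline(pts, np.arange(float(n)), 1.0)
    sv = curved_planar_reformat(mask, cl, compute_frames(cl), 60.0, "nearest")
    return profile_from_straightened(sv)


class TestProfileFromStraightened:
    def test_constant_diameter(self, tube_profile):
        interior = ~tube_profile.truncated
        d = tube_profile.diameter_raw[interior]
        assert np.percentile(d, 75) - np.percentile(d, 25) < 2.0
        assert np.median(d) == pytest.approx(30.0, abs=2.0)

    def test_channel_lengths_match(self, tube_profile):
        n = len(tube_profile)
        assert all(len(ch) == n for ch in (
            tube_profile.arclength, tube_profile.diameter_raw,
            tube_profile.diameter_smooth, tube_profile.area_raw,
            tube_profile.area_smooth, tube_profile.truncated))

    def test_bulge_located(self, candy_cane):
        from aortaquant.cli import RunConfig, run_quantify

        mask, truth = candy_cane
        lm = {"bct_point_mm": truth.landmark_points[0].tolist(),
              "lsa_point_mm": truth.landmark_points[1].tolist()}
        _, prof, cl, _ = run_quantify(RunConfig(), mask, lm)
        interior = ~prof.truncated
        s_peak = prof.arclength[interior][
            np.argmax(prof.diameter_smooth[interior])]
        assert abs(s_peak - 30.0) <= 5.0  # bulge centered at s0 = 30

    def test_empty_everywhere_raises(self):
        from aortaquant.centerline import Centerline
        from aortaquant.straighten import StraightenedVolume
        from aortaquant.volume_io import ImageVolume

        vol = ImageVolume(np.zeros((21, 21, 10), dtype=np.uint8), (1, 1, 1))
        pts = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        cl = Centerline(pts, np.arange(10.0), 1.0)
        sv = StraightenedVolume(vol, 20.0, cl, "nearest")
        with pytest.raises(ValueError, match="foreground"):
            profile_from_straightened(sv)
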