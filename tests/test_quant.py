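"""Core quantification: dF/F0 arithmetic, frame windows, stalk masking,
profile collapse, z-scoring and bilateral peak averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perivasc.geometry import StraightenedImage, VesselSegment, resample_polyline
from perivasc.quant import (
    MaskedColumnError,
    QuantConfig,
    QuantError,
    RadialProfile,
    apply_mask,
    collapse_profile,
    dff_trace,
    estimate_sigma_temporal,
    frame_average,
    peak_zscores,
    quantify_movie,
    stalk_mask,
    zscore_profile,
)
from perivasc.synthetic import TwoChannelMovie, generate_movie

from conftest import tiny_spec


def flat_movie(onset=10, n=30, h=20, w=20, f0=100.0):
    glial = np.full((n, h, w), f0)
    vessel = np.zeros((h, w))
    vessel[9:12, :] = 100.0
    return TwoChannelMovie(glial, vessel, 1.0, 0.5, onset)


def mid_segment(h=20, w=20):
    pts = np.array([[h / 2, 1.0], [h / 2, w - 2.0]])
    return VesselSegment(resample_polyline(pts, 1.0), radius_um=1.5, pixel_size_um=1.0)


class TestDffTrace:
    def test_constant_movie_is_zero(self):
        series, peak = dff_trace(flat_movie(), mid_segment(), 5.0)
        assert np.all(series == 0.0)
        assert peak == 0.0

    def test_eq1_arithmetic(self):
        """F0 = 100 and a peak-frame ROI mean of 188 give dF/F0 = 0.88."""
        m = flat_movie()
        m.glial[15] = 188.0
        series, peak = dff_trace(m, mid_segment(), 5.0)
        assert peak == pytest.approx(0.88)
        assert series[15] == pytest.approx(0.88)

    def test_single_frame_excursion(self):
        m = flat_movie()
        m.glial[12] = 150.0
        series, _ = dff_trace(m, mid_segment(), 5.0)
        assert series[12] == pytest.approx(0.5)

    def test_zero_baseline_rejected(self):
        m = flat_movie(f0=0.0)
        with pytest.raises(QuantError, match="F0"):
            dff_trace(m, mid_segment(), 5.0)


class TestFrameAverage:
    def test_baseline_window_precedes_onset(self):
        stack = np.arange(30, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        fa = frame_average(stack, "baseline", puff_onset_frame=20, n_frames=9)
        assert fa.frame_indices == list(range(11, 20))
        assert np.all(fa.values == 15.0)

    def test_peak_window_centered_and_clipped(self):
        stack = np.zeros((30, 2, 2))
        fa = frame_average(stack, "peak", 10, n_frames=9, peak_frame=25)
        assert fa.frame_indices == list(range(21, 30))
        fa2 = frame_average(stack, "peak", 10, n_frames=9, peak_frame=28)
        assert fa2.frame_indices == list(range(21, 30))  # clipped, count kept

    def test_alternating_frames_average_to_midpoint(self):
        stack = np.zeros((10, 3, 3))
        stack[1::2] = 2.0
        fa = frame_average(stack, "baseline", 10, n_frames=10)
        assert np.all(fa.values == 1.0)

    def test_insufficient_baseline_errors(self):
        with pytest.raises(QuantError, match="baseline"):
            frame_average(np.zeros((30, 2, 2)), "baseline", 5, n_frames=9)


class TestStalkMask:
    def test_exact_top_percentile_on_distinct_values(self):
        """On a 10x10 image with distinct values 1..100 the top-2% mask is
        exactly the pixels valued 99 and 100."""
        img = np.arange(1, 101, dtype=float).reshape(10, 10)
        sm = stalk_mask(img, percentile=2.0, dilation_iterations=0)
        assert set(img[sm.mask].ravel()) == {99.0, 100.0}

    def test_constant_image_gives_empty_mask(self):
        sm = stalk_mask(np.full((10, 10), 7.0), percentile=3.0, dilation_iterations=2)
        assert not sm.mask.any()

    def test_dilation_chebyshev_bound(self, rng):
        img = rng.uniform(0, 1, (30, 30))
        pre = stalk_mask(img, 3.0, dilation_iterations=0)
        post = stalk_mask(img, 3.0, dilation_iterations=2)
        pr, pc = np.nonzero(pre.mask)
        for r, c in zip(*np.nonzero(post.mask)):
            assert np.min(np.maximum(np.abs(pr - r), np.abs(pc - c))) <= 2

    def test_monotone_in_percentile_and_dilation(self, rng):
        img = rng.uniform(0, 1, (25, 25))
        m2 = stalk_mask(img, 2.0, 0).mask
        m4 = stalk_mask(img, 4.0, 0).mask
        assert np.all(m4 >= m2)
        d2 = stalk_mask(img, 3.0, 2).mask
        d3 = stalk_mask(img, 3.0, 3).mask
        assert np.all(d3 >= d2)

    def test_dilation_only_grows(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        pre = stalk_mask(img, 3.0, 0).mask
        post = stalk_mask(img, 3.0, 2).mask
        assert np.all(post >= pre)

    def test_percentile_contract(self):
        with pytest.raises(QuantError):
            stalk_mask(np.ones((5, 5)), percentile=0.0)

    def test_apply_mask_sets_nan(self):
        img = np.ones((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        out = apply_mask(img, mask)
        assert np.isnan(out[1, 2]) and np.isfinite(out).sum() == 15


class TestCollapse:
    def test_constant_collapse(self):
        st = StraightenedImage(np.full((10, 41), 2.5), 1.0)
        prof = collapse_profile(st)
        assert np.all(prof.delta_f == 2.5)
        assert prof.positions_um[20] == 0.0

    def test_exclusions_ignored_not_propagated(self):
        vals = np.full((10, 5), 3.0)
        vals[:5, 2] = np.nan
        prof = collapse_profile(StraightenedImage(vals, 1.0))
        assert prof.delta_f[2] == 3.0

    def test_fully_excluded_column_is_error(self):
        vals = np.ones((4, 5))
        vals[:, 3] = np.nan
        with pytest.raises(MaskedColumnError, match="3"):
            collapse_profile(StraightenedImage(vals, 1.0))

    def test_matches_bruteforce_exclusion_aware_mean(self, rng):
        vals = rng.normal(size=(20, 20))
        vals[rng.uniform(size=(20, 20)) < 0.2] = np.nan
        vals[0] = 1.0  # keep every column non-empty
        prof = collapse_profile(StraightenedImage(vals, 1.0))
        for j in range(20):
            acc, cnt = 0.0, 0
            for i in range(20):
                if np.isfinite(vals[i, j]):
                    acc += vals[i, j]
                    cnt += 1
            assert prof.delta_f[j] == pytest.approx(acc / cnt)


class TestZScore:
    def test_unit_sigma_identity(self):
        prof = RadialProfile(np.linspace(-20, 20, 41), np.full(41, 2.0))
        out = zscore_profile(prof, sigma=2.0)
        assert np.all(out.z == 1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, k):
        """Jointly rescaling dF and sigma leaves z unchanged."""
        base = np.linspace(-1, 3, 41)
        p1 = zscore_profile(
            RadialProfile(np.linspace(-20, 20, 41), base.copy()), sigma=1.5
        )
        p2 = zscore_profile(
            RadialProfile(np.linspace(-20, 20, 41), base * k), sigma=1.5 * k
        )
        np.testing.assert_allclose(p1.z, p2.z, rtol=1e-9)

    def test_temporal_sigma_recovers_noise_floor(self, rng):
        frames = rng.normal(0.0, 2.0, size=(200, 30, 30))
        assert estimate_sigma_temporal(frames) == pytest.approx(2.0, rel=0.05)

    def test_zero_sigma_instructs_override(self):
        prof = RadialProfile(np.linspace(-20, 20, 41), np.zeros(41))
        with pytest.raises(QuantError, match="override"):
            zscore_profile(prof, sigma=0.0)


class TestPeakZscores:
    def make_profile(self, z):
        n = len(z)
        pos = np.linspace(-20, 20, n)
        return RadialProfile(pos, np.asarray(z, float), z=np.asarray(z, float))

    def test_eq3_exact_average(self):
        pos = np.linspace(-20, 20, 41)
        z = np.zeros(41)
        z[pos == -5.0] = 2.0
        z[pos == 5.0] = 4.0
        prof = RadialProfile(pos, z, z=z)
        seg = mid_segment()
        lp, rp, ave = peak_zscores(prof, seg, 10.0)
        assert (lp, rp) == (2.0, 4.0)
        assert ave == (lp + rp) / 2

    def test_symmetric_profile_equal_sides(self):
        pos = np.linspace(-20, 20, 41)
        z = np.exp(-((np.abs(pos) - 3.0) ** 2))
        prof = RadialProfile(pos, z, z=z)
        lp, rp, ave = peak_zscores(prof, mid_segment(), 10.0)
        assert lp == rp == ave

    def test_mirrored_profile_swaps_sides(self, rng):
        pos = np.linspace(-20, 20, 41)
        z = rng.uniform(0, 1, 41)
        prof = RadialProfile(pos, z, z=z)
        mirror = RadialProfile(pos, z[::-1], z=z[::-1])
        lp, rp, ave = peak_zscores(prof, mid_segment(), 10.0)
        lp2, rp2, ave2 = peak_zscores(mirror, mid_segment(), 10.0)
        assert (lp, rp) == (rp2, lp2)
        assert ave == pytest.approx(ave2)

    def test_lumen_excluded_from_search(self):
        pos = np.linspace(-20, 20, 41)
        z = np.zeros(41)
        z[pos == 0.0] = 100.0  # giant lumen value must not win
        z[pos == 5.0] = 1.0
        z[pos == -5.0] = 1.0
        prof = RadialProfile(pos, z, z=z)
        _, _, ave = peak_zscores(prof, mid_segment(), 10.0)
        assert ave == 1.0


class TestQuantifyMovie:
    def test_null_movies_stay_below_two_z(self):
        """With no sheath signal, ave_peak_z behaves like a noise maximum:
        |ave_peak_z| < 2 in at least 90% of seeds."""
        below = 0
        for seed in range(20):
            movie, _ = generate_movie(tiny_spec(seed=seed, sheath_amplitude=0.0))
            m, _ = quantify_movie(movie)
            below += abs(m.ave_peak_z) < 2.0
        assert below >= 18

    def test_vessel_display_max_exactly_five(self):
        movie, _ = generate_movie(tiny_spec(seed=1))
        _, prof = quantify_movie(movie)
        assert np.nanmax(prof.vessel_display) == 5.0

    def test_metrics_provenance_fields(self):
        movie, _ = generate_movie(tiny_spec(seed=2))
        m, prof = quantify_movie(movie)
        assert m.n_baseline_frames == 9 and m.n_peak_frames == 9
        assert m.ave_peak_z == (m.left_peak_z + m.right_peak_z) / 2
        assert 0 < m.mask_fraction < 0.5
        assert m.sigma_used == prof.sigma_used > 0

    def test_roi_halfwidth_default_rule(self):
        """Default ROI half-width is max(3 * diameter, 10 um)."""
        movie, _ = generate_movie(tiny_spec(seed=3))
        m, _ = quantify_movie(movie)
        assert m.roi_halfwidth_um == pytest.approx(
            max(3 * 2 * m.radius_um, 10.0)
        )

    def test_out_of_focus_rejected(self):
        movie, _ = generate_movie(tiny_spec(seed=4))
        from perivasc.geometry import segment_vessel

        seg = segment_vessel(movie.vessel, movie.pixel_size_um)
        seg.in_focus = False
        with pytest.raises(QuantError, match="focus"):
            quantify_movie(movie, segment=seg)
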