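"""Tracking, axis profiles, kymographs, edge bands, polar maps and the
peak-oscillation statistics."""

import numpy as np
import pytest
from conftest import make_series

from fretpol.polarity import (axis_profile, axis_profile_series, build_track,
                              combine_polar_maps, edge_band_values,
                              front_back_summary, kymograph, peak_trace,
                              polar_map)


class TestBuildTrack:
    def test_eastward_translation_gives_unit_east_heading(self):
        masks = []
        for i in range(10):
            m = np.zeros((40, 80), bool)
            m[14:26, 10 + 2 * i:30 + 2 * i] = True
            masks.append(m)
        track = build_track(masks, frame_interval=1.0, pixel_size=1.0)
        for tf in track.frames[2:-2]:
            assert np.allclose(tf.heading, [1.0, 0.0], atol=1e-6)

    def test_stationary_cell_falls_back_to_long_axis(self):
        m = np.zeros((40, 80), bool)
        m[14:26, 20:60] = True                     # long axis along x
        track = build_track([m] * 5, frame_interval=1.0, pixel_size=1.0)
        for tf in track.frames:
            assert abs(abs(tf.heading[0]) - 1.0) < 1e-6

    def test_track_splits_on_long_gap_with_warning(self):
        m = np.zeros((30, 30), bool)
        m[10:20, 10:20] = True
        masks = [m, m, m, None, None, None, m, m, m, m, m]
        with pytest.warns(UserWarning, match="split"):
            track = build_track(masks, 1.0, 1.0)
        assert [f.index for f in track.frames] == [6, 7, 8, 9, 10]

    def test_too_few_frames_rejected(self):
        m = np.zeros((10, 10), bool)
        m[3:7, 3:7] = True
        with pytest.raises(ValueError):
            build_track([m], 1.0, 1.0)

    def test_anchors_near_ground_truth(self, osc16):
        """Leading-edge/uropod anchors within 1 px of the simulator's true
        extremal points in at least 90% of frames."""
        movie, gt, bundle = osc16
        track = bundle["track"]
        ps = movie.pixel_size
        hits = 0
        for tf in track.frames:
            d_front = np.linalg.norm(tf.front_um - gt.front_um[tf.index]) / ps
            d_rear = np.linalg.norm(tf.rear_um - gt.rear_um[tf.index]) / ps
            hits += (d_front <= 1.0) and (d_rear <= 1.0)
        assert hits / track.n_frames >= 0.90


class TestAxisProfile:
    def test_uniform_ratio_uniform_bins(self):
        from fretpol.io import RatioMovie
        mask = np.zeros((60, 90), bool)
        mask[20:40, 10:80] = True
        ratio = np.where(mask, 1.2, np.nan)[None]
        rm = RatioMovie(ratio=ratio, valid=~np.isnan(ratio),
                        pixel_size=1.0, frame_interval=1.0)
        track = build_track([mask] * 2, 1.0, 1.0)
        prof = axis_profile(rm, track.frames[0])
        assert np.allclose(prof.bin_means, 1.2)

    def test_linear_gradient_recovered(self, gradient_scene):
        """Front 2.0 -> back 1.0 gradient: strictly decreasing bins with the
        end bins within 5% of the analytic end values."""
        _, gt, bundle = gradient_scene
        prof = bundle["profiles"].profiles[5]
        assert prof is not None
        assert np.all(np.diff(prof.bin_means) < 0)
        assert abs(prof.bin_means[0] - 2.0) < 0.1
        assert abs(prof.bin_means[-1] - 1.0) < 0.05

    def test_piecewise_constant_segments_bin_exactly(self):
        """Four equal axial segments at ratios 1, 2, 3, 4 reduce to 4 bins
        {1, 2, 3, 4} (segment layout chosen so bins align with segments)."""
        from fretpol.io import RatioMovie
        mask = np.zeros((60, 100), bool)
        mask[20:40, 10:90] = True
        x = np.arange(100)
        levels = np.select([x < 30, x < 50, x < 70], [4.0, 3.0, 2.0], 1.0)
        ratio = np.where(mask, levels[None, :], np.nan)[None]
        rm = RatioMovie(ratio=ratio, valid=~np.isnan(ratio),
                        pixel_size=1.0, frame_interval=1.0)
        track = build_track([mask] * 2, 1.0, 1.0)
        prof = axis_profile(rm, track.frames[0], n_bins=4)
        assert np.allclose(np.sort(prof.bin_means), [1.0, 2.0, 3.0, 4.0],
                           atol=0.15)

    def test_bin_mean_conservation(self, gradient_scene):
        _, _, bundle = gradient_scene
        prof = bundle["profiles"].profiles[0]
        assert np.isfinite(prof.values).all()
        assert abs(np.mean(prof.bin_means) - np.mean(prof.values)) < 1e-6

    def test_short_axis_rejected(self):
        from fretpol.io import RatioMovie
        mask = np.zeros((30, 30), bool)
        mask[12:18, 10:20] = True
        ratio = np.where(mask, 1.0, np.nan)[None]
        rm = RatioMovie(ratio=ratio, valid=~np.isnan(ratio),
                        pixel_size=1.0, frame_interval=1.0)
        track = build_track([mask] * 2, 1.0, 1.0)
        with pytest.raises(ValueError, match="axis"):
            axis_profile(rm, track.frames[0], n_bins=20)


class TestKymograph:
    def test_rows_equal_binned_profiles_bitwise(self, osc16):
        _, _, bundle = osc16
        series = bundle["profiles"]
        kymo = kymograph(series)
        for t, p in enumerate(series.profiles):
            if p is not None:
                assert np.array_equal(kymo[t], p.bin_means)

    def test_oscillating_ridge_alternates_at_true_period(self, osc16):
        _, gt, bundle = osc16
        kymo = kymograph(bundle["profiles"])
        ridge = np.nanargmax(kymo, axis=1)
        # pole frames every 8 s: front pole at t=0 mod 16, rear at t=8 mod 16
        for t in range(0, 120, 16):
            assert ridge[t] <= 2
        for t in range(8, 120, 16):
            assert ridge[t] >= 17

    def test_single_frame_rejected(self, osc16):
        _, _, bundle = osc16
        series = bundle["profiles"]
        from fretpol.polarity import AxisProfileSeries
        short = AxisProfileSeries(profiles=series.profiles[:1],
                                  times=series.times[:1],
                                  frame_interval=1.0, n_bins=20)
        with pytest.raises(ValueError):
            kymograph(short)


class TestEdgeBand:
    def test_uniform_ratio_flat_profile(self, gradient_scene):
        movie, gt, bundle = gradient_scene
        # build a uniform ratio movie on the measured masks
        from fretpol.io import RatioMovie
        uniform = np.where(gt.mask, 1.4, np.nan)
        rm = RatioMovie(ratio=uniform, valid=~np.isnan(uniform),
                        pixel_size=movie.pixel_size, frame_interval=1.0)
        prof = edge_band_values(rm, bundle["track"].frames[0])
        finite = prof[np.isfinite(prof)]
        assert finite.size > 90
        assert np.allclose(finite, 1.4)

    def test_peripheral_band_scene_reads_band_value(self):
        """Ratio 2 within the true peripheral band, 1 inside: the 0.4 um
        edge-band profile reads 2.0 everywhere it is defined."""
        from fretpol.io import RatioMovie
        from fretpol.synthetic import (AcquisitionConfig, ActivityField,
                                       CellModel, stationary_trajectory)
        from fretpol.synthetic import render_movie
        from fretpol.ratiometric import compute_ratio
        acq = AcquisitionConfig(frame_count=2, noise=False)
        c, h = stationary_trajectory((17.28, 17.28), (1.0, 0.0), 2)
        cell = CellModel(centroids_um=c, headings=h)
        field = ActivityField(baseline_ratio=1.0, edge_enrichment=2.0,
                              edge_band_um=0.8)
        movie, gt = render_movie(cell, field, acq)
        rm = compute_ratio(movie)
        track = build_track(list(gt.mask), 1.0, acq.pixel_size)
        prof = edge_band_values(rm, track.frames[0], band_width_um=0.4)
        finite = prof[np.isfinite(prof)]
        assert np.allclose(finite, 2.0)

    def test_pixels_beyond_band_excluded(self):
        """A bright pixel 1 um inside the contour contributes nothing to a
        0.4 um band."""
        from fretpol.io import RatioMovie
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        ratio = np.where(mask, 1.0, np.nan)
        ratio[20, 20] = 100.0               # ~15 px from the edge at 1 um/px
        rm = RatioMovie(ratio=ratio[None], valid=~np.isnan(ratio)[None],
                        pixel_size=1.0, frame_interval=1.0)
        track = build_track([mask] * 2, 1.0, 1.0)
        prof = edge_band_values(rm, track.frames[0], band_width_um=1.0)
        assert np.nanmax(prof) <= 1.0 + 1e-9

    def test_subpixel_band_widened_with_warning(self):
        from fretpol.io import RatioMovie
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        ratio = np.where(mask, 1.0, np.nan)
        rm = RatioMovie(ratio=ratio[None], valid=~np.isnan(ratio)[None],
                        pixel_size=1.0, frame_interval=1.0)
        track = build_track([mask] * 2, 1.0, 1.0)
        with pytest.warns(UserWarning, match="widened"):
            prof = edge_band_values(rm, track.frames[0], band_width_um=0.3)
        assert np.isfinite(prof).any()


class TestPolarMap:
    def test_needle_already_west_no_rotation(self):
        prof = np.random.default_rng(1).uniform(1, 2, (5, 360))
        pm = polar_map(prof, np.pi)
        assert np.array_equal(pm.matrix, prof)

    def test_rotation_matches_manual_permutation(self):
        """Needle due north: the map rotates by +90 deg, i.e. a hotspot at
        0 deg lands at 90 deg (manual bin permutation oracle)."""
        prof = np.full((1, 360), 1.0)
        prof[0, 0] = 5.0                    # hotspot at angle 0
        pm = polar_map(prof, np.pi / 2)     # needle due north
        assert np.array_equal(pm.matrix, np.roll(prof, 90, axis=1))
        assert pm.matrix[0, 90] == 5.0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 2, (4, 360))
        ref = polar_map(base, 0.0)
        for k in (30, 115, 270):
            rotated = np.roll(base, k, axis=1)
            pm = polar_map(rotated, k * 2 * np.pi / 360)
            assert np.allclose(pm.matrix, ref.matrix)

    def test_missing_needle_warns_and_leaves_unrotated(self):
        prof = np.ones((3, 360))
        with pytest.warns(UserWarning, match="unrotated"):
            pm = polar_map(prof, None)
        assert np.array_equal(pm.matrix, prof)

    def test_combining_identical_cells_is_idempotent(self):
        prof = np.random.default_rng(3).uniform(1, 2, (4, 360))
        a = polar_map(prof, np.pi)
        mean = combine_polar_maps([a, a])
        assert np.allclose(mean.matrix, a.matrix)


class TestPeakTrace:
    def test_fixed_front_peak_dwells_without_switching(self):
        series = make_series([0.0] * 120)
        trace = peak_trace(series)
        assert trace.dwell_front_s == 120.0
        assert trace.n_switches == 0

    def test_square_wave_16s_cycle_gives_8s_waves(self):
        """Peak alternating poles every 8 s: 14 switches in 120 s, mean wave
        duration 8 s (120/8 - 1 transitions counted by construction)."""
        fractions = [0.0 if (t // 8) % 2 == 0 else 1.0 for t in range(120)]
        trace = peak_trace(make_series(fractions))
        assert trace.n_switches == 14
        assert np.isclose(trace.mean_wave_s, 8.0)

    def test_uniform_profile_tie_breaks_to_leading_edge(self):
        from fretpol.polarity import AxisProfile, AxisProfileSeries
        d = (np.arange(100) + 0.5) * 15.6 / 100
        profiles = [AxisProfile(distances_um=d, values=np.ones(100),
                                bin_means=np.ones(20), axis_length_um=15.6,
                                frame_index=i, time_s=float(i))
                    for i in range(3)]
        series = AxisProfileSeries(profiles=profiles, times=np.arange(3.0),
                                   frame_interval=1.0, n_bins=20)
        trace = peak_trace(series)
        assert trace.zones[0] == "front"
        assert np.all(trace.peak_um_from_front < 0.2)

    def test_no_switch_inferred_across_gap(self):
        fractions = [0.0, 0.0, 0.5] + [None] * 3 + [1.0, 1.0]
        trace = peak_trace(make_series(fractions))
        assert trace.n_switches == 0

    def test_dwell_times_add_up_exactly(self, osc16):
        _, _, bundle = osc16
        trace = bundle["peak_trace"]
        total = len(trace.times) * trace.frame_interval
        assert (trace.dwell_front_s + trace.dwell_rear_s
                + trace.dwell_interior_s) == total


class TestFrontBackSummary:
    def test_constant_profile_aucs_equal_duration(self):
        series = make_series([0.5] * 101)      # peak mid-cell, away from ends
        series_flat = make_series([0.5] * 101)
        for p in series_flat.profiles:
            p.values[:] = 1.0
            p.bin_means[:] = 1.0
        fb = front_back_summary(series_flat)
        assert np.isclose(fb.leading_edge_auc, 100.0)
        assert np.isclose(fb.uropod_auc, 100.0)
        assert np.isclose(fb.whole_cell_auc, 100.0)

    def test_front_high_gradient_orders_aucs(self, gradient_scene):
        _, _, bundle = gradient_scene
        fb = bundle["front_back"]
        assert fb.leading_edge_auc > fb.uropod_auc

    def test_axis_reversal_swaps_outputs_exactly(self):
        series = make_series([0.2] * 30)
        reversed_series = make_series([0.8] * 30)
        for p, q in zip(series.profiles, reversed_series.profiles):
            q.values[:] = p.values[::-1]
            q.bin_means[:] = p.bin_means[::-1]
        a = front_back_summary(series)
        b = front_back_summary(reversed_series)
        assert np.isclose(a.leading_edge_auc, b.uropod_auc)
        assert np.isclose(a.uropod_auc, b.leading_edge_auc)
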