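"""Gaussian smoothing, areal extent, peak amplitude, and phase detection."""

import dataclasses

import numpy as np
import pytest

from wfrquant.protocols import NoiseSpec, SPARSE, ScenarioSpec, default_truth
from wfrquant.ratio import aggregate_trials, session_fc, sum_frames
from wfrquant.spatial import (
    DEFAULT_FWHM_PX,
    DEFAULT_THRESHOLDS,
    DEFAULT_WINDOWS,
    areal_extent,
    detect_phases,
    fwhm_to_sigma,
    measure_phase,
    peak_amplitude,
    select_phase_frame,
    smooth,
)
from wfrquant.synthetic import generate_session

PIXEL_AREA = (7.0 / 64) ** 2


def gaussian_blob(shape=(64, 64), center=(30, 34), sigma=10.0, amp=-3e-4):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return amp * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2))


class TestSmooth:
    def test_constant_frame_unchanged(self):
        out = smooth(np.full((32, 32), 3.3e-4))
        np.testing.assert_allclose(out, 3.3e-4, rtol=1e-12)

    def test_impulse_matches_explicit_kernel_oracle(self):
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        out = smooth(frame)
        # independent oracle: separable discrete Gaussian, sigma = FWHM/2.3548
        sigma = DEFAULT_FWHM_PX / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        assert sigma == pytest.approx(2.123, abs=1e-3)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        assert out[16, 16] == pytest.approx(w[radius] ** 2, rel=1e-9)

    def test_default_half_width_is_five_pixels(self):
        assert DEFAULT_FWHM_PX == 5.0

    def test_frame_smaller_than_kernel_support_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros((8, 8)))

    def test_masked_pixels_excluded_by_normalized_convolution(self):
        frame = np.full((32, 32), 2e-4)
        frame[10, 10] = 1.0  # corrupt value under the mask
        valid = np.ones((32, 32), dtype=bool)
        valid[10, 10] = False
        out = smooth(frame, valid=valid)
        np.testing.assert_allclose(out, 2e-4, rtol=1e-9)

    def test_never_increases_global_extremum(self):
        rng = np.random.default_rng(0)
        frame = rng.standard_normal((40, 40)) * 1e-4
        out = smooth(frame)
        assert np.abs(out).max() <= np.abs(frame).max() + 1e-15


class TestArealExtent:
    def test_all_zero_frame(self):
        ext = areal_extent(np.zeros((64, 64)), 1.75e-4, -1, pixel_area_mm2=PIXEL_AREA)
        assert ext.pixel_count == 0 and ext.area_mm2 == 0.0

    def test_default_thresholds(self):
        assert DEFAULT_THRESHOLDS["initial_dip"] == pytest.approx(1.75e-4)
        assert DEFAULT_THRESHOLDS["overshoot"] == pytest.approx(2.5e-4)

    def test_blob_count_equals_brute_force_scan(self):
        frame = gaussian_blob()
        thr = 1.75e-4
        ext = areal_extent(frame, thr, -1, pixel_area_mm2=PIXEL_AREA)
        brute = int((frame <= -thr).sum())  # single blob: one component
        assert ext.pixel_count == brute
        assert ext.area_mm2 == pytest.approx(brute * PIXEL_AREA)

    def test_ignores_disjoint_noise_island(self):
        frame = gaussian_blob()
        frame[2, 2] = -5e-4  # isolated suprathreshold speck far from the blob
        ext = areal_extent(frame, 1.75e-4, -1, pixel_area_mm2=PIXEL_AREA)
        # the extremal pixel is now the speck; extent is its component
        assert ext.pixel_count == 1
        blob_only = areal_extent(gaussian_blob(), 1.75e-4, -1, pixel_area_mm2=PIXEL_AREA)
        assert blob_only.pixel_count > 100

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(3)
        frame = smooth(rng.standard_normal((48, 48)) * 2e-4)
        counts = [
            areal_extent(frame, thr, -1).pixel_count
            for thr in np.linspace(0.5e-4, 4e-4, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bad_roi_rejected(self):
        with pytest.raises(ValueError):
            areal_extent(np.zeros((8, 8)), 1e-4, -1, roi=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            areal_extent(np.zeros((8, 8)), 0.0, -1)


class TestPeakAmplitude:
    def test_unique_extremum(self):
        frame = np.zeros((32, 32))
        frame[10, 12] = -3e-4
        val, px = peak_amplitude(frame, -1)
        assert val == pytest.approx(-3e-4) and px == (10, 12)

    def test_constant_frame_tie_breaks_row_major(self):
        val, px = peak_amplitude(np.full((16, 16), 2e-4), +1)
        assert val == pytest.approx(2e-4) and px == (0, 0)

    def test_noise_free_peak_near_ground_truth_center(self, noisefree_sparse):
        agg, rec = noisefree_sparse
        m = measure_phase(agg, "initial_dip", pixel_area_mm2=PIXEL_AREA)
        center = tuple(rec["center_px"])
        assert abs(m.peak_px[0] - center[0]) <= 1
        assert abs(m.peak_px[1] - center[1]) <= 1

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            peak_amplitude(np.zeros((8, 8)), -1, roi=np.zeros((8, 8), bool))


class TestFrameSelection:
    def test_noise_free_dip_selects_peak_frame(self, noisefree_sparse, truth64):
        agg, _ = noisefree_sparse
        idx, ext = select_phase_frame(
            agg, DEFAULT_WINDOWS["initial_dip"], 1.75e-4, pixel_area_mm2=PIXEL_AREA
        )
        # kernel peaks at 1.75 s -> the 500 ms frame with midpoint 1.75 s
        k = int(np.argmin(np.abs(agg.time_s - truth64.timing["initial_dip"].peak_s)))
        assert idx == k
        assert ext.pixel_count > 0

    def test_all_zero_series_returns_first_window_frame_with_flag(self, noisefree_sparse):
        agg, _ = noisefree_sparse
        zero = dataclasses.replace(agg)
        zero.fc = np.zeros_like(agg.fc)
        idx, ext = select_phase_frame(
            zero, DEFAULT_WINDOWS["initial_dip"], 1.75e-4, pixel_area_mm2=PIXEL_AREA
        )
        in_window = np.flatnonzero((zero.time_s > 0.0) & (zero.time_s <= 3.5))
        assert idx == in_window[0]
        assert ext.pixel_count == 0


class TestDetectPhases:
    def test_sparse_session_has_three_phases_in_order(self, noisefree_sparse):
        agg, _ = noisefree_sparse
        det = detect_phases(agg, pixel_area_mm2=PIXEL_AREA)
        assert [d.phase for d in det] == ["initial_dip", "overshoot", "undershoot"]
        times = [d.selected_time_s for d in det]
        assert times == sorted(times)

    def test_condensed_session_single_growing_dip(self, noisefree_condensed):
        agg, _ = noisefree_condensed
        det = detect_phases(agg, pixel_area_mm2=PIXEL_AREA)
        assert [d.phase for d in det] == ["initial_dip"]

    def test_eliminated_wfr_yields_zero_phases(self):
        truth = default_truth((64, 64))
        sc = ScenarioSpec(4, "24h")  # default noise, response scale 0
        stack, _ = generate_session(
            SPARSE, sc, truth, n_trials=8, frame_size=(64, 64), seed=2
        )
        agg = aggregate_trials(session_fc(sum_frames(stack, 5)))
        assert detect_phases(agg, pixel_area_mm2=PIXEL_AREA) == []

    def test_overshoot_window_on_dip_only_series_flags_zero_extent(
        self, noisefree_condensed
    ):
        agg, _ = noisefree_condensed
        m = measure_phase(agg, "overshoot", pixel_area_mm2=PIXEL_AREA)
        assert not m.detected and m.pixel_count == 0


class TestRecoveryProperties:
    def test_extent_ranks_with_footprint_and_amplitude(self, silent_scenario):
        from scipy.stats import spearmanr

        sigmas = [6.0, 9.0, 12.0]
        amps = [2.5e-4, 3.5e-4]
        counts, keys = [], []
        for s in sigmas:
            for a in amps:
                truth = dataclasses.replace(
                    default_truth((64, 64)), footprint_sigma_px=s, amp_dip=a
                )
                frame = gaussian_blob(center=truth.center_px, sigma=s, amp=-a)
                ext = areal_extent(smooth(frame), 1.75e-4, -1, pixel_area_mm2=PIXEL_AREA)
                counts.append(ext.pixel_count)
        # extent grows with sigma at fixed amp and with amp at fixed sigma
        by_amp = np.array(counts).reshape(len(sigmas), len(amps))
        for col in by_amp.T:
            assert spearmanr(sigmas, col).statistic == pytest.approx(1.0)
        for row in by_amp:
            assert row[0] < row[1]

    def test_peak_amplitude_within_3_se_over_20_seeds(self):
        truth = default_truth((64, 64))
        noise = NoiseSpec(pixel_sd=1e-4, drift_amp=0, physio_amp=0, vessel_streaks=0)
        sc = ScenarioSpec(1, "baseline", noise=noise)
        n_trials = 8
        se = noise.pixel_sd / np.sqrt(5 * n_trials)
        # expected depth at the ground-truth peak frame (kernel discretized)
        from test_synthetic import kernel_at_500ms_midpoints

        oracle = kernel_at_500ms_midpoints(SPARSE, truth)
        k = int(np.argmin(oracle))
        r, c = truth.center_px
        ok = 0
        for seed in range(20):
            stack, _ = generate_session(
                SPARSE, sc, truth, n_trials=n_trials, frame_size=(64, 64), seed=seed
            )
            agg = aggregate_trials(session_fc(sum_frames(stack, 5)))
            ok += abs(agg.fc[k, r, c] - oracle[k]) < 3 * se
        assert ok >= 19
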