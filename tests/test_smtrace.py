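"""Detectability-metric tests: spot detection, SBR, traces, steps, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phonescope import simcam, smtrace
from phonescope.smtrace import (compute_sbr, compute_snr, detect_bleach_step,
                                detect_spots, extract_trace)

from conftest import integrated_gaussian_roi, make_site_layout


def spot_image(shape=(40, 40), center=(20.0, 20.0), photons=4000.0,
               sigma=1.3, background=10.0):
    # integrated_gaussian_roi uses edge coords; pixel-center (r, c) = edge + 0.5
    return integrated_gaussian_roi(shape, center[1] + 0.5, center[0] + 0.5,
                                   photons, sigma, background)


class TestDetectSpots:
    def test_single_spot_found_within_one_pixel(self):
        img = spot_image()
        centers = detect_spots(img, psf_sigma_px=1.3)
        assert len(centers) == 1
        assert np.hypot(centers[0][0] - 20.0, centers[0][1] - 20.0) < 1.0

    def test_blank_image_gives_no_detections(self):
        assert detect_spots(np.zeros((30, 30))) == []
        assert detect_spots(np.zeros((0, 0))) == []

    def test_recall_and_precision_on_simulated_field(self):
        # 20 well-separated spots at SBR ~ 1 on a noisy background
        rng = np.random.default_rng(12)
        img = rng.normal(100.0, 8.0, size=(160, 160))
        truth = []
        for i in range(20):
            r, c = 10 + 30 * (i // 5), 10 + 30 * (i % 5) + 4 * (i // 5)
            img += spot_image((160, 160), (r, c), photons=3600.0, sigma=1.3,
                              background=0.0)
            truth.append((r, c))
        centers = detect_spots(img - np.median(img), psf_sigma_px=1.3,
                               threshold_k=6.0)
        matched = 0
        for r, c in truth:
            if any(np.hypot(r - cr, c - cc) <= 2.0 for cr, cc in centers):
                matched += 1
        recall = matched / len(truth)
        precision = sum(
            any(np.hypot(r - cr, c - cc) <= 2.0 for r, c in truth)
            for cr, cc in centers) / max(len(centers), 1)
        assert recall >= 0.9
        assert precision >= 0.9


class TestComputeSbr:
    def test_flat_image_gives_zero(self):
        rec = compute_sbr(np.full((20, 20), 40.0), (10.0, 10.0))
        assert rec.sbr == pytest.approx(0.0)

    def test_constructed_inner_and_ring_means(self):
        img = np.full((20, 20), 100.0)
        rec0 = compute_sbr(img, (10.0, 10.0))
        r0, c0 = 8, 8  # anchor for center 10.0 -> rounds to block [8, 14)
        img[r0:r0 + 6, c0:c0 + 6] = 200.0
        rec = compute_sbr(img, (10.0, 10.0))
        assert rec0.sbr == pytest.approx(0.0)
        assert rec.sbr == pytest.approx(1.0)
        assert rec.signal == pytest.approx(200.0)
        assert rec.background == pytest.approx(100.0)

    def test_matches_bruteforce_pixel_means_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            img = rng.uniform(1.0, 500.0, size=(24, 24))
            center = (rng.uniform(8, 15), rng.uniform(8, 15))
            rec = compute_sbr(img, center)
            # independent brute-force oracle over explicit pixel lists
            r_half = round(center[0] * 2) / 2
            c_half = round(center[1] * 2) / 2
            r0, c0 = int(round(r_half - 2.5)), int(round(c_half - 2.5))
            inner = [img[r, c] for r in range(r0, r0 + 6)
                     for c in range(c0, c0 + 6)]
            ring = [img[r, c] for r in range(r0 - 1, r0 + 7)
                    for c in range(c0 - 1, c0 + 7)
                    if not (r0 <= r < r0 + 6 and c0 <= c < c0 + 6)]
            assert len(inner) == 36 and len(ring) == 28
            s, b = np.mean(inner), np.mean(ring)
            assert rec.sbr == pytest.approx((s - b) / b, rel=1e-12)

    def test_overlapping_outer_rois_excluded(self):
        img = np.full((30, 30), 50.0)
        rec = compute_sbr(img, (15.0, 15.0), other_centers=[(15.0, 21.0)])
        assert rec.excluded and "overlap" in rec.reason
        far = compute_sbr(img, (15.0, 15.0), other_centers=[(15.0, 24.0)])
        assert not far.excluded

    def test_roi_at_border_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            compute_sbr(np.zeros((20, 20)), (2.0, 10.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(gain=st.floats(0.01, 100.0))
    def test_scale_invariance_under_gain(self, gain):
        img = spot_image(background=20.0)
        a = compute_sbr(img, (20.0, 20.0)).sbr
        b = compute_sbr(img * gain, (20.0, 20.0)).sbr
        assert b == pytest.approx(a, rel=1e-9)


class TestExtractTrace:
    def test_constant_stack_gives_constant_trace(self):
        frames = np.full((7, 20, 20), 5.0)
        tr = extract_trace(frames, (10.0, 10.0))
        assert np.allclose(tr.values, 5.0)
        assert len(tr.values) == 7

    def test_single_bright_pixel_divided_by_roi_pixel_count(self):
        frames = np.zeros((3, 21, 21))
        frames[:, 10, 10] = 290.0
        tr = extract_trace(frames, (10.0, 10.0))
        # brute-force count of pixels whose centers are within 3 px
        count = sum(1 for r in range(21) for c in range(21)
                    if (r - 10.0) ** 2 + (c - 10.0) ** 2 <= 9.0)
        assert np.allclose(tr.values, 290.0 / count)

    def test_clipped_roi_rejected(self):
        with pytest.raises(ValueError, match="border"):
            extract_trace(np.zeros((2, 10, 10)), (1.0, 5.0))

    def test_blinking_emitter_trace_follows_schedule(self, mono_camera,
                                                     smartphone_optics):
        layout = make_site_layout([(4300.0, 4300.0, simcam.SITE_DOCKING, 0.0)],
                                  field=(8600.0, 8600.0))
        kin = simcam.KineticsModel(mean_dwell=2.0, event_rate=0.5,
                                   photons_per_second_on=4000.0)
        sched = simcam.simulate_schedule(layout, kin, 30.0, 0.25, seed=4)
        sim = simcam.render_video(sched, layout, smartphone_optics,
                                  mono_camera, noise=False, seed=0)
        tr = extract_trace(sim.stack.frames - mono_camera.baseline,
                           (10.0, 10.0))
        on = sched.frame_photons[:, 0] > 500.0
        off = sched.frame_photons[:, 0] == 0.0
        assert on.any() and off.any()
        assert tr.values[on].mean() > 10 * max(tr.values[off].mean(), 1e-9)


class TestDetectBleachStep:
    def test_noiseless_step_localized_exactly(self):
        trace = np.concatenate([np.full(50, 10.0), np.zeros(50)])
        step = detect_bleach_step(trace)
        assert step == (50, 10.0, 0.0)

    def test_constant_trace_gives_none(self):
        assert detect_bleach_step(np.full(60, 3.0)) is None

    def test_rising_step_not_accepted(self):
        trace = np.concatenate([np.zeros(30), np.full(30, 8.0)])
        assert detect_bleach_step(trace) is None

    def test_matches_exhaustive_sse_oracle(self):
        rng = np.random.default_rng(8)
        trace = np.concatenate([rng.normal(100, 5, 40), rng.normal(20, 5, 60)])
        step = detect_bleach_step(trace)
        # independent exhaustive SSE oracle
        best_s, best_sse = None, np.inf
        n = len(trace)
        for s in range(2, n - 1):
            sse = ((trace[:s] - trace[:s].mean()) ** 2).sum() \
                + ((trace[s:] - trace[s:].mean()) ** 2).sum()
            if sse < best_sse - 1e-12:
                best_sse, best_s = sse, s
        assert step is not None and step[0] == best_s

    def test_noisy_step_frame_recovered_in_95pct_of_runs(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            trace = np.concatenate([rng.normal(100.0, 8.0, 50),
                                    rng.normal(20.0, 8.0, 50)])
            step = detect_bleach_step(trace)
            if step is not None and abs(step[0] - 50) <= 2:
                hits += 1
        assert hits / 200 >= 0.95

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_bleach_step(np.zeros(9))


class TestComputeSnr:
    def test_hand_computed_sample_statistics(self):
        # 20 pre-bleach frames alternating 90/110: mean 100, sample SD
        # 10*sqrt(20/19) = 10.26; post-bleach constant 50 -> SNR = 4.87
        trace = np.concatenate([np.tile([90.0, 110.0], 10), np.full(20, 50.0)])
        snr = compute_snr(trace, (20, 100.0, 50.0))
        sd = np.std(trace[:20], ddof=1)
        assert sd == pytest.approx(10.2598, abs=1e-3)
        assert snr == pytest.approx(50.0 / sd, rel=1e-12)
        assert snr == pytest.approx(4.87, abs=0.01)

    def test_zero_prebleach_variance_flagged(self):
        trace = np.concatenate([np.full(20, 100.0), np.full(20, 10.0)])
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(compute_snr(trace, (20,)))

    def test_missing_step_is_an_error(self):
        with pytest.raises(ValueError):
            compute_snr(np.zeros(40), None)

    def test_poisson_trace_follows_sqrt_law(self):
        # S = 400, B = 100 -> sigma_S = 20 -> SNR = 15
        snrs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = np.concatenate([rng.poisson(400.0, 60),
                                    rng.poisson(100.0, 60)]).astype(float)
            snrs.append(compute_snr(trace, (60,)))
        assert np.mean(snrs) == pytest.approx(300.0 / 20.0, rel=0.15)

    def test_snr_numerator_scale_invariance(self):
        rng = np.random.default_rng(9)
        trace = np.concatenate([rng.normal(200, 12, 40),
                                rng.normal(40, 12, 40)])
        a = compute_snr(trace, (40,))
        b = compute_snr(trace * 7.5, (40,))
        assert b == pytest.approx(a, rel=1e-9)


class TestChannelOrdering:
    def test_green_channel_sbr_exceeds_red_on_green_dye(self,
                                                        smartphone_camera,
                                                        smartphone_optics):
        """Direction of the channel comparison: median SBR(G) > SBR(R)."""
        from phonescope import rawproc
        layout = make_site_layout(
            [(8000.0 + 6000.0 * i, 8000.0 + 6000.0 * j,
              simcam.SITE_FIXED_DYE, 0.0)
             for i in range(4) for j in range(4)],
            field=(34400.0, 34400.0))
        kin = simcam.KineticsModel(bleach_mean_time=1e6,
                                   photons_per_second_on=6000.0)
        sched = simcam.simulate_schedule(layout, kin, 2.5, 0.25, seed=0)
        sim = simcam.render_video(sched, layout, smartphone_optics,
                                  smartphone_camera, seed=1,
                                  background_photons_px_s=80.0)
        sub = rawproc.subtract_baseline(sim.stack, smartphone_camera.baseline)
        channels = rawproc.split_bayer(sub)
        img_g, _ = rawproc.sum_frames(channels["G"], 5)
        img_r, _ = rawproc.sum_frames(channels["R"], 5)
        centers = detect_spots(img_g, psf_sigma_px=0.64, threshold_k=6.0)
        assert len(centers) >= 8
        sbr_g = [compute_sbr(img_g, c).sbr for c in centers]
        sbr_r = [compute_sbr(img_r, c).sbr for c in centers]
        assert np.median(sbr_g) > np.median(sbr_r)
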