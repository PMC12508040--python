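"""Metrology tests: rendering, clustering, distance fits, NeNa, dwell."""

import numpy as np
import pandas as pd
import pytest

from phonescope import simcam
from phonescope.locfit import LocalizationTable
from phonescope.metrology import (DoubleGaussianFit, align_and_average,
                                  align_cluster, axis_profile_fit,
                                  cluster_structures, estimate_binding_time,
                                  fit_psf_fwhm, nena_precision,
                                  render_histogram, resolution_gain)

from conftest import integrated_gaussian_roi, make_site_layout


def table_from_xy(xy, frames=None, frame_time=0.25, n_frames=None):
    xy = np.asarray(xy, float)
    if frames is None:
        frames = np.zeros(len(xy), dtype=int)
    df = pd.DataFrame({"frame": frames, "x_nm": xy[:, 0], "y_nm": xy[:, 1],
                       "photons": 1000.0, "bg": 1.0, "sigma_nm": 500.0,
                       "precision_nm": 20.0, "converged": True,
                       "iterations": 5})
    return LocalizationTable(df=df, pixel_size_nm=860.0, frame_time=frame_time,
                             n_frames=n_frames or int(np.max(frames)) + 1)


class TestRenderHistogram:
    def test_single_localization_single_count(self):
        img = render_histogram(np.array([[10.0, 20.0]]), 25.0)
        assert img.total == 1.0
        assert img.counts.shape == (1, 1)

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1000, size=(500, 2))
        img = render_histogram(xy, 25.0)
        assert img.total == 500.0

    def test_uniform_cloud_uniformity_not_rejected(self):
        from scipy.stats import chisquare
        rng = np.random.default_rng(1)
        xy = rng.uniform(0.0, 400.0, size=(40000, 2))
        img = render_histogram(xy, 25.0)
        interior = img.counts[1:-1, 1:-1].ravel()  # skip edge bins
        stat, p = chisquare(interior)
        assert p > 0.01

    def test_empty_table_empty_image(self):
        img = render_histogram(np.zeros((0, 2)), 10.0)
        assert img.counts.size == 0


class TestClusterStructures:
    def test_two_structures_5um_apart(self):
        rng = np.random.default_rng(2)
        a = rng.normal((1000.0, 1000.0), 30.0, size=(100, 2))
        b = rng.normal((6000.0, 1000.0), 30.0, size=(80, 2))
        clusters = cluster_structures(np.vstack([a, b]), eps_nm=300.0,
                                      min_pts=20)
        assert sorted(len(c) for c in clusters) == [80, 100]

    def test_empty_input_no_clusters(self):
        assert cluster_structures(np.zeros((0, 2)), eps_nm=100.0) == []

    def test_all_points_within_eps_single_cluster(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 5.0], [15.0, 15.0]])
        clusters = cluster_structures(xy, eps_nm=50.0, min_pts=2)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_min_pts_filters_noise(self):
        xy = np.vstack([np.zeros((30, 2)), [[5000.0, 5000.0]]])
        clusters = cluster_structures(xy, eps_nm=100.0, min_pts=5)
        assert len(clusters) == 1 and len(clusters[0]) == 30


class TestAlignAndAverage:
    def two_lobe_cluster(self, rng, n=400, brighter_right=True):
        frac = 0.65 if brighter_right else 0.35
        n_r = int(n * frac)
        right = rng.normal((128.0, 0.0), 25.0, size=(n_r, 2))
        left = rng.normal((-128.0, 0.0), 25.0, size=(n - n_r, 2))
        return np.vstack([left, right])

    @staticmethod
    def rotate(xy, deg):
        th = np.deg2rad(deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return xy @ rot.T

    def test_axis_aligned_cluster_average_is_own_render(self):
        rng = np.random.default_rng(3)
        xy = self.two_lobe_cluster(rng)
        img, angles, pooled = align_and_average([np.arange(len(xy))], xy, 25.0)
        assert img.total == len(xy)
        assert abs(angles[0]) < 0.2  # already on +x

    def test_rotation_invariance_of_average(self):
        rng = np.random.default_rng(4)
        xy = self.two_lobe_cluster(rng)
        _, _, pooled_a = align_and_average([np.arange(len(xy))], xy, 25.0)
        _, _, pooled_b = align_and_average([np.arange(len(xy))],
                                           self.rotate(xy, 37.0), 25.0)
        ha, _ = np.histogram(pooled_a[:, 0], bins=24, range=(-300, 300))
        hb, _ = np.histogram(pooled_b[:, 0], bins=24, range=(-300, 300))
        corr = np.corrcoef(ha, hb)[0, 1]
        assert corr >= 0.99

    def test_ten_nanorulers_random_angles_give_two_lobes(self):
        rng = np.random.default_rng(5)
        tables, idx, offset = [], [], 0
        for i in range(10):
            xy = self.two_lobe_cluster(rng, n=300)
            xy = self.rotate(xy, rng.uniform(0, 360))
            xy += rng.uniform(0, 50000, size=2)
            tables.append(xy)
            idx.append(np.arange(offset, offset + len(xy)))
            offset += len(xy)
        allxy = np.vstack(tables)
        _, _, pooled = align_and_average(idx, allxy, 25.0)
        fit = axis_profile_fit(pooled[:, 0], 25.0)
        assert fit.distance == pytest.approx(256.0, abs=15.0)

    def test_brighter_lobe_lands_at_positive_x(self):
        rng = np.random.default_rng(6)
        xy = self.two_lobe_cluster(rng, brighter_right=False)
        aligned, _, _ = align_cluster(xy)
        assert (aligned[:, 0] > 0).sum() > (aligned[:, 0] < 0).sum()


class TestAxisProfileFit:
    def test_generator_oracle_256nm_sigma84(self):
        rng = np.random.default_rng(7)
        n = 6000
        x = np.concatenate([rng.normal(-128.0, 84.0, n // 2),
                            rng.normal(128.0, 84.0, n // 2)])
        fit = axis_profile_fit(x, 25.0)
        se_mu = 84.0 / np.sqrt(n / 2)
        assert fit.distance == pytest.approx(256.0, abs=3 * np.sqrt(2) * se_mu)
        assert fit.sigma_shared == pytest.approx(84.0, abs=3 * 84.0 / np.sqrt(n))

    def test_sigma84_reports_fwhm_197(self):
        fit = DoubleGaussianFit(mu1=0.0, mu2=256.0, amp1=1.0, amp2=1.0,
                                sigma_shared=84.0, rss=0.0)
        assert fit.fwhm == pytest.approx(197.4, abs=0.01)

    def test_unimodal_input_gives_small_distance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 50.0, 4000)
        fit = axis_profile_fit(x, 10.0)
        assert fit.distance < 50.0

    def test_distance_invariant_under_table_rotation(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-128.0, 40.0, 2000),
                            rng.normal(128.0, 40.0, 2000)])
        xy = np.column_stack([x, rng.normal(0, 25.0, 4000)])
        fits = []
        for deg in (0.0, 63.0):
            rot = TestAlignAndAverage.rotate(xy, deg) + [3000.0, -700.0]
            _, _, pooled = align_and_average([np.arange(len(xy))], rot, 25.0)
            fits.append(axis_profile_fit(pooled[:, 0], 25.0).distance)
        assert abs(fits[0] - fits[1]) <= 25.0  # within one bin

    def test_fwhm_sigma_ratio_exact_for_every_fit(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x = np.concatenate([rng.normal(0, 60.0, 1500),
                                rng.normal(300.0, 60.0, 1500)])
            fit = axis_profile_fit(x, 20.0)
            assert fit.fwhm / fit.sigma_shared == pytest.approx(2.35)


class TestFitPsfFwhm:
    def test_noiseless_sigma110nm_gives_omega220(self):
        # sigma = 110 nm on a 108 nm grid
        sigma_px = 110.0 / 108.0
        img = integrated_gaussian_roi((21, 21), 10.5, 10.3, 5000.0,
                                      sigma_px, 2.0)
        fit = fit_psf_fwhm(img, pixel_size_nm=108.0)
        assert fit["omega_nm"] == pytest.approx(220.0, rel=0.01)
        assert fit["fwhm_nm"] == pytest.approx(258.5, rel=0.01)

    def test_doubling_sigma_doubles_fwhm(self):
        a = fit_psf_fwhm(integrated_gaussian_roi((31, 31), 15.5, 15.5,
                                                 5000.0, 1.5, 0.0),
                         pixel_size_nm=430.0)
        b = fit_psf_fwhm(integrated_gaussian_roi((31, 31), 15.5, 15.5,
                                                 5000.0, 3.0, 0.0),
                         pixel_size_nm=430.0)
        assert b["fwhm_nm"] == pytest.approx(2 * a["fwhm_nm"], rel=0.01)

    def test_smartphone_preset_spot_within_10pct_of_1300nm(
            self, mono_camera, smartphone_optics, single_emitter_layout):
        kin = simcam.KineticsModel(fiducial_photons_per_second=20000.0)
        sched = simcam.simulate_schedule(single_emitter_layout, kin,
                                         0.25, 0.25, seed=0)
        sim = simcam.render_video(sched, single_emitter_layout,
                                  smartphone_optics, mono_camera, seed=1)
        img = sim.stack.frames[0].astype(float) - mono_camera.baseline
        fit = fit_psf_fwhm(img, pixel_size_nm=430.0)
        assert fit["fwhm_nm"] == pytest.approx(1300.0, rel=0.10)


class TestResolutionGain:
    @pytest.mark.parametrize("psf,site,expected", [
        (1300.0, 197.0, 6.6), (270.0, 56.0, 4.8), (100.0, 100.0, 1.0)])
    def test_reported_to_two_significant_figures(self, psf, site, expected):
        assert resolution_gain(psf, site) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            resolution_gain(-1.0, 100.0)


class TestNenaPrecision:
    def repeated_point_table(self, sigma, n_frames=6000, nonspecific=0.0,
                             seed=11):
        rng = np.random.default_rng(seed)
        xy = rng.normal((2000.0, 2000.0), sigma, size=(n_frames, 2))
        frames = np.arange(n_frames)
        if nonspecific > 0:
            n_ns = int(n_frames * nonspecific)
            ns_xy = rng.uniform(1000.0, 3000.0, size=(n_ns, 2))
            ns_frames = rng.integers(0, n_frames, n_ns)
            xy = np.vstack([xy, ns_xy])
            frames = np.concatenate([frames, ns_frames])
        return table_from_xy(xy, frames=frames, n_frames=n_frames)

    def test_recovers_injected_sigma_within_10pct(self):
        t = self.repeated_point_table(50.0)
        assert nena_precision(t) == pytest.approx(50.0, rel=0.10)

    def test_zero_noise_degenerates_to_zero(self):
        t = table_from_xy(np.full((500, 2), 1000.0), frames=np.arange(500))
        assert nena_precision(t) == 0.0

    def test_nonspecific_background_inflates_estimate(self):
        pure = nena_precision(self.repeated_point_table(50.0))
        mixed = nena_precision(self.repeated_point_table(50.0,
                                                         nonspecific=0.4))
        assert mixed >= pure


class TestEstimateBindingTime:
    def fixed_duration_table(self, k_frames, n_events, frame_time):
        recs, frame = [], 0
        rng = np.random.default_rng(12)
        for i in range(n_events):
            x, y = rng.uniform(0, 50000, 2)
            for f in range(frame, frame + k_frames):
                recs.append((f, x, y))
            frame += k_frames + 3
        xy = np.array([(r[1], r[2]) for r in recs])
        frames = np.array([r[0] for r in recs])
        return table_from_xy(xy, frames=frames, frame_time=frame_time)

    def test_uniform_4frame_events_give_mean_duration(self):
        t = self.fixed_duration_table(4, 60, 0.25)
        assert estimate_binding_time(t, frame_time=0.25) == pytest.approx(1.0)

    def test_doubling_frame_time_doubles_estimate(self):
        rng = np.random.default_rng(13)
        ks = rng.geometric(0.3, 300) + 1
        recs, frame = [], 0
        for k in ks:
            x, y = rng.uniform(0, 50000, 2)
            recs += [(f, x, y) for f in range(frame, frame + k)]
            frame += k + 3
        xy = np.array([(r[1], r[2]) for r in recs])
        frames = np.array([r[0] for r in recs])
        t = table_from_xy(xy, frames=frames)
        a = estimate_binding_time(t, frame_time=0.25)
        b = estimate_binding_time(t, frame_time=0.5)
        assert b == pytest.approx(2 * a, rel=1e-9)

    def test_monte_carlo_exponential_dwell_recovered(self):
        """Schedule-level oracle: exponential(1.05 s) events observed on a
        250 ms frame grid are recovered within 3 standard errors."""
        layout = make_site_layout(
            [(2000.0 * (1 + i % 10), 2000.0 * (1 + i // 10),
              simcam.SITE_DOCKING, 0.0) for i in range(100)],
            field=(25000.0, 25000.0))
        kin = simcam.KineticsModel(mean_dwell=1.05, event_rate=0.1)
        sched = simcam.simulate_schedule(layout, kin, 250.0, 0.25, seed=14)
        recs = []
        pos = layout.positions()
        n_events = 0
        for s in range(100):
            n_events += len(sched.intervals[s])
            for f in np.nonzero(sched.frame_photons[:, s] > 0)[0]:
                recs.append((f, pos[s, 0], pos[s, 1]))
        xy = np.array([(r[1], r[2]) for r in recs])
        frames = np.array([r[0] for r in recs])
        t = table_from_xy(xy, frames=frames, frame_time=0.25)
        assert n_events >= 2000
        est = estimate_binding_time(t, frame_time=0.25)
        se = 1.05 / np.sqrt(n_events)
        assert est == pytest.approx(1.05, abs=3 * se)

    def test_few_events_warns(self):
        t = self.fixed_duration_table(3, 10, 0.25)
        with pytest.warns(RuntimeWarning, match="events"):
            estimate_binding_time(t, frame_time=0.25)
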