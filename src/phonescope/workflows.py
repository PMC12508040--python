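"""End-to-end analysis workflows on fully synthetic acquisitions.

Each benchmark generates a smartphone-preset video with known ground
truth, runs the complete analysis chain (preprocessing -> localization ->
drift correction -> metrology) and reports the recovered quantity next to
the truth.  Problem sizes are reduced-scale versions of a real
acquisition (tens of structures, thousands of binding events) so a full
run completes in minutes on one core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import driftcorr, locfit, metrology, presets, rawproc, simcam


def _cluster_extent(xy: np.ndarray) -> float:
    """Robust major-axis extent of a localization cluster (nm)."""
    aligned, _, _ = metrology.align_cluster(xy)
    lo, hi = np.percentile(aligned[:, 0], [2, 98])
    return float(hi - lo)


def nanoruler_benchmark(seed: int, *, n_structures: int = 20,
                        target_events: int = 5600,
                        event_rate: float = 0.05,
                        mosaic_px: int = 96, pre_average_n: int = 3,
                        bin_size_nm: float = 25.0,
                        with_drift: bool = True) -> dict:
    """Recover the 256 nm nanoruler site separation with the full chain.

    Simulates a smartphone-preset DNA-PAINT video of two-site nanorulers
    (sites 256 nm apart) plus 3 fiducial markers and slow stage drift,
    then: baseline subtraction -> green-channel split -> 3-frame
    pre-average -> MLE localization -> fiducial drift correction ->
    clustering -> principal-axis averaging -> shared-sigma double-Gaussian
    fit of the axis profile.
    """
    camera = presets.camera("smartphone")
    optics = presets.optics("smartphone")
    kin = replace(presets.kinetics(), event_rate=event_rate)
    drift = presets.desk_drift() if with_drift else simcam.DriftModel()

    field_nm = mosaic_px * camera.pixel_size_nm
    area_um2 = (field_nm / 1000.0) ** 2
    n_sites = 2 * n_structures
    duration = target_events / (n_sites * event_rate)

    ss = np.random.SeedSequence(seed)
    s_layout, s_fid, s_sched, s_render = ss.spawn(4)
    layout = simcam.make_layout("8HB", (field_nm, field_nm),
                                n_structures / area_um2,
                                rng=np.random.default_rng(s_layout))
    layout = simcam.add_fiducials(layout, 3, margin_nm=4000.0,
                                  rng=np.random.default_rng(s_fid))
    schedule = simcam.simulate_schedule(layout, kin, duration,
                                        camera.frame_time,
                                        rng=np.random.default_rng(s_sched))
    n_events = sum(len(iv) for iv, t in zip(schedule.intervals,
                                            layout.sites["type"])
                   if t == simcam.SITE_DOCKING)
    sim = simcam.render_video(schedule, layout, optics, camera, drift,
                              background_photons_px_s=50.0,
                              rng=np.random.default_rng(s_render))

    sub = rawproc.subtract_baseline(sim.stack, camera.baseline)
    green = rawproc.split_bayer(sub)["G"]
    table = locfit.localize_stack(green, box_px=7, threshold_k=6.0,
                                  pre_average_n=pre_average_n,
                                  gain=camera.gain)

    tracks = driftcorr.find_fiducials(table, link_radius_nm=500.0)
    trajectory = driftcorr.estimate_drift(tracks, smooth_window_frames=50,
                                          n_frames=table.n_frames)
    corrected = driftcorr.apply_drift(table, trajectory)
    corrected = driftcorr.mask_fiducials(corrected, tracks, radius_nm=500.0,
                                         trajectory=trajectory)
    sigma_nm = optics.psf_sigma_nm
    corrected = locfit.filter_sigma(corrected, 0.5 * sigma_nm, 2.0 * sigma_nm)

    clusters = metrology.cluster_structures(corrected, eps_nm=300.0,
                                            min_pts=50)
    xy = corrected.xy()
    clusters = [c for c in clusters
                if 150.0 <= _cluster_extent(xy[c]) <= 500.0]
    if not clusters:
        raise RuntimeError("no nanoruler clusters survived quality control")
    _, angles, pooled = metrology.align_and_average(clusters, corrected,
                                                    bin_size_nm=bin_size_nm)
    fit = metrology.axis_profile_fit(pooled[:, 0], bin_size_nm=bin_size_nm)
    return {"distance_nm": fit.distance, "sigma_nm": fit.sigma_shared,
            "fwhm_nm": fit.fwhm, "fit": fit, "n_events": n_events,
            "n_localizations": len(corrected), "n_clusters": len(clusters),
            "table": corrected, "trajectory": trajectory,
            "true_distance_nm": 256.0}


def dwell_benchmark(seed: int, *, n_sites: int = 196,
                    target_events: int = 2400,
                    event_rate: float = 0.02,
                    grid_spacing_px: int = 16) -> dict:
    """Recover the 1.05 s imager dwell time from localized binding events.

    Docking sites are laid out on a grid (spacing wide enough that
    neighboring sites never compete during candidate detection), imaged at
    250 ms frames with the smartphone preset and localized frame by frame;
    events are linked across consecutive frames and the exponential dwell
    is estimated with the discretization-corrected geometric MLE.  The
    per-site event rate is kept low so that consecutive events at one
    site are almost never separated by less than a frame (which would
    merge them and bias the estimate upward).
    """
    camera = presets.camera("smartphone")
    optics = presets.optics("smartphone")
    kin = replace(presets.kinetics(), event_rate=event_rate)

    side = int(np.ceil(np.sqrt(n_sites)))
    a = camera.pixel_size_nm
    spacing = grid_spacing_px * a
    margin = 8 * a
    field_nm = margin * 2 + spacing * (side - 1)
    rows = []
    for i in range(n_sites):
        r, c = divmod(i, side)
        rows.append((i, i, margin + c * spacing, margin + r * spacing,
                     simcam.SITE_DOCKING, 28.0))
    layout = simcam.EmitterLayout(
        sites=pd.DataFrame(rows, columns=["structure_id", "site_id", "x_nm",
                                          "y_nm", "type", "site_extent_nm"]),
        field_size_nm=(field_nm, field_nm), design="dwell-grid")

    duration = target_events / (n_sites * event_rate)
    ss = np.random.SeedSequence(seed)
    s_sched, s_render = ss.spawn(2)
    schedule = simcam.simulate_schedule(layout, kin, duration,
                                        camera.frame_time,
                                        rng=np.random.default_rng(s_sched))
    n_events = sum(len(iv) for iv in schedule.intervals)
    sim = simcam.render_video(schedule, layout, optics, camera,
                              background_photons_px_s=50.0,
                              rng=np.random.default_rng(s_render))
    sub = rawproc.subtract_baseline(sim.stack, camera.baseline)
    green = rawproc.split_bayer(sub)["G"]
    table = locfit.localize_stack(green, box_px=7, threshold_k=6.0,
                                  gain=camera.gain)
    dwell = metrology.estimate_binding_time(table, link_radius_nm=500.0,
                                            frame_time=camera.frame_time)
    se = kin.mean_dwell / np.sqrt(max(n_events, 1))
    return {"dwell_s": dwell, "n_events": n_events, "se_s": se,
            "true_dwell_s": kin.mean_dwell, "table": table}


def drift_benchmark(seed: int, *, n_frames: int = 361,
                    frame_time_s: float = 10.0, n_fiducials: int = 3,
                    mosaic_px: int = 96) -> dict:
    """Recover a ~3.5 µm/hour drift endpoint from fiducial tracks.

    Three always-on fiducials are imaged for one hour at one frame per
    10 s under the desk-drift preset (linear 3.5 µm/h plus a 1 nm/sqrt
    frame random walk); the estimator output is compared with the exact
    simulated trajectory.
    """
    camera = replace(presets.camera("smartphone"), frame_time=frame_time_s)
    optics = presets.optics("smartphone")
    # keep the long-exposure fiducial images well below saturation
    kin = replace(presets.kinetics(), fiducial_photons_per_second=3000.0)
    drift = presets.desk_drift()

    field_nm = mosaic_px * camera.pixel_size_nm
    layout = simcam.EmitterLayout(
        sites=pd.DataFrame(columns=["structure_id", "site_id", "x_nm", "y_nm",
                                    "type", "site_extent_nm"]),
        field_size_nm=(field_nm, field_nm), design="fiducials")
    ss = np.random.SeedSequence(seed)
    s_fid, s_sched, s_render = ss.spawn(3)
    layout = simcam.add_fiducials(layout, n_fiducials, margin_nm=5000.0,
                                  rng=np.random.default_rng(s_fid))
    duration = n_frames * frame_time_s
    schedule = simcam.simulate_schedule(layout, kin, duration, frame_time_s,
                                        rng=np.random.default_rng(s_sched))
    sim = simcam.render_video(schedule, layout, optics, camera, drift,
                              background_photons_px_s=5.0,
                              rng=np.random.default_rng(s_render))
    sub = rawproc.subtract_baseline(sim.stack, camera.baseline)
    green = rawproc.split_bayer(sub)["G"]
    table = locfit.localize_stack(green, box_px=7, threshold_k=6.0,
                                  gain=camera.gain)
    tracks = driftcorr.find_fiducials(table, link_radius_nm=1000.0)
    trajectory = driftcorr.estimate_drift(tracks, smooth_window_frames=50,
                                          n_frames=table.n_frames)
    true_endpoint = float(np.hypot(*sim.drift_nm[-1]))
    return {"endpoint_um": trajectory.endpoint_nm / 1000.0,
            "true_endpoint_um": true_endpoint / 1000.0,
            "trajectory": trajectory, "n_tracks": len(tracks),
            "drift_true_nm": sim.drift_nm}
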