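"""Synthetic smartphone-camera single-molecule video generator.

Produces Bayer-mosaic (or mono) image stacks of sparse point emitters with
known ground truth: DNA-origami site layouts, DNA-PAINT binding kinetics,
single-step photobleaching, always-on fiducial markers, an integrated
Gaussian PSF, per-channel color sensitivity, Poisson shot noise, Gaussian
read noise and slow stage drift.  Every stage is seeded and reproducible,
so the downstream analysis chain can be validated end to end without
instrument data.

Conventions
-----------
* All sample-plane coordinates are in nanometres; pixel ``p`` of the mosaic
  covers ``[p*a, (p+1)*a)`` nm where ``a`` is the mosaic pixel pitch.
* FWHM and Gaussian sigma are related by the fixed package-wide factor
  ``FWHM_PER_SIGMA = 2.35``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

FWHM_PER_SIGMA = 2.35

SITE_DOCKING = "docking"
SITE_FIXED_DYE = "fixed_dye"
SITE_FIDUCIAL = "fiducial"

_BAYER_LAYOUTS = {
    "RGGB": (("R", "G"), ("G", "B")),
    "BGGR": (("B", "G"), ("G", "R")),
    "GRBG": (("G", "R"), ("B", "G")),
    "GBRG": (("G", "B"), ("R", "G")),
}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Sensor model: geometry, color filter array and noise parameters.

    ``channel_sensitivity`` is the relative quantum efficiency of each CFA
    color for the simulated emission band (values in [0, 1]).  ``gain`` is
    in counts per photoelectron, ``baseline`` and ``read_noise_sd`` in
    counts.
    """

    pixel_size_nm: float
    bayer_pattern: str = "RGGB"
    baseline: float = 512.0
    read_noise_sd: float = 6.0
    gain: float = 1.8
    channel_sensitivity: dict = field(
        default_factory=lambda: {"R": 0.45, "G": 1.0, "B": 0.0}
    )
    bit_depth: int = 16
    frame_time: float = 0.25

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.bayer_pattern != "mono" and self.bayer_pattern not in _BAYER_LAYOUTS:
            raise ValueError(f"unknown Bayer pattern {self.bayer_pattern!r}")
        for ch, s in self.channel_sensitivity.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"channel sensitivity {ch}={s} outside [0, 1]")

    @property
    def saturation(self) -> int:
        return 2 ** self.bit_depth - 1

    def sensitivity_map(self, shape: tuple[int, int],
                        sensitivity: dict | None = None) -> np.ndarray:
        """Per-pixel relative sensitivity for this CFA and emission color."""
        sens = self.channel_sensitivity if sensitivity is None else sensitivity
        h, w = shape
        if self.bayer_pattern == "mono":
            return np.full((h, w), float(sens.get("mono", 1.0)))
        layout = _BAYER_LAYOUTS[self.bayer_pattern]
        out = np.empty((h, w))
        for dr in (0, 1):
            for dc in (0, 1):
                out[dr::2, dc::2] = float(sens.get(layout[dr][dc], 0.0))
        return out


@dataclass(frozen=True)
class OpticsModel:
    """Point-spread-function model: symmetric Gaussian of given FWHM."""

    psf_fwhm_nm: float
    name: str = ""

    def __post_init__(self):
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be > 0")

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm_nm / FWHM_PER_SIGMA


@dataclass(frozen=True)
class KineticsModel:
    """Emission kinetics for the three site types.

    Docking sites blink: exponential on-times (``mean_dwell``) separated by
    exponential waits (rate ``event_rate`` per site).  Fixed dyes are on
    from t=0 until a single exponential photobleaching step.  Fiducials are
    always on and never bleach.
    """

    mean_dwell: float = 1.05
    event_rate: float = 0.05
    bleach_mean_time: float = 30.0
    photons_per_second_on: float = 8000.0
    fiducial_photons_per_second: float = 30000.0

    def __post_init__(self):
        for name in ("mean_dwell", "event_rate", "bleach_mean_time",
                     "photons_per_second_on", "fiducial_photons_per_second"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DriftModel:
    """Stage drift: linear velocity (nm/s) plus a per-frame random walk."""

    linear_velocity: tuple[float, float] = (0.0, 0.0)
    random_walk_sd: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.linear_velocity)):
            raise ValueError("linear_velocity must be finite")
        if not np.isfinite(self.random_walk_sd) or self.random_walk_sd < 0:
            raise ValueError("random_walk_sd must be finite and >= 0")


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

@dataclass
class EmitterLayout:
    """Ground-truth emitter sites for a simulated field of view.

    ``sites`` has columns: structure_id, site_id, x_nm, y_nm, type,
    site_extent_nm.
    """

    sites: pd.DataFrame
    field_size_nm: tuple[float, float]
    design: str = ""

    def __post_init__(self):
        w, h = self.field_size_nm
        if len(self.sites):
            x, y = self.sites["x_nm"].values, self.sites["y_nm"].values
            if (x < 0).any() or (x > w).any() or (y < 0).any() or (y > h).any():
                raise ValueError("layout contains sites outside the field")
            if (self.sites["site_extent_nm"].values < 0).any():
                raise ValueError("site_extent_nm must be >= 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return self.sites[["x_nm", "y_nm"]].to_numpy(float)


def _preset_sites(design: str, second_dye: bool,
                  with_target: bool) -> list[tuple[float, float, str, float]]:
    """Local (unrotated, centered) site geometry of each origami preset."""
    if design == "2LS":
        sites = [(0.0, 0.0, SITE_FIXED_DYE, 0.0)]
        if second_dye:
            sites.append((22.0, 0.0, SITE_FIXED_DYE, 0.0))
        return sites
    if design == "8HB":
        return [(-128.0, 0.0, SITE_DOCKING, 28.0),
                (128.0, 0.0, SITE_DOCKING, 28.0)]
    if design == "dimer_sensor":
        # ~600 nm dimer: control sites at one end and as an unresolvable
        # central pair; the target site (occupied only when the analyte is
        # captured) sits at the far end.
        sites = [(-300.0, 0.0, SITE_DOCKING, 28.0),
                 (-10.0, 0.0, SITE_DOCKING, 28.0),
                 (10.0, 0.0, SITE_DOCKING, 28.0)]
        if with_target:
            sites.append((300.0, 0.0, SITE_DOCKING, 28.0))
        return sites
    raise ValueError(f"unknown layout preset {design!r}")


def make_layout(design: str, field_size_nm: tuple[float, float],
                density_per_um2: float, seed: int | None = None, *,
                second_dye: bool = False, target_occupancy: float = 1.0,
                rng: np.random.Generator | None = None) -> EmitterLayout:
    """Place ``design``-preset structures uniformly at random in the field.

    The number of structures is ``round(density * area)``; each structure
    gets an independent uniform in-plane rotation.  ``target_occupancy``
    applies to the ``dimer_sensor`` preset only: it is the probability that
    a given sensor carries its target site (analyte captured).
    """
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    w, h = field_size_nm
    area_um2 = (w / 1000.0) * (h / 1000.0)
    n = int(round(density_per_um2 * area_um2))

    base = _preset_sites(design, second_dye, True)  # probe geometry / extent
    radius = max(np.hypot(x, y) for x, y, _, _ in base) + 1.0
    rows = []
    if n > 0:
        if 2 * radius >= min(w, h):
            raise ValueError("field too small to hold one structure")
        site_counter = 0
        for sid in range(n):
            cx = rng.uniform(radius, w - radius)
            cy = rng.uniform(radius, h - radius)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            with_target = True
            if design == "dimer_sensor":
                with_target = bool(rng.random() < target_occupancy)
            ct, st = np.cos(theta), np.sin(theta)
            for lx, ly, typ, ext in _preset_sites(design, second_dye, with_target):
                rows.append((sid, site_counter,
                             cx + ct * lx - st * ly,
                             cy + st * lx + ct * ly, typ, ext))
                site_counter += 1
    sites = pd.DataFrame(
        rows, columns=["structure_id", "site_id", "x_nm", "y_nm",
                       "type", "site_extent_nm"])
    return EmitterLayout(sites=sites, field_size_nm=field_size_nm, design=design)


def add_fiducials(layout: EmitterLayout, n: int,
                  seed: int | None = None, margin_nm: float = 2000.0,
                  min_separation_nm: float = 8000.0,
                  rng: np.random.Generator | None = None) -> EmitterLayout:
    """Return a copy of ``layout`` with ``n`` always-on fiducial sites added.

    Fiducials are kept at least ``min_separation_nm`` apart (markers too
    close together shadow each other during spot detection), by rejection
    sampling.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    w, h = layout.field_size_nm
    next_struct = int(layout.sites["structure_id"].max() + 1) if len(layout.sites) else 0
    next_site = int(layout.sites["site_id"].max() + 1) if len(layout.sites) else 0
    rows = []
    placed: list[tuple[float, float]] = []
    for i in range(n):
        for _ in range(1000):
            x = rng.uniform(margin_nm, w - margin_nm)
            y = rng.uniform(margin_nm, h - margin_nm)
            if all(np.hypot(x - px, y - py) >= min_separation_nm
                   for px, py in placed):
                break
        else:
            raise ValueError("could not place fiducials with the requested "
                             "separation")
        placed.append((x, y))
        rows.append((next_struct + i, next_site + i, x, y, SITE_FIDUCIAL, 0.0))
    new = pd.DataFrame(rows, columns=layout.sites.columns)
    sites = new if layout.sites.empty else pd.concat([layout.sites, new],
                                                     ignore_index=True)
    return EmitterLayout(sites=sites, field_size_nm=layout.field_size_nm,
                         design=layout.design)


# ---------------------------------------------------------------------------
# emission schedule
# ---------------------------------------------------------------------------

@dataclass
class EmissionSchedule:
    """Per-site on-intervals and the derived per-frame photon expectations.

    ``frame_photons[f, s]`` is the expected photon count emitted by site
    ``s`` during frame ``f`` (flux times the overlap of the site's
    on-intervals with the frame).  ``frame_interval[f, s]`` is the index of
    the on-interval with the largest overlap in that frame (-1 if off).
    """

    intervals: list[list[tuple[float, float]]]
    frame_photons: np.ndarray
    frame_interval: np.ndarray
    duration: float
    frame_time: float

    @property
    def n_frames(self) -> int:
        return self.frame_photons.shape[0]

    def on_times(self, site: int) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals[site]])


def _docking_intervals(rng, duration, mean_dwell, event_rate):
    out, t = [], 0.0
    while True:
        t += rng.exponential(1.0 / event_rate)
        if t >= duration:
            return out
        dwell = rng.exponential(mean_dwell)
        out.append((t, min(t + dwell, duration)))
        t += dwell


def simulate_schedule(layout: EmitterLayout, kinetics: KineticsModel,
                      duration: float, frame_time: float,
                      seed: int | None = None, *,
                      rng: np.random.Generator | None = None,
                      bleach_times: Sequence[float] | None = None
                      ) -> EmissionSchedule:
    """Draw stochastic on-intervals for every site and bin them into frames.

    ``bleach_times`` can force the bleaching time of each fixed dye (in
    site order) for deterministic tests; normally they are exponential with
    mean ``kinetics.bleach_mean_time``.
    """
    if duration <= 0 or frame_time <= 0:
        raise ValueError("duration and frame_time must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_frames = int(round(duration / frame_time))
    types = layout.sites["type"].tolist()
    intervals: list[list[tuple[float, float]]] = []
    fluxes = np.empty(layout.n_sites)
    bleach_iter = iter(bleach_times) if bleach_times is not None else None
    for s, typ in enumerate(types):
        if typ == SITE_FIDUCIAL:
            intervals.append([(0.0, duration)])
            fluxes[s] = kinetics.fiducial_photons_per_second
        elif typ == SITE_FIXED_DYE:
            if bleach_iter is not None:
                tb = float(next(bleach_iter))
            else:
                tb = rng.exponential(kinetics.bleach_mean_time)
            intervals.append([(0.0, min(tb, duration))] if tb > 0 else [])
            fluxes[s] = kinetics.photons_per_second_on
        elif typ == SITE_DOCKING:
            intervals.append(_docking_intervals(
                rng, duration, kinetics.mean_dwell, kinetics.event_rate))
            fluxes[s] = kinetics.photons_per_second_on
        else:
            raise ValueError(f"unknown site type {typ!r}")

    frame_photons = np.zeros((n_frames, layout.n_sites))
    frame_interval = np.full((n_frames, layout.n_sites), -1, dtype=np.int32)
    best_overlap = np.zeros((n_frames, layout.n_sites))
    for s, ivs in enumerate(intervals):
        for k, (a, b) in enumerate(ivs):
            f0 = max(int(a / frame_time), 0)
            f1 = min(int(np.ceil(b / frame_time)), n_frames)
            for f in range(f0, f1):
                ov = min(b, (f + 1) * frame_time) - max(a, f * frame_time)
                if ov <= 0:
                    continue
                frame_photons[f, s] += fluxes[s] * ov
                if ov > best_overlap[f, s]:
                    best_overlap[f, s] = ov
                    frame_interval[f, s] = k
    return EmissionSchedule(intervals=intervals, frame_photons=frame_photons,
                            frame_interval=frame_interval, duration=duration,
                            frame_time=frame_time)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class MosaicStack:
    """Raw sensor frames plus the metadata needed to interpret them."""

    frames: np.ndarray  # (F, H, W)
    bayer_pattern: str = "mono"
    frame_time: float = 1.0
    bit_depth: int = 16
    pixel_size_nm: float | None = None
    baseline: float | None = None

    def __post_init__(self):
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (F, H, W) array with F >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SimulationResult:
    stack: MosaicStack
    truth: pd.DataFrame           # frame, site_id, x_nm, y_nm, photons
    drift_nm: np.ndarray          # (F, 2) cumulative (dx, dy)
    layout: EmitterLayout
    schedule: EmissionSchedule


def simulate_drift_trajectory(drift: DriftModel, n_frames: int,
                              frame_time: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Cumulative (dx, dy) in nm per frame: linear term + random-walk sums.

    Frame 0 is the origin.  Increments are drawn as
    ``rng.normal(0, random_walk_sd, size=(n_frames - 1, 2))`` and summed,
    so the exported trajectory is exactly linear + partial sums.
    """
    t = np.arange(n_frames) * frame_time
    traj = np.outer(t, np.asarray(drift.linear_velocity, float))
    if drift.random_walk_sd > 0 and n_frames > 1:
        steps = rng.normal(0.0, drift.random_walk_sd, size=(n_frames - 1, 2))
        traj[1:] += np.cumsum(steps, axis=0)
    return traj


def _stamp(expected: np.ndarray, x_px: float, y_px: float,
           photons: float, sigma_px: float, reach: float) -> None:
    """Add an integrated-Gaussian spot to the expected-photon image."""
    h, w = expected.shape
    r = int(np.ceil(reach * sigma_px))
    c0, c1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    r0, r1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    c0, c1 = max(c0, 0), min(c1, w)
    r0, r1 = max(r0, 0), min(r1, h)
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    ex = ndtr((cols - x_px) / sigma_px)
    ey = ndtr((rows - y_px) / sigma_px)
    expected[r0:r1, c0:c1] += photons * np.outer(np.diff(ey), np.diff(ex))


def render_video(schedule: EmissionSchedule, layout: EmitterLayout,
                 optics: OpticsModel, camera: CameraModel,
                 drift: DriftModel | None = None, seed: int | None = None, *,
                 noise: bool = True, background_photons_px_s: float = 0.0,
                 background_sensitivity: dict | None = None,
                 stamp_reach_sigma: float = 5.0,
                 rng: np.random.Generator | None = None) -> SimulationResult:
    """Render the emission schedule into a camera mosaic stack.

    Per frame: emitter positions are shifted by the cumulative drift;
    docking-site binding positions are additionally jittered uniformly
    within a disc of diameter ``site_extent`` (one draw per binding event);
    expected photons are spread over pixels with the pixel-integrated
    Gaussian PSF; per-pixel photoelectrons are Poisson with the pixel's CFA
    sensitivity applied; counts = gain * electrons + baseline + read noise,
    rounded and clipped to [0, saturation].  With ``noise=False`` the exact
    expectation is returned unrounded (floating point), which makes photon
    conservation testable.

    ``background_photons_px_s`` adds a uniform background photon rate per
    pixel (at unit sensitivity); its spectral profile
    ``background_sensitivity`` defaults to broadband with the blue channel
    blocked by the long-pass emission filter.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a = camera.pixel_size_nm
    w_nm, h_nm = layout.field_size_nm
    shape = (int(round(h_nm / a)), int(round(w_nm / a)))
    n_frames = schedule.n_frames
    sigma_px = optics.psf_sigma_nm / a

    drift = drift or DriftModel()
    traj = simulate_drift_trajectory(drift, n_frames, schedule.frame_time, rng)

    # one position jitter per binding event, drawn up front per interval
    extents = layout.sites["site_extent_nm"].to_numpy(float)
    types = layout.sites["type"].tolist()
    jitters: list[np.ndarray] = []
    for s, ivs in enumerate(schedule.intervals):
        if types[s] == SITE_DOCKING and extents[s] > 0 and len(ivs):
            radius = extents[s] / 2.0
            rr = radius * np.sqrt(rng.uniform(0.0, 1.0, len(ivs)))
            th = rng.uniform(0.0, 2.0 * np.pi, len(ivs))
            jitters.append(np.column_stack([rr * np.cos(th), rr * np.sin(th)]))
        else:
            jitters.append(np.zeros((max(len(ivs), 1), 2)))

    sens = camera.sensitivity_map(shape)
    if background_sensitivity is None:
        background_sensitivity = {"R": 1.0, "G": 1.0, "B": 0.0, "mono": 1.0}
    bg_sens = camera.sensitivity_map(shape, background_sensitivity)
    bg_expected = background_photons_px_s * schedule.frame_time * bg_sens

    positions = layout.positions()
    sat = camera.saturation
    frames = np.empty((n_frames,) + shape,
                      dtype=np.uint16 if noise else np.float64)
    truth_rows = []
    all_outside_frames = 0
    for f in range(n_frames):
        expected = np.zeros(shape)
        active = np.nonzero(schedule.frame_photons[f] > 0)[0]
        inside_this_frame = False
        for s in active:
            k = schedule.frame_interval[f, s]
            jx, jy = jitters[s][k] if k >= 0 else (0.0, 0.0)
            x = positions[s, 0] + traj[f, 0] + jx
            y = positions[s, 1] + traj[f, 1] + jy
            photons = schedule.frame_photons[f, s]
            _stamp(expected, x / a, y / a, photons, sigma_px, stamp_reach_sigma)
            if 0 <= x < w_nm and 0 <= y < h_nm:
                inside_this_frame = True
            truth_rows.append((f, int(layout.sites["site_id"].iloc[s]),
                               x, y, photons))
        if len(active) and not inside_this_frame:
            all_outside_frames += 1
        e_map = expected * sens + bg_expected
        if noise:
            electrons = rng.poisson(e_map).astype(np.float64)
            counts = camera.gain * electrons + camera.baseline
            if camera.read_noise_sd > 0:
                counts = counts + rng.normal(0.0, camera.read_noise_sd, shape)
            frames[f] = np.clip(np.rint(counts), 0, sat).astype(np.uint16)
        else:
            frames[f] = camera.gain * e_map + camera.baseline
    if all_outside_frames:
        warnings.warn(f"drift moved every emitter outside the field in "
                      f"{all_outside_frames} frame(s)",
                      RuntimeWarning, stacklevel=2)

    stack = MosaicStack(frames=frames, bayer_pattern=camera.bayer_pattern,
                        frame_time=schedule.frame_time,
                        bit_depth=camera.bit_depth, pixel_size_nm=a,
                        baseline=camera.baseline)
    truth = pd.DataFrame(truth_rows,
                         columns=["frame", "site_id", "x_nm", "y_nm", "photons"])
    return SimulationResult(stack=stack, truth=truth, drift_nm=traj,
                            layout=layout, schedule=schedule)


def simulate_dark_stack(camera: CameraModel, n_frames: int,
                        shape: tuple[int, int] = (64, 64),
                        seed: int | None = None, *,
                        rng: np.random.Generator | None = None) -> MosaicStack:
    """Dark frames: baseline plus read noise only (no photon signal)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.full((n_frames,) + shape, camera.baseline, dtype=np.float64)
    if camera.read_noise_sd > 0:
        counts += rng.normal(0.0, camera.read_noise_sd, counts.shape)
    frames = np.clip(np.rint(counts), 0, camera.saturation).astype(np.uint16)
    return MosaicStack(frames=frames, bayer_pattern=camera.bayer_pattern,
                       frame_time=camera.frame_time, bit_depth=camera.bit_depth,
                       pixel_size_nm=camera.pixel_size_nm,
                       baseline=camera.baseline)
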