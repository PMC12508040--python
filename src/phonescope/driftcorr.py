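"""Fiducial-marker drift estimation and correction of localization tables.

Gold nanoparticles are bright and never blink, so they appear in (nearly)
every frame of an acquisition.  Tracks are built by greedy frame-to-frame
nearest-neighbor linking; tracks present in most frames and spanning the
acquisition are fiducials.  The drift trajectory is the across-track mean
of each track's displacement from its initial position, gap-interpolated
and smoothed with a centered local-linear (Savitzky-Golay, order 1)
filter, which is exact for linear drift including at the trace ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree

from .locfit import LocalizationTable


@dataclass
class DriftTrajectory:
    """Cumulative per-frame (dx, dy) in nm, anchored at 0 for frame 0."""

    dx_nm: np.ndarray
    dy_nm: np.ndarray

    def __post_init__(self):
        self.dx_nm = np.asarray(self.dx_nm, float)
        self.dy_nm = np.asarray(self.dy_nm, float)
        if self.dx_nm.shape != self.dy_nm.shape:
            raise ValueError("dx and dy must have the same length")

    def __len__(self) -> int:
        return len(self.dx_nm)

    @property
    def endpoint_nm(self) -> float:
        return float(np.hypot(self.dx_nm[-1], self.dy_nm[-1]))

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(dx_nm=-self.dx_nm, dy_nm=-self.dy_nm)

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self)),
                      "dx_nm": self.dx_nm,
                      "dy_nm": self.dy_nm}).to_csv(path, index=False)


def find_fiducials(table: LocalizationTable, min_presence: float = 0.8,
                   link_radius_nm: float = 500.0, max_gap_frames: int = 5,
                   min_span: float = 0.9) -> list[pd.DataFrame]:
    """Extract always-on marker tracks from a localization table.

    Localizations are linked greedily frame to frame (nearest neighbor
    within ``link_radius_nm``; gaps up to ``max_gap_frames`` tolerated).
    Tracks present in at least ``min_presence`` of all frames and spanning
    at least ``min_span`` of the acquisition are returned as DataFrames
    with columns (frame, x_nm, y_nm).  Transient binding events (~1 s
    dwell) can never satisfy the presence requirement.
    """
    if len(table) == 0:
        raise ValueError("empty localization table")
    n_frames = table.n_frames or int(table.df["frame"].max()) + 1
    tracks: list[dict] = []
    for f, grp in table.df.groupby("frame", sort=True):
        pts = grp[["x_nm", "y_nm"]].to_numpy(float)
        active = [t for t in tracks if f - t["last_frame"] <= max_gap_frames]
        pairs = []
        for ti, t in enumerate(active):
            d = np.hypot(pts[:, 0] - t["last_xy"][0], pts[:, 1] - t["last_xy"][1])
            for pi in np.nonzero(d <= link_radius_nm)[0]:
                pairs.append((d[pi], ti, int(pi)))
        used_t, used_p = set(), set()
        for d, ti, pi in sorted(pairs):
            if ti in used_t or pi in used_p:
                continue
            t = active[ti]
            t["frames"].append(int(f))
            t["xs"].append(pts[pi, 0])
            t["ys"].append(pts[pi, 1])
            t["last_xy"] = pts[pi]
            t["last_frame"] = int(f)
            used_t.add(ti)
            used_p.add(pi)
        for pi in range(len(pts)):
            if pi not in used_p:
                tracks.append({"frames": [int(f)], "xs": [pts[pi, 0]],
                               "ys": [pts[pi, 1]], "last_xy": pts[pi],
                               "last_frame": int(f)})
    tracks = _merge_fragments(tracks, 2.0 * link_radius_nm, max_gap_frames)
    out = []
    for t in tracks:
        n_present = len(t["frames"])
        span = t["frames"][-1] - t["frames"][0]
        if (n_present >= min_presence * n_frames
                and span >= min_span * max(n_frames - 1, 1)):
            out.append(pd.DataFrame({"frame": t["frames"],
                                     "x_nm": t["xs"], "y_nm": t["ys"]}))
    return out


def _merge_fragments(tracks: list[dict], radius_nm: float,
                     max_gap_frames: int) -> list[dict]:
    """Stitch track fragments split by a single stray localization.

    A fragment starting within ``max_gap_frames + 1`` frames of another
    fragment's end and within ``radius_nm`` of its last position is
    appended to it; repeated until stable.
    """
    tracks = sorted(tracks, key=lambda t: t["frames"][0])
    merged: list[dict] = []
    for t in tracks:
        for m in merged:
            gap = t["frames"][0] - m["frames"][-1]
            if (1 <= gap <= max_gap_frames + 1
                    and np.hypot(t["xs"][0] - m["xs"][-1],
                                 t["ys"][0] - m["ys"][-1]) <= radius_nm):
                m["frames"].extend(t["frames"])
                m["xs"].extend(t["xs"])
                m["ys"].extend(t["ys"])
                break
        else:
            merged.append(t)
    return merged


def estimate_drift(tracks: list[pd.DataFrame],
                   smooth_window_frames: int = 50,
                   n_frames: int | None = None) -> DriftTrajectory:
    """Average fiducial displacement per frame, interpolated and smoothed.

    Each track contributes (position - its first observed position); gaps
    are linearly interpolated over the full frame range; the across-track
    mean is smoothed with a centered first-order Savitzky-Golay filter of
    width ``smooth_window_frames`` and anchored to (0, 0) at frame 0.
    """
    if not tracks:
        raise ValueError("no fiducial tracks to estimate drift from")
    if n_frames is None:
        n_frames = int(max(t["frame"].max() for t in tracks)) + 1
    frames = np.arange(n_frames)
    disp = np.zeros((len(tracks), n_frames, 2))
    for i, t in enumerate(tracks):
        tf = t["frame"].to_numpy(float)
        for k, col in enumerate(("x_nm", "y_nm")):
            v = t[col].to_numpy(float)
            disp[i, :, k] = np.interp(frames, tf, v - v[0])
    mean_disp = disp.mean(axis=0)
    win = int(smooth_window_frames)
    if win > 1:
        win = min(win, n_frames)
        if win % 2 == 0:
            win -= 1
    if win >= 3:
        mean_disp = savgol_filter(mean_disp, window_length=win, polyorder=1,
                                  axis=0, mode="interp")
    mean_disp = mean_disp - mean_disp[0]
    return DriftTrajectory(dx_nm=mean_disp[:, 0], dy_nm=mean_disp[:, 1])


def apply_drift(table: LocalizationTable,
                trajectory: DriftTrajectory) -> LocalizationTable:
    """Subtract the per-frame drift from every localization."""
    frames = table.df["frame"].to_numpy(int)
    if len(frames) and frames.max() >= len(trajectory):
        raise ValueError("trajectory shorter than the table's frame range")
    df = table.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy(float) - trajectory.dx_nm[frames]
    df["y_nm"] = df["y_nm"].to_numpy(float) - trajectory.dy_nm[frames]
    return table.copy_with(df, "apply_drift")


def mask_fiducials(table: LocalizationTable, tracks: list[pd.DataFrame],
                   radius_nm: float = 500.0,
                   trajectory: DriftTrajectory | None = None
                   ) -> LocalizationTable:
    """Drop localizations within ``radius_nm`` of any fiducial track center.

    Run after drift correction so each marker collapses to a tight spot;
    pass the same ``trajectory`` so the (uncorrected) track positions are
    un-drifted before their centers are taken.  Keeps the always-on
    markers out of downstream metrology.
    """
    if not tracks or len(table) == 0:
        return table.copy_with(table.df.copy(), "mask_fiducials(none)")
    centers = []
    for t in tracks:
        x = t["x_nm"].to_numpy(float)
        y = t["y_nm"].to_numpy(float)
        if trajectory is not None:
            f = t["frame"].to_numpy(int)
            x = x - trajectory.dx_nm[f]
            y = y - trajectory.dy_nm[f]
        centers.append([x.mean(), y.mean()])
    centers = np.array(centers)
    tree = cKDTree(centers)
    d, _ = tree.query(table.xy(), k=1)
    df = table.df[d > radius_nm]
    return table.copy_with(df, f"mask_fiducials(r={radius_nm})")
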