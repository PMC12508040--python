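"""Single-molecule detectability metrics.

Spot detection on a (baseline-subtracted, frame-summed) image, the
signal-to-background ratio (Weber contrast) with its exact square-ROI
geometry, circular-ROI intensity traces, single-step photobleach
detection, and the trace-based signal-to-noise ratio.

Definitions
-----------
SBR = (S - B) / B, where S is the mean over an inner 6x6 px ROI and B the
mean over the 28-pixel ring left when that ROI is removed from the
concentric 8x8 px ROI.  Spots whose outer ROI overlaps another detected
spot's outer ROI are excluded.

SNR = (S - B) / sigma_S from a raw (un-averaged) intensity trace: S and
sigma_S are the mean and sample SD before the photobleach step, B the
mean after it (the post-bleach signal is the local background).

Coordinates here are (row, col) pixel indices; the center of pixel p is
at coordinate p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class SpotRecord:
    center: tuple[float, float]           # (row, col)
    sbr: float | None = None
    snr: float | None = None
    signal: float | None = None
    background: float | None = None
    excluded: bool = False
    reason: str = ""


@dataclass
class IntensityTrace:
    """Per-frame mean over a 6-pixel-diameter circular ROI, no averaging."""

    values: np.ndarray
    frame_time: float
    center: tuple[float, float]
    roi_diameter_px: float = 6.0
    time_averaged: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_time


def detect_spots(image: np.ndarray, min_separation_px: float = 5.0,
                 threshold_k: float = 5.0, psf_sigma_px: float = 1.3
                 ) -> list[tuple[float, float]]:
    """Find diffraction-limited spot centers in a single image.

    The image is smoothed with a Gaussian of sigma = psf_sigma/sqrt(2)
    (matched-filter scale); local maxima above median + k*MAD survive;
    maxima closer than ``min_separation_px`` keep only the brightest
    (ties: smallest row, then col).  Centers are refined to the
    intensity-weighted centroid of a 6x6 window.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        return []
    smoothed = ndimage.gaussian_filter(image, psf_sigma_px / np.sqrt(2.0))
    med = np.median(smoothed)
    mad = np.median(np.abs(smoothed - med))
    thr = med + threshold_k * mad
    is_max = (smoothed == ndimage.maximum_filter(smoothed, size=3)) & (smoothed > thr)
    rows, cols = np.nonzero(is_max)
    if len(rows) == 0:
        return []
    order = np.lexsort((cols, rows, -smoothed[rows, cols]))
    kept: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all((r - rk) ** 2 + (c - ck) ** 2 >= min_separation_px ** 2
               for rk, ck in kept):
            kept.append((r, c))
    centers = []
    h, w = image.shape
    for r, c in kept:
        r0, c0 = max(r - 2, 0), max(c - 2, 0)
        win = image[r0:min(r0 + 6, h), c0:min(c0 + 6, w)]
        weights = np.clip(win, 0.0, None)
        tot = weights.sum()
        if tot <= 0:
            centers.append((float(r), float(c)))
            continue
        rr, cc = np.mgrid[r0:r0 + win.shape[0], c0:c0 + win.shape[1]]
        centers.append((float((weights * rr).sum() / tot),
                        float((weights * cc).sum() / tot)))
    return centers


def _roi_anchor(center: tuple[float, float]) -> tuple[int, int]:
    """Top-left index of the 6x6 inner ROI whose center is nearest to the
    detected centroid rounded to the half-pixel grid."""
    r_half = round(center[0] * 2.0) / 2.0
    c_half = round(center[1] * 2.0) / 2.0
    return int(round(r_half - 2.5)), int(round(c_half - 2.5))


def compute_sbr(image: np.ndarray, center: tuple[float, float],
                other_centers: list[tuple[float, float]] | None = None
                ) -> SpotRecord:
    """Signal-to-background ratio of one spot in a single image.

    ``image`` should already be baseline-subtracted (and, by convention,
    a short frame sum to extend the virtual exposure).  If any of
    ``other_centers``' 8x8 outer ROIs overlaps this spot's outer ROI the
    spot is excluded from the statistics.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    r0, c0 = _roi_anchor(center)
    if r0 - 1 < 0 or c0 - 1 < 0 or r0 + 7 > h or c0 + 7 > w:
        raise ValueError("8x8 outer ROI extends beyond the image")
    for oc in other_centers or []:
        orr, occ = _roi_anchor(oc)
        if abs(orr - r0) < 8 and abs(occ - c0) < 8:
            return SpotRecord(center=center, excluded=True,
                              reason="outer ROI overlaps another spot")
    inner = image[r0:r0 + 6, c0:c0 + 6]
    outer = image[r0 - 1:r0 + 7, c0 - 1:c0 + 7]
    s = inner.mean()
    b = (outer.sum() - inner.sum()) / (outer.size - inner.size)
    if b <= 0:
        return SpotRecord(center=center, signal=s, background=b,
                          excluded=True, reason="nonpositive background")
    return SpotRecord(center=center, sbr=(s - b) / b, signal=s, background=b)


def extract_trace(stack, center: tuple[float, float],
                  roi_diameter_px: float = 6.0) -> IntensityTrace:
    """Per-frame mean over the circular ROI around ``center``.

    A pixel belongs to the ROI when its center lies within
    ``roi_diameter_px / 2`` of the spot center (pixel-center inclusion
    rule).  Raises if the ROI is clipped by the image border.
    """
    frames = np.asarray(stack.frames if hasattr(stack, "frames") else stack,
                        dtype=np.float64)
    h, w = frames.shape[1:]
    radius = roi_diameter_px / 2.0
    rc, cc = center
    rr, cci = np.mgrid[0:h, 0:w]
    mask = (rr - rc) ** 2 + (cci - cc) ** 2 <= radius ** 2
    if not mask.any():
        raise ValueError("ROI contains no pixels")
    # border check: the nominal ROI bounding box must lie inside the frame
    if (rc - radius < -0.5 or cc - radius < -0.5
            or rc + radius > h - 0.5 or cc + radius > w - 0.5):
        raise ValueError("circular ROI clipped by the image border")
    values = frames[:, mask].mean(axis=1)
    return IntensityTrace(values=values,
                          frame_time=getattr(stack, "frame_time", 1.0),
                          center=center, roi_diameter_px=roi_diameter_px)


def detect_bleach_step(trace, min_segment: int = 2,
                       accept_sd: float = 2.0):
    """Best two-segment piecewise-constant fit of an intensity trace.

    All split points are tried exhaustively (least squares).  The step is
    accepted iff the drop (level_before - level_after) is positive and at
    least ``accept_sd`` pooled standard deviations; otherwise None.
    A noiseless step (pooled SD = 0) is accepted whenever the drop is
    positive.  Returns (step_frame, level_before, level_after) or None.
    """
    values = np.asarray(trace.values if hasattr(trace, "values") else trace,
                        dtype=np.float64)
    n = len(values)
    if n < 10:
        raise ValueError("need at least 10 frames for step detection")
    best = None
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values ** 2)])
    for s in range(min_segment, n - min_segment + 1):
        n1, n2 = s, n - s
        s1, s2 = csum[s], csum[n] - csum[s]
        q1, q2 = csq[s], csq[n] - csq[s]
        sse = (q1 - s1 ** 2 / n1) + (q2 - s2 ** 2 / n2)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, s, s1 / n1, s2 / n2)
    sse, s, before, after = best
    n1, n2 = s, n - s
    pooled_var = sse / (n1 + n2 - 2)
    pooled_sd = np.sqrt(max(pooled_var, 0.0))
    drop = before - after
    if drop <= 0:
        return None
    if pooled_sd == 0.0 or drop / pooled_sd >= accept_sd:
        return (s, before, after)
    return None


def compute_snr(trace, step) -> float:
    """(S - B) / sigma_S from a trace with a detected photobleach step.

    S and sigma_S (sample SD, ddof=1) are computed over frames before the
    step, B over the frames after it.  Returns NaN (with a warning) when
    the pre-bleach variance is zero.
    """
    if step is None:
        raise ValueError("compute_snr requires a detected photobleach step")
    step_frame = step[0] if isinstance(step, (tuple, list)) else int(step)
    values = np.asarray(trace.values if hasattr(trace, "values") else trace,
                        dtype=np.float64)
    n = len(values)
    if step_frame < 5 or n - step_frame < 5:
        raise ValueError("need at least 5 frames on each side of the step")
    pre, post = values[:step_frame], values[step_frame:]
    sigma_s = pre.std(ddof=1)
    if sigma_s == 0.0:
        warnings.warn("zero pre-bleach variance: SNR undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((pre.mean() - post.mean()) / sigma_s)


def spot_metrics(image: np.ndarray, stack=None, *,
                 psf_sigma_px: float = 1.3, min_separation_px: float = 5.0,
                 threshold_k: float = 5.0) -> list[SpotRecord]:
    """Detect spots on ``image`` and attach SBR (and SNR when a stack of
    raw frames is supplied and a photobleach step is found)."""
    centers = detect_spots(image, min_separation_px=min_separation_px,
                           threshold_k=threshold_k, psf_sigma_px=psf_sigma_px)
    records = []
    for i, c in enumerate(centers):
        others = centers[:i] + centers[i + 1:]
        try:
            rec = compute_sbr(image, c, others)
        except ValueError:
            rec = SpotRecord(center=c, excluded=True, reason="ROI at border")
        if stack is not None and not rec.excluded:
            try:
                tr = extract_trace(stack, c)
                step = detect_bleach_step(tr)
                if step is not None and step[0] >= 5 and len(tr.values) - step[0] >= 5:
                    rec.snr = compute_snr(tr, step)
            except ValueError:
                pass
        records.append(rec)
    return records
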