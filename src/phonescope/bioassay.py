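"""Digital bioassay caller for the DNA-origami RNA sensor.

Each ~600 nm sensor carries three always-available control DNA-PAINT
sites (one end site plus an adjacent central pair) and one target site at
the far end that only becomes active when the target RNA is captured in a
sandwich hybridization.  Counting the resolvable spots of each
super-resolved sensor therefore digitizes the assay: a sensor showing the
control pattern means "target absent", one extra spot means "target
detected", anything else is rejected as malformed.

Spot counting is template-driven: the expected spot pattern of each
instrument mode is derived by merging the designed site positions at the
mode's resolvability radius (half the super-resolved site FWHM).  With
the default geometry the smartphone mode resolves 2 control spots
(central pair merged with the near end at its own scale) and 3 when the
target site is on; a mode that resolves the central pair expects 3 and 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from statsmodels.stats.proportion import proportion_confint

from .presets import SITE_FWHM_NM
from .metrology import align_cluster

LABEL_CONTROL = "control"
LABEL_DETECTED = "detected"
LABEL_REJECT = "reject"

#: collinear site coordinates (nm) along the sensor axis
DEFAULT_CONTROL_SITES = (-300.0, -10.0, 10.0)
DEFAULT_TARGET_SITE = 300.0


@dataclass
class SensorGeometry:
    control_sites_nm: tuple = DEFAULT_CONTROL_SITES
    target_site_nm: float = DEFAULT_TARGET_SITE
    extent_tolerance_nm: float = 150.0

    def merged_positions(self, radius_nm: float, with_target: bool
                         ) -> np.ndarray:
        """Merge design sites closer than ``radius_nm`` (1D single link)."""
        sites = sorted(self.control_sites_nm
                       + ((self.target_site_nm,) if with_target else ()))
        groups, current = [], [sites[0]]
        for s in sites[1:]:
            if s - current[-1] <= radius_nm:
                current.append(s)
            else:
                groups.append(current)
                current = [s]
        groups.append(current)
        return np.array([np.mean(g) for g in groups])

    def template(self, radius_nm: float, with_target: bool) -> dict:
        pos = self.merged_positions(radius_nm, with_target)
        return {"n_spots": len(pos), "extent_nm": float(pos.max() - pos.min())}


@dataclass
class SensorCall:
    structure_id: int
    n_spots: int
    label: str
    spot_positions_nm: list = field(default_factory=list)
    extent_nm: float = 0.0
    instrument_mode: str = ""
    reason: str = ""


def _count_axis_spots(axis_nm: np.ndarray, radius_nm: float,
                      min_weight: float = 0.05) -> np.ndarray:
    """Resolvable spot positions along the sensor axis.

    The axis coordinates are histogrammed at radius/4 and smoothed with a
    Gaussian kernel of sigma = radius/2 (the mode's resolvability scale);
    peaks separated by at least the radius with height >= 20% of the
    maximum and a fractional weight >= ``min_weight`` count as spots.
    """
    bin_nm = radius_nm / 4.0
    lo = axis_nm.min() - 4 * radius_nm
    hi = axis_nm.max() + 4 * radius_nm
    n_bins = int(np.ceil((hi - lo) / bin_nm))
    counts, edges = np.histogram(axis_nm, bins=n_bins, range=(lo, lo + n_bins * bin_nm))
    density = gaussian_filter1d(counts.astype(float), sigma=radius_nm / 2.0 / bin_nm)
    if density.max() <= 0:
        return np.array([])
    peaks, props = find_peaks(density, height=0.2 * density.max(),
                              distance=max(int(radius_nm / bin_nm), 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    positions = []
    for p in peaks:
        # fractional localization weight within one radius of the peak
        w = ((axis_nm > centers[p] - radius_nm)
             & (axis_nm < centers[p] + radius_nm)).mean()
        if w >= min_weight:
            positions.append(centers[p])
    return np.asarray(positions)


def classify_sensor(cluster_xy: np.ndarray, instrument_mode: str,
                    geometry: SensorGeometry | None = None,
                    structure_id: int = -1,
                    merge_radius_nm: float | None = None) -> SensorCall:
    """Call one sensor cluster as control / detected / reject.

    The cluster's localizations are projected onto their principal axis
    and the resolvable spots counted at the mode's resolution scale
    (merge radius = super-resolved site FWHM / 2 by default).  The spot
    count and end-to-end extent must match the geometry's control or
    detected template (extent within ``extent_tolerance_nm``); everything
    else is rejected.
    """
    geometry = geometry or SensorGeometry()
    if merge_radius_nm is None:
        merge_radius_nm = SITE_FWHM_NM[instrument_mode] / 2.0
    xy = np.asarray(cluster_xy, dtype=float).reshape(-1, 2)
    if len(xy) < 10:
        return SensorCall(structure_id=structure_id, n_spots=0,
                          label=LABEL_REJECT, instrument_mode=instrument_mode,
                          reason="too few localizations")
    aligned, _, _ = align_cluster(xy)
    positions = _count_axis_spots(aligned[:, 0], merge_radius_nm)
    n_spots = len(positions)
    extent = float(positions.max() - positions.min()) if n_spots >= 2 else 0.0

    for with_target, label in ((False, LABEL_CONTROL), (True, LABEL_DETECTED)):
        tpl = geometry.template(merge_radius_nm, with_target)
        if (n_spots == tpl["n_spots"]
                and abs(extent - tpl["extent_nm"]) <= geometry.extent_tolerance_nm):
            return SensorCall(structure_id=structure_id, n_spots=n_spots,
                              label=label,
                              spot_positions_nm=sorted(positions.tolist()),
                              extent_nm=extent,
                              instrument_mode=instrument_mode)
    return SensorCall(structure_id=structure_id, n_spots=n_spots,
                      label=LABEL_REJECT,
                      spot_positions_nm=sorted(positions.tolist()),
                      extent_nm=extent, instrument_mode=instrument_mode,
                      reason="spot count / extent outside both templates")


def detection_fraction(calls: list[SensorCall],
                       alpha: float = 0.05) -> dict:
    """Fraction of non-rejected sensors that captured the target.

    Returns the point estimate, its Wilson score interval, and the call
    counts (rejected sensors are excluded from the denominator but
    reported).
    """
    n_det = sum(1 for c in calls if c.label == LABEL_DETECTED)
    n_ctl = sum(1 for c in calls if c.label == LABEL_CONTROL)
    n_rej = sum(1 for c in calls if c.label == LABEL_REJECT)
    n = n_det + n_ctl
    if n == 0:
        raise ValueError("all sensors were rejected; no fraction to report")
    lo, hi = proportion_confint(n_det, n, alpha=alpha, method="wilson")
    return {"fraction": n_det / n, "ci_low": float(lo), "ci_high": float(hi),
            "n_detected": n_det, "n_control": n_ctl, "n_rejected": n_rej}
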