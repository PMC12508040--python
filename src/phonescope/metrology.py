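"""Super-resolution rendering and quantitative metrology.

Covers the measurement chain applied to DNA-origami nanorulers: 2D
histogram rendering, density-based grouping of per-structure
localizations, principal-axis alignment and averaging, the shared-sigma
double-Gaussian fit that yields the inter-site distance and the
super-resolved FWHM (= 2.35 sigma), diffraction-limited PSF width fits,
the resolution-gain ratio, nearest-neighbor (NeNa) localization
precision, and the imager dwell-time estimator from linked
consecutive-frame localizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .locfit import LocalizationTable
from .simcam import FWHM_PER_SIGMA


@dataclass
class DoubleGaussianFit:
    """Shared-sigma two-Gaussian fit of a 1D localization histogram."""

    mu1: float
    mu2: float
    amp1: float
    amp2: float
    sigma_shared: float
    rss: float

    def __post_init__(self):
        if self.sigma_shared <= 0:
            raise ValueError("sigma_shared must be > 0")

    @property
    def distance(self) -> float:
        return abs(self.mu2 - self.mu1)

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_shared


@dataclass
class RenderedImage:
    """2D localization-count histogram with half-open square bins."""

    counts: np.ndarray      # (rows = y, cols = x)
    bin_size_nm: float
    origin_nm: tuple[float, float]  # (x0, y0) of bin [0, 0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _as_xy(table) -> np.ndarray:
    if isinstance(table, LocalizationTable):
        return table.xy()
    return np.asarray(table, dtype=float).reshape(-1, 2)


def render_histogram(table, bin_size_nm: float) -> RenderedImage:
    """Histogram localizations into square bins [k*b, (k+1)*b) anchored at
    the bounding-box minimum; the total count equals the number rendered."""
    if bin_size_nm <= 0:
        raise ValueError("bin_size_nm must be > 0")
    xy = _as_xy(table)
    if len(xy) == 0:
        return RenderedImage(counts=np.zeros((0, 0)), bin_size_nm=bin_size_nm,
                             origin_nm=(0.0, 0.0))
    x0, y0 = xy.min(axis=0)
    ix = np.floor((xy[:, 0] - x0) / bin_size_nm).astype(int)
    iy = np.floor((xy[:, 1] - y0) / bin_size_nm).astype(int)
    counts = np.zeros((iy.max() + 1, ix.max() + 1))
    np.add.at(counts, (iy, ix), 1.0)
    return RenderedImage(counts=counts, bin_size_nm=bin_size_nm,
                         origin_nm=(float(x0), float(y0)))


def cluster_structures(table, eps_nm: float, min_pts: int = 10
                       ) -> list[np.ndarray]:
    """Single-linkage density clustering of localizations.

    Two localizations are linked when within ``eps_nm``; a cluster is a
    connected component with at least ``min_pts`` members, everything else
    is noise.  Returns index arrays into the table's rows, ordered by
    descending cluster size.
    """
    if eps_nm <= 0:
        raise ValueError("eps_nm must be > 0")
    xy = _as_xy(table)
    n = len(xy)
    if n == 0:
        return []
    tree = cKDTree(xy)
    pairs = tree.query_pairs(eps_nm, output_type="ndarray")
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [np.nonzero(labels == c)[0] for c in range(n_comp)]
    clusters = [c for c in clusters if len(c) >= min_pts]
    clusters.sort(key=len, reverse=True)
    return clusters


def align_cluster(xy: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Center a cluster and rotate its principal axis onto +x.

    The 180-degree ambiguity is resolved by putting the brighter lobe
    (more localizations) at +x; exact ties are left unflipped.  Returns
    (rotated coords, axis angle in radians, degenerate flag); a degenerate
    (isotropic) cluster keeps the +x axis.
    """
    centered = xy - xy.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(np.isclose(evals[0], evals[1]))
    axis = evecs[:, np.argmax(evals)] if not degenerate else np.array([1.0, 0.0])
    angle = float(np.arctan2(axis[1], axis[0]))
    rot = np.array([[np.cos(-angle), -np.sin(-angle)],
                    [np.sin(-angle), np.cos(-angle)]])
    rotated = centered @ rot.T
    n_pos = int((rotated[:, 0] > 0).sum())
    n_neg = int((rotated[:, 0] < 0).sum())
    if n_neg > n_pos:
        rotated = -rotated
        angle += np.pi
    return rotated, angle, degenerate


def align_and_average(clusters: list[np.ndarray], table,
                      bin_size_nm: float = 25.0
                      ) -> tuple[RenderedImage, list[float], np.ndarray]:
    """Average structures: center, rotate onto the principal axis, pool.

    Returns the rendered average image, the per-cluster axis angle and the
    pooled axis-aligned coordinates (useful for 1D profile fits).
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    xy = _as_xy(table)
    pooled, angles = [], []
    for idx in clusters:
        rotated, angle, _ = align_cluster(xy[idx])
        pooled.append(rotated)
        angles.append(angle)
    pooled = np.vstack(pooled)
    return render_histogram(pooled, bin_size_nm), angles, pooled


def _double_gauss(x, a1, mu1, a2, mu2, sigma):
    return (a1 * np.exp(-0.5 * ((x - mu1) / sigma) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / sigma) ** 2))


def axis_profile_fit(data, bin_size_nm: float,
                     min_mode_separation_nm: float | None = None
                     ) -> DoubleGaussianFit:
    """Fit a 1D localization histogram with two shared-sigma Gaussians.

    ``data`` is either a 1D array of axis coordinates (nm) or a
    RenderedImage (collapsed along y).  Initialization places the two
    means at the two highest histogram bins separated by at least
    ``min_mode_separation_nm`` (default 3 bins); a quartile-based start is
    also tried and the best residual sum of squares wins.
    """
    if isinstance(data, RenderedImage):
        profile = data.counts.sum(axis=0)
        centers = (data.origin_nm[0]
                   + (np.arange(profile.size) + 0.5) * data.bin_size_nm)
    else:
        coords = np.asarray(data, dtype=float).ravel()
        if coords.size < 10:
            raise ValueError("too few localizations for a profile fit")
        lo, hi = coords.min(), coords.max()
        n_bins = max(int(np.ceil((hi - lo) / bin_size_nm)), 4)
        profile, edges = np.histogram(coords, bins=n_bins, range=(lo, lo + n_bins * bin_size_nm))
        centers = 0.5 * (edges[:-1] + edges[1:])
    profile = profile.astype(float)
    if min_mode_separation_nm is None:
        min_mode_separation_nm = 3 * bin_size_nm

    i1 = int(np.argmax(profile))
    far = np.abs(centers - centers[i1]) >= min_mode_separation_nm
    if far.any():
        masked = np.where(far, profile, -np.inf)
        i2 = int(np.argmax(masked))
    else:
        i2 = i1
    span = max(centers[-1] - centers[0], bin_size_nm)
    starts = [
        (profile[i1], centers[i1], max(profile[i2], 1.0), centers[i2], span / 6),
        (profile.max(), np.percentile(centers, 25), profile.max(),
         np.percentile(centers, 75), span / 6),
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _double_gauss, centers, profile, p0=p0,
                bounds=([0, centers[0] - span, 0, centers[0] - span, 1e-6],
                        [np.inf, centers[-1] + span, np.inf,
                         centers[-1] + span, span]),
                maxfev=20000)
        except RuntimeError:
            continue
        rss = float(((profile - _double_gauss(centers, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("double-Gaussian fit did not converge")
    (a1, mu1, a2, mu2, sigma), rss = best
    if mu1 > mu2:
        mu1, mu2, a1, a2 = mu2, mu1, a2, a1
    return DoubleGaussianFit(mu1=float(mu1), mu2=float(mu2), amp1=float(a1),
                             amp2=float(a2), sigma_shared=float(sigma),
                             rss=rss)


def fit_psf_fwhm(image: np.ndarray, center: tuple[float, float] | None = None,
                 pixel_size_nm: float = 1.0) -> dict:
    """Least-squares symmetric 2D Gaussian fit of a diffraction-limited
    spot; returns FWHM = 2.35 sigma and the 1/e^2 radius omega = 2 sigma,
    both in nm.  The model is pixel-integrated, so the recovered sigma is
    free of pixelation broadening."""
    from scipy.special import ndtr

    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    r_edges = np.arange(h + 1, dtype=float)
    c_edges = np.arange(w + 1, dtype=float)
    if center is None:
        center = np.unravel_index(np.argmax(image), image.shape)

    def model(_, amp, r0, c0, sigma, offset):
        ey = np.diff(ndtr((r_edges - r0 - 0.5) / sigma))
        ex = np.diff(ndtr((c_edges - c0 - 0.5) / sigma))
        peak = 1.0 / (2.0 * np.pi * sigma ** 2)
        return (offset + amp * np.outer(ey, ex) / peak).ravel()

    amp0 = image.max() - np.median(image)
    p0 = [max(amp0, 1e-6), center[0], center[1], max(min(h, w) / 6, 1.0),
          np.median(image)]
    try:
        popt, _ = optimize.curve_fit(model, None, image.ravel(), p0=p0,
                                     maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError("PSF fit did not converge") from err
    sigma_nm = abs(popt[3]) * pixel_size_nm
    return {"fwhm_nm": FWHM_PER_SIGMA * sigma_nm, "omega_nm": 2.0 * sigma_nm,
            "sigma_nm": sigma_nm, "center": (float(popt[1]), float(popt[2]))}


def resolution_gain(psf_fwhm_nm: float, site_fwhm_nm: float) -> float:
    """Ratio of diffraction-limited to super-resolved FWHM, to 2 s.f."""
    if psf_fwhm_nm <= 0 or site_fwhm_nm <= 0:
        raise ValueError("FWHM inputs must be > 0")
    return float(f"{psf_fwhm_nm / site_fwhm_nm:.2g}")


def _nena_model(d, a, sigma, b):
    return a * d / (2 * sigma ** 2) * np.exp(-d ** 2 / (4 * sigma ** 2)) + b * d


def nena_precision(table, cap_nm: float = 1000.0,
                   bin_nm: float | None = None) -> float:
    """Localization precision from first-neighbor distances on consecutive
    frames.

    For each localization in frame f the nearest neighbor in frame f+1
    (within ``cap_nm``) contributes a distance; the histogram is fitted
    with the same-molecule re-localization density
    p(d) = d/(2 sigma^2) exp(-d^2 / (4 sigma^2)) plus a linear background
    term for unrelated neighbors.  Returns sigma in nm.
    """
    if isinstance(table, LocalizationTable):
        df = table.df
    else:
        df = table
    dists = []
    frames = df["frame"].to_numpy(int)
    xy = df[["x_nm", "y_nm"]].to_numpy(float)
    order = np.unique(frames)
    by_frame = {f: xy[frames == f] for f in order}
    for f in order:
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        tree = cKDTree(nxt)
        d, _ = tree.query(by_frame[f], k=1, distance_upper_bound=cap_nm)
        dists.extend(d[np.isfinite(d)])
    dists = np.asarray(dists)
    if len(dists) < 10:
        raise ValueError("too few consecutive-frame neighbor pairs for NeNa")
    if np.percentile(dists, 90) < 1e-9:
        return 0.0
    if bin_nm is None:
        bin_nm = max(np.percentile(dists, 50) / 10.0, 1e-3)
    n_bins = max(int(np.ceil(dists.max() / bin_nm)), 10)
    counts, edges = np.histogram(dists, bins=n_bins,
                                 range=(0.0, n_bins * bin_nm))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma0 = np.percentile(dists, 40) / 1.18  # Rayleigh-mode scale guess
    popt, _ = optimize.curve_fit(
        _nena_model, centers, counts.astype(float),
        p0=[counts.sum() * bin_nm, max(sigma0, bin_nm), 0.0],
        bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000)
    return float(popt[1])


def link_binding_events(table, link_radius_nm: float = 500.0) -> list[int]:
    """Group localizations of the same site over consecutive frames.

    Returns the duration (in frames) of every linked event.  An event ends
    on the first frame without a localization within ``link_radius_nm``.
    """
    if isinstance(table, LocalizationTable):
        df = table.df
    else:
        df = table
    frames = df["frame"].to_numpy(int)
    xy = df[["x_nm", "y_nm"]].to_numpy(float)
    order = np.unique(frames)
    active: list[dict] = []
    durations: list[int] = []
    for f in order:
        pts = xy[frames == f]
        still, expired = [], []
        for ev in active:
            (still if ev["last"] == f - 1 else expired).append(ev)
        durations.extend(ev["n"] for ev in expired)
        pairs = []
        for ei, ev in enumerate(still):
            d = np.hypot(pts[:, 0] - ev["xy"][0], pts[:, 1] - ev["xy"][1])
            for pi in np.nonzero(d <= link_radius_nm)[0]:
                pairs.append((d[pi], ei, int(pi)))
        used_e, used_p = set(), set()
        for d, ei, pi in sorted(pairs):
            if ei in used_e or pi in used_p:
                continue
            ev = still[ei]
            ev["n"] += 1
            ev["xy"] = pts[pi]
            ev["last"] = int(f)
            used_e.add(ei)
            used_p.add(pi)
        survivors = [ev for ei, ev in enumerate(still) if ei in used_e]
        durations.extend(ev["n"] for ei, ev in enumerate(still)
                         if ei not in used_e)
        for pi in range(len(pts)):
            if pi not in used_p:
                survivors.append({"n": 1, "xy": pts[pi], "last": int(f)})
        active = survivors
    durations.extend(ev["n"] for ev in active)
    return durations


def estimate_binding_time(table, link_radius_nm: float = 500.0,
                          frame_time: float | None = None) -> float:
    """Mean imager dwell time (s) from linked consecutive-frame events.

    An exponential on-time of mean tau observed on a frame grid of pitch
    dt spans K frames, where for k >= 2,

        P(K = k | K >= 2) = (1 - q) * q^(k-2),   q = exp(-dt / tau),

    i.e. a geometric law (the event straddles k-1 frame boundaries).
    One-frame events are excluded (they mix sub-frame events with the
    discretization floor) and tau is the geometric maximum-likelihood
    estimate tau = -dt / ln((kbar - 2) / (kbar - 1)).  A degenerate
    duration distribution (all events equal) is handled as the plain mean
    duration.
    """
    if frame_time is None:
        if not isinstance(table, LocalizationTable):
            raise ValueError("frame_time required for a bare DataFrame")
        frame_time = table.frame_time
    durations = np.asarray(link_binding_events(table, link_radius_nm))
    if len(durations) < 50:
        warnings.warn(f"only {len(durations)} binding events; the dwell "
                      "estimate will be noisy", RuntimeWarning, stacklevel=2)
    if len(durations) == 0:
        raise ValueError("no binding events found")
    if durations.std() == 0:
        return float(durations.mean() * frame_time)
    multi = durations[durations >= 2]
    if len(multi) == 0:
        raise ValueError("no multi-frame events; cannot correct discretization")
    kbar = float(multi.mean())
    if kbar <= 2.0:
        return float((kbar - 1.0) * frame_time)
    q = (kbar - 2.0) / (kbar - 1.0)
    return float(-frame_time / np.log(q))
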