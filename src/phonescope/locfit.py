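"""DNA-PAINT localization engine.

Per-frame candidate detection, maximum-likelihood fitting of a
pixel-integrated symmetric 2D Gaussian plus constant background under a
Poisson noise model, localization-precision estimation and filtering.

Model
-----
For an ROI pixel (i, j) (pixel p covers [p, p+1) in ROI edge
coordinates) the expected photoelectron count is

    mu_ij = N * Ex(j) * Ey(i) + b,
    Ex(j) = Phi((j+1-x)/sigma) - Phi((j-x)/sigma)        (Phi: normal CDF)

with five free parameters (x, y, N, b, sigma).  The fitter maximizes the
Poisson log-likelihood sum(k*log mu - mu) with analytic gradients.

The per-localization precision is the standard closed-form approximation
for MLE fitting of a pixelated Gaussian with background:

    sigma_a^2 = sigma^2 + a^2/12
    var(x) = sigma_a^2/N * (16/9 + 8*pi*sigma_a^2*b / (N*a^2))

with a the pixel size, N the photon count and b the background per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import ndtr

from .rawproc import ChannelStack, average_frames

TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "bg", "sigma_nm",
                 "precision_nm", "converged", "iterations"]


@dataclass
class FitResult:
    x: float            # ROI edge coordinates (pixel units)
    y: float
    photons: float
    background: float
    sigma: float        # pixels
    converged: bool
    iterations: int
    rejected: bool = False
    reason: str = ""


@dataclass
class LocalizationTable:
    """Super-resolution localization records with acquisition metadata."""

    df: pd.DataFrame
    pixel_size_nm: float
    frame_time: float
    n_frames: int = 0
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def copy_with(self, df: pd.DataFrame, op: str) -> "LocalizationTable":
        return LocalizationTable(df=df.reset_index(drop=True),
                                 pixel_size_nm=self.pixel_size_nm,
                                 frame_time=self.frame_time,
                                 n_frames=self.n_frames,
                                 provenance=self.provenance + [op])

    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(float)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pixel_size_nm: {self.pixel_size_nm}\n")
            fh.write(f"# frame_time: {self.frame_time}\n")
            fh.write(f"# n_frames: {self.n_frames}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LocalizationTable":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_meta = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
            n_meta += 1
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[n_meta:])))
        return cls(df=df, pixel_size_nm=meta.get("pixel_size_nm", 1.0),
                   frame_time=meta.get("frame_time", 1.0),
                   n_frames=int(meta.get("n_frames", 0)))


def find_candidates(image: np.ndarray, box_px: int = 7,
                    threshold_k: float = 6.0) -> list[tuple[int, int]]:
    """Local maxima above median + k*MAD; brightest-wins within a box.

    Ties are broken toward the lowest row, then lowest column.
    """
    if box_px < 5 or box_px % 2 == 0:
        raise ValueError("box_px must be odd and >= 5")
    image = np.asarray(image, dtype=np.float64)
    med = np.median(image)
    mad = np.median(np.abs(image - med))
    thr = med + threshold_k * mad
    is_max = (image == ndimage.maximum_filter(image, size=box_px)) & (image > thr)
    rows, cols = np.nonzero(is_max)
    if len(rows) == 0:
        return []
    order = np.lexsort((cols, rows, -image[rows, cols]))
    kept: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all(max(abs(r - rk), abs(c - ck)) >= box_px for rk, ck in kept):
            kept.append((r, c))
    return kept


def _model_terms(params, rows_edges, cols_edges):
    x, y, n, b, sigma = params
    phix = ndtr((cols_edges - x) / sigma)
    phiy = ndtr((rows_edges - y) / sigma)
    ex = np.diff(phix)
    ey = np.diff(phiy)
    mu = n * np.outer(ey, ex) + b
    return mu, ex, ey


def fit_gaussian_mle(roi: np.ndarray, init: dict | None = None,
                     max_iter: int = 100) -> FitResult:
    """Poisson MLE of one emitter in a square ROI of photoelectron counts.

    ``roi`` must be non-negative (floor baseline-subtracted data at 0).
    Initialization defaults to the intensity-weighted centroid.  The flat
    (no-signal) case is rejected.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if roi.ndim != 2:
        raise ValueError("ROI must be 2D")
    if (roi < 0).any():
        raise ValueError("ROI must be non-negative (floor at 0 first)")
    h, w = roi.shape
    rows_edges = np.arange(h + 1, dtype=np.float64)
    cols_edges = np.arange(w + 1, dtype=np.float64)

    b0 = float(np.median(np.concatenate([roi[0], roi[-1], roi[1:-1, 0],
                                         roi[1:-1, -1]])))
    signal = np.clip(roi - b0, 0.0, None)
    n0 = float(signal.sum())
    if init:
        x0 = init.get("x", w / 2.0)
        y0 = init.get("y", h / 2.0)
        n0 = init.get("photons", n0)
        b0 = init.get("background", b0)
        s0 = init.get("sigma", 1.3)
    else:
        if n0 <= 0:
            return FitResult(x=w / 2, y=h / 2, photons=0.0, background=b0,
                             sigma=0.0, converged=False, iterations=0,
                             rejected=True, reason="flat ROI")
        rr, cc = np.mgrid[0:h, 0:w]
        x0 = float((signal * (cc + 0.5)).sum() / n0)
        y0 = float((signal * (rr + 0.5)).sum() / n0)
        s0 = 1.3
    if n0 <= 0:
        return FitResult(x=x0, y=y0, photons=0.0, background=b0, sigma=0.0,
                         converged=False, iterations=0, rejected=True,
                         reason="nonpositive initial photons")

    def nll_and_grad(theta):
        mu, ex, ey = _model_terms(theta, rows_edges, cols_edges)
        mu = np.clip(mu, 1e-12, None)
        resid = 1.0 - roi / mu
        x, y, n, b, sigma = theta
        ax = (cols_edges - x) / sigma
        ay = (rows_edges - y) / sigma
        phix = np.exp(-0.5 * ax ** 2) / np.sqrt(2 * np.pi)
        phiy = np.exp(-0.5 * ay ** 2) / np.sqrt(2 * np.pi)
        dex_dx = (phix[:-1] - phix[1:]) / sigma
        dey_dy = (phiy[:-1] - phiy[1:]) / sigma
        dex_ds = (ax[:-1] * phix[:-1] - ax[1:] * phix[1:]) / sigma
        dey_ds = (ay[:-1] * phiy[:-1] - ay[1:] * phiy[1:]) / sigma
        g = np.empty(5)
        g[0] = (resid * (n * np.outer(ey, dex_dx))).sum()
        g[1] = (resid * (n * np.outer(dey_dy, ex))).sum()
        g[2] = (resid * np.outer(ey, ex)).sum()
        g[3] = resid.sum()
        g[4] = (resid * n * (np.outer(ey, dex_ds) + np.outer(dey_ds, ex))).sum()
        nll = (mu - roi * np.log(mu)).sum()
        return nll, g

    bounds = [(-1.0, w + 1.0), (-1.0, h + 1.0),
              (1e-3, None), (0.0, None), (0.3, max(h, w))]
    res = optimize.minimize(
        nll_and_grad, np.array([x0, y0, max(n0, 1.0), max(b0, 0.0), s0]),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    x, y, n, b, sigma = res.x
    rejected = n <= 1e-2
    return FitResult(x=float(x), y=float(y), photons=float(n),
                     background=float(b), sigma=float(sigma),
                     converged=bool(res.success), iterations=int(res.nit),
                     rejected=rejected,
                     reason="nonpositive photons at optimum" if rejected else "")


def mortensen_precision(sigma_nm: float, pixel_nm: float, photons: float,
                        background: float) -> float:
    """Closed-form lateral localization precision (nm); see module docs."""
    if photons <= 0:
        return float("inf")
    sa2 = sigma_nm ** 2 + pixel_nm ** 2 / 12.0
    var = sa2 / photons * (16.0 / 9.0
                           + 8.0 * np.pi * sa2 * max(background, 0.0)
                           / (photons * pixel_nm ** 2))
    return float(np.sqrt(var))


def localize_stack(stack: ChannelStack, *, box_px: int = 7,
                   threshold_k: float = 6.0, pre_average_n: int = 1,
                   pixel_size_nm: float | None = None, gain: float = 1.0,
                   mosaic_pixel_nm: float | None = None) -> LocalizationTable:
    """Detect and fit single-molecule spots in every frame of a channel
    stack, returning a localization table in sample-plane nanometres.

    With ``pre_average_n`` > 1 the stack is first block-averaged (frame
    indices in the output then refer to averaged frames).  ``gain``
    (counts per photoelectron) converts counts to photoelectrons before
    the Poisson fit.  The nm mapping uses the channel pixel pitch and the
    channel's grid offset on the mosaic.
    """
    if pre_average_n > 1:
        stack = average_frames(stack, pre_average_n)
    pitch = pixel_size_nm or stack.pixel_size_nm
    if pitch is None:
        raise ValueError("pixel size unknown; pass pixel_size_nm")
    off_r, off_c = getattr(stack, "grid_offset_px", (0.0, 0.0))
    if mosaic_pixel_nm is None:
        mosaic_pixel_nm = pitch / 2.0 if getattr(stack, "channel", "mono") != "mono" else pitch
    half = box_px // 2
    frames = np.asarray(stack.frames, dtype=np.float64)
    n_frames, h, w = frames.shape
    rows = []
    for f in range(n_frames):
        img = frames[f]
        for (r, c) in find_candidates(img, box_px=box_px, threshold_k=threshold_k):
            if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
                continue
            roi = np.clip(img[r - half:r + half + 1, c - half:c + half + 1]
                          / gain, 0.0, None)
            fit = fit_gaussian_mle(roi)
            if fit.rejected or not fit.converged:
                continue
            x_px = c - half + fit.x   # channel edge coordinates
            y_px = r - half + fit.y
            x_nm = x_px * pitch + off_c * mosaic_pixel_nm
            y_nm = y_px * pitch + off_r * mosaic_pixel_nm
            sigma_nm = fit.sigma * pitch
            prec = mortensen_precision(sigma_nm, pitch, fit.photons,
                                       fit.background)
            rows.append((f, x_nm, y_nm, fit.photons, fit.background,
                         sigma_nm, prec, fit.converged, fit.iterations))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
    return LocalizationTable(
        df=df, pixel_size_nm=pitch, frame_time=stack.effective_exposure,
        n_frames=n_frames,
        provenance=list(getattr(stack, "provenance", []))
        + [f"localize_stack(box={box_px}, k={threshold_k}, "
           f"pre_average={pre_average_n})"])


def filter_localizations(table: LocalizationTable,
                         max_precision_nm: float) -> LocalizationTable:
    """Keep only localizations with precision strictly below the cutoff."""
    if max_precision_nm <= 0:
        raise ValueError("max_precision_nm must be > 0")
    df = table.df[table.df["precision_nm"] < max_precision_nm]
    return table.copy_with(df, f"filter(precision<{max_precision_nm})")


def filter_sigma(table: LocalizationTable, min_nm: float,
                 max_nm: float) -> LocalizationTable:
    """Keep localizations whose fitted PSF width lies in [min_nm, max_nm].

    Removes fit artifacts (cosmic-ray-like spikes, overlapping emitters)
    whose width is inconsistent with the instrument PSF.
    """
    df = table.df[(table.df["sigma_nm"] >= min_nm)
                  & (table.df["sigma_nm"] <= max_nm)]
    return table.copy_with(df, f"filter(sigma in [{min_nm}, {max_nm}])")
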