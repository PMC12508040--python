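# Methods

`phonescope` implements the computational chain behind direct
single-molecule fluorescence detection and DNA-PAINT super-resolution
imaging with a smartphone-camera microscope, together with a synthetic
video generator that makes every stage of the chain testable without
instrument data. This note records the models, the parameter choices and
their rationale, the numerical decisions, and the limits of what the
synthetic benchmarks demonstrate.

## Forward model (simcam)

A field of view contains point emitters of three kinds:

* **docking sites** — DNA-PAINT binding sites. They blink: on-times are
  exponential with mean `mean_dwell` (default 1.05 s, the measured mean
  dwell of the 12-nt fluorogenic imager with its 3-bp mismatch), and
  waiting times between events are exponential with rate `event_rate`
  per site (default 0.05 s⁻¹, a typical per-site event rate at ~10 nM
  imager). Each binding event is placed uniformly on a disc of diameter
  `site_extent` (28 nm for origami docking sites) around the site.
* **fixed dyes** — on from t = 0 until a single exponential
  photobleaching step (mean 30 s at the default excitation level), then
  off forever. Used for the 2LS single-molecule standards.
* **fiducials** — gold-nanoparticle-like markers: always on, never
  bleach, bright (30 000 photons/s by default vs 8 000 photons/s for a
  single dye).

Expected photons per frame are flux × (overlap of the on-interval with
the frame), so partial frames at the edges of a binding event carry
proportionally fewer photons — the feature that makes dwell-time
estimation on a frame grid non-trivial.

Photons are spread over pixels with a pixel-integrated symmetric
Gaussian PSF, σ = FWHM / 2.35 (the 2.35 conversion is fixed
package-wide). Presets: FWHM 1.3 µm for the smartphone objective,
0.27 µm for the research-grade microscope. No aberrations, no
astigmatism, no vectorial effects.

The camera applies a Bayer color filter (RGGB by default) with
per-channel relative sensitivities for the simulated emission color.
For a green-emitting dye behind the 550 nm long-pass filter the preset
is G = 1.0, R = 0.45, B = 0.0 — chosen to reproduce the *ordering* of
channel contrast (green best, red weaker, blue blocked), not fitted to
any measurement. A uniform background photon rate (default 50
photons/px/s in the benchmarks) models residual scattered light and
autofluorescence; its spectrum is broadband (R = G = 1, B = 0), which is
what makes the green channel's signal-to-background ratio exceed the red
channel's in simulation, as observed on real sensors. Per pixel:
photoelectrons ~ Poisson(expectation × sensitivity), then
counts = gain × electrons + baseline + Gaussian read noise, rounded and
clipped to the bit depth. With noise disabled the renderer returns the
exact expectation in floating point, which makes photon conservation
testable to the PSF-truncation tolerance (stamps reach 5σ; < 10⁻⁵ of
the flux is lost).

Camera presets are plausible for the devices involved rather than
calibrated: smartphone telephoto sensor — 430 nm/px on the sample plane
(a 1.3 µm spot then spans ~3 sensor pixels, the recommended sampling),
16-bit container, baseline 512 counts, read noise 6 counts, gain
1.8 counts/e⁻, 250 ms frames; research-grade sCMOS — 108 nm/px,
baseline 100, read noise 3.2 counts, gain 2.0, 100 ms frames.

Stage drift is linear velocity plus an optional per-frame random walk.
The `desk_drift` preset moves 3.5 µm/hour (diagonal) with a
1 nm/√frame walk — the drift scale of a portable instrument standing on
an office desk. The exported ground-truth trajectory is exactly the
linear term plus the random-walk partial sums, so drift estimators can
be scored without ambiguity.

Layout presets: `2LS` (one fixed dye, optionally a second 22 nm away),
`8HB` (two docking sites 256 nm apart — the nanoruler), and
`dimer_sensor` (collinear sites at −300/−10/+10/+300 nm: three control
sites, of which the central pair is deliberately unresolvable, plus a
target site present with probability `target_occupancy`). The ~600 nm
dimer length is the design figure; the exact central-pair gap (20 nm)
is an approximation of the sensor drawing and is configurable.

## Preprocessing (rawproc)

Baseline subtraction uses a scalar or the temporal mean of a dark
stack; results are signed and never clipped, because the detectability
metrics are difference-based. Bayer splitting returns quarter-resolution
R/B subsamples and G as the *mean* of the two green subsamples, so all
channels share one intensity scale; `G+R` is the pixelwise channel sum.
Each channel records where its effective sample sits on the mosaic (the
quincunx green average lands exactly on the 2×2 block center; R and B
are offset by half a mosaic pixel), and the localization engine applies
that offset in the nm conversion.

Hot-pixel removal replaces pixels deviating from their 3×3 neighborhood
median by more than k (default 5) robust standard deviations, where the
scale is 1.4826 × MAD floored at the frame's global robust σ — the
floor is required because a 9-sample MAD is noisy enough to produce ~1%
false replacements on pure Gaussian noise at k = 5.

Frame averaging (non-overlapping blocks, trailing partial block
dropped) and frame summation track an `effective_exposure` so that,
e.g., summing five 250 ms frames is explicitly a 1.25 s virtual
exposure, the convention used before computing spot contrast.

## Detectability metrics (smtrace)

SBR (Weber contrast) = (S − B)/B with S the mean of a 6×6 px inner ROI
and B the mean of the 28-pixel ring completing the concentric 8×8 px
ROI. The ROI is anchored so that its center is the detected centroid
rounded to the half-pixel grid (a 6×6 block has no central pixel).
Spots whose 8×8 ROI overlaps another detected spot's are excluded.

SNR = (S − B)/σ_S from a raw, un-averaged circular-ROI (6 px diameter,
pixel-center inclusion) intensity trace: S and σ_S (sample SD) over the
frames before the photobleach step, B the mean after it — the
post-bleach trace *is* the local background. Step detection is the
exhaustive least-squares two-segment fit; a step is accepted when the
drop is positive and ≥ 2 pooled standard deviations (the acceptance
threshold is a package decision; step detection quality is validated
against simulation truth). Both metrics are invariant under pure gain
rescaling.

## Localization (locfit)

Candidates are local maxima above median + k·MAD within non-overlapping
boxes (brightest wins; ties toward the top-left). Each candidate ROI is
fitted by maximum likelihood under Poisson noise with a five-parameter
model — position (x, y), photons N, background b per pixel, shared
width σ — using the pixel-integrated Gaussian. The optimizer is L-BFGS-B
on the negative log-likelihood with analytic gradients; equivalence
with an exhaustive likelihood grid search (0.005 px grid) is asserted
in the test suite, so the optimizer is interchangeable as long as that
contract holds. Flat ROIs and fits collapsing to zero photons are
rejected.

The per-localization precision is the closed-form MLE approximation for
a pixelated Gaussian with background:

    σ_a² = σ² + a²/12
    var(x) = σ_a²/N · (16/9 + 8π σ_a² b / (N a²))

with a the pixel size. The empirical scatter of repeated fits matches
this estimate within 25% in the tests.

A precision filter (`filter_localizations`, strict `<`) reproduces the
31 nm cutoff used on research-grade data; the smartphone benchmarks do
not precision-filter by default (smartphone precisions are several-fold
larger) but instead drop fits whose σ is outside [0.5, 2] × the
instrument PSF σ, which removes double-emitter and noise artifacts
without biasing positions.

With 3-frame pre-averaging (the smartphone operating point) the Poisson
likelihood is applied to averaged counts; this is the same
approximation the real pipeline makes and does not bias positions.

## Drift correction (driftcorr)

Fiducial tracks are built by greedy frame-to-frame nearest-neighbor
linking (gaps up to 5 frames); fragments split by a stray localization
are stitched when temporally adjacent and spatially consistent. Tracks
present in ≥ 80% of frames and spanning ≥ 90% of the acquisition are
fiducials — transient binders (~1 s dwell) can never qualify. The drift
trajectory is the across-track mean displacement, gap-interpolated and
smoothed with a centered **local-linear** (Savitzky-Golay, order 1)
filter of width 50 frames. A plain moving average was rejected because
its endpoint bias on a linear drift (~v·w/4) alone would exceed the 5%
endpoint accuracy demonstrated in the benchmarks; the local-linear
smoother is exact for linear drift everywhere, including the trace
ends. Corrected tables mask a 500 nm radius around each (un-drifted)
fiducial center before metrology.

## Metrology

Rendering is a 2D localization-count histogram on half-open square bins
anchored at the table's bounding-box minimum (default bin 25 nm for the
smartphone, 10 nm for the research-grade mode). Structures are grouped
by single-linkage density clustering (ε = 300 nm, ≥ 50 localizations
for nanorulers) and quality-controlled by their major-axis extent
(150–500 nm for the 256 nm ruler). Each cluster is centered, rotated so
its principal axis lies on +x (the brighter lobe resolves the 180°
ambiguity; ties are left unflipped), and the pooled axis coordinates
are fitted with two Gaussians of shared σ. The fit reports the
inter-site distance |μ₂ − μ₁| and FWHM = 2.35σ — the quantity used for
the resolution-gain ratio (PSF FWHM / site FWHM, reported to two
significant figures).

NeNa precision: nearest-neighbor distances between consecutive frames
(1 µm cap), histogram fitted with the same-molecule re-localization
density d/(2σ²)·exp(−d²/4σ²) plus a *linear* background term for
unrelated neighbors. The multi-term correction of the original
estimator is not implemented; with nonspecific localizations injected
the estimate correctly inflates (direction, not magnitude, is the
contract).

Dwell-time estimation: localizations are linked into binding events
across consecutive frames (500 nm radius). An exponential on-time of
mean τ starting uniformly within a frame spans K frames with
P(K = k | K ≥ 2) = (1 − q)q^(k−2), q = exp(−Δ/τ) — a geometric law.
One-frame events are excluded (they mix sub-frame events with the
discretization floor) and τ̂ = −Δ/ln((k̄ − 2)/(k̄ − 1)) is the geometric
MLE, an exact censoring correction under the model. A degenerate
duration distribution (all events identical) falls back to the plain
mean duration. Residual bias sources — edge frames whose partial-
overlap signal falls below the detection threshold, and consecutive
events merged across a sub-frame gap — are at the few-hundredths-of-a-
second level at the default settings and are covered by the 3-standard-
error tolerance of the recovery benchmark.

## Bioassay calling

A sensor cluster is projected onto its principal axis and its
resolvable spots are counted as peaks of the axis density smoothed at
the instrument's resolvability scale (kernel σ = super-resolved site
FWHM/2: ≈ 99 nm smartphone, ≈ 28 nm research grade). Plain
single-linkage sub-clustering at that radius was rejected: at
smartphone precision (σ ≈ 84 nm) the localization clouds of sites
290 nm apart chain through their overlapping tails essentially always,
whereas the smoothed-density peak count is stable.

Classification is template-driven: the expected spot count *and*
end-to-end extent for "control" (target absent) and "detected" (target
captured) are derived from the geometry config by merging design sites
within the resolvability radius. With the default geometry the
smartphone mode expects 2 vs 3 spots (extents ≈ 300 vs 600 nm) and the
research-grade mode likewise 2 vs 3, because the central control pair
(20 nm) is below even its resolution; a geometry with the central pair
≥ ~60 nm apart yields the 3-vs-4-spot signature seen on research-grade
instruments. A fixed absolute length gate was rejected because a
target-absent sensor's *active* sites span only ~310 nm of the 600 nm
frame; the gate is instead ±150 nm around the matched template's
extent. Anything matching neither template is rejected and excluded
from (but reported next to) the detection fraction, which carries a
Wilson 95% score interval.

## Benchmark problem sizes

The seeded end-to-end benchmarks (`phonescope.workflows`, also run by
`scripts/acceptance.py`) are reduced-scale versions of a real
acquisition, sized so a full run takes minutes on one core:

* nanoruler distance: 20 nanorulers + 3 fiducials in a 41×41 µm field,
  ~5 300 binding events over ~2 900 s (≈ 11 600 raw frames at 250 ms,
  3-frame pre-averaged), desk drift on; recovers 256 nm within a few nm.
* dwell time: 196 isolated docking sites at a low per-site event rate
  (0.02 s⁻¹, so consecutive events at a site are almost never separated
  by less than a frame), ~2 300 events at 250 ms frames, no
  pre-averaging; recovers 1.05 s within three standard errors.
* drift: 3 fiducials, one frame per 10 s for one hour under
  `desk_drift`; recovers the ~3.5 µm endpoint within ~1%.

## What the synthetic benchmarks do and do not show

The generator reproduces the features the analysis depends on — Bayer
mosaics with channel-dependent sensitivity, shot + read noise, blinking
kinetics with frame-overlap photometry, bleaching, drift, fiducials —
under idealized conditions: uniform illumination (the real instrument's
elliptical TIR excitation profile is not modelled), a symmetric
Gaussian PSF, spatially uniform and temporally constant background, no
sensor nonuniformity (PRNU/DSNU), no hot-pixel population unless
injected, and no nonspecific binding unless injected. Passing the
benchmarks therefore demonstrates the *correctness of the estimators
under their stated models*, not instrument-level performance figures:
measured quantities such as real-sample SBR/SNR medians, measured
distances and precisions, colocalization yields or assay fractions
depend on optics, buffers and sample quality, and are not claimed by
these simulations.

## Numerical choices and degenerate inputs

* FWHM/σ = 2.35 everywhere, by definition in `DoubleGaussianFit` and
  the optics model.
* Candidate/spot tie-breaks: brightest first, then smallest row, then
  smallest column — deterministic outputs for identical inputs.
* MLE convergence: L-BFGS-B, ftol 1e−12, gtol 1e−9, ≤ 100 iterations;
  non-converged fits are flagged and dropped by the stack localizer.
* Double-Gaussian fit: multi-start (two highest separated bins, then a
  quartile start), best RSS wins; failure of both starts raises.
* NeNa on a zero-noise table returns exactly 0 (below bin resolution);
  fewer than 10 neighbor pairs raises.
* Empty inputs: empty layouts, frames and tables flow through as empty
  outputs wherever a sensible empty exists; operations whose result
  would be undefined (drift with no tracks, SNR without a step, B ≤ 0
  in SBR) raise or flag instead of guessing.
* All randomness flows through `numpy.random.Generator`; compound
  workflows split seeds with `SeedSequence.spawn`, and identical seeds
  give bit-identical stacks, tables and results.
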