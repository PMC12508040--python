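# phonescope

Analysis toolkit for **single-molecule fluorescence microscopy with
smartphone cameras**: raw Bayer-video preprocessing, single-molecule
detectability metrics, DNA-PAINT super-resolution localization with
fiducial drift correction, DNA-origami nanoruler metrology, and a
digital bioassay caller — plus a synthetic smartphone-video generator
with full ground truth, so the entire chain is verifiable without
instrument data.

It is written for microscopists and assay developers working with
low-cost or phone-based single-molecule setups, and for anyone who
needs a fully seeded, ground-truthed sandbox for SMLM analysis code.

## The problem and the models

A phone camera behind a low-NA objective can detect single fluorophores
directly, but everything downstream is quantitative bookkeeping:

* **Weber contrast / SBR** of a spot in one image:
  `SBR = (S − B)/B`, with `S` the mean of a 6×6 px inner ROI and `B`
  the mean of the 28-px ring completing a concentric 8×8 px ROI.
* **SNR** from an intensity trace: `SNR = (S − B)/σ_S`, where `S`, `σ_S`
  are the mean and SD of the trace before the single photobleach step
  and `B` is the post-bleach level.
* **Localization** by Poisson maximum likelihood of a pixel-integrated
  Gaussian, `μ_ij = N·Ex(j)·Ey(i) + b`, five free parameters
  `(x, y, N, b, σ)`, with the closed-form precision
  `var(x) = σ_a²/N · (16/9 + 8π σ_a² b /(N a²))`, `σ_a² = σ² + a²/12`.
* **Nanoruler metrology**: per-structure localizations are aligned on
  their principal axis, pooled, and fitted with two shared-σ Gaussians;
  the fit reports the inter-site distance `|μ₂ − μ₁|` and
  `FWHM = 2.35 σ`, from which the resolution gain is
  `FWHM_PSF / FWHM_site`.
* **Dwell times** of transient DNA-PAINT binding: an exponential
  on-time observed on a frame grid of pitch Δ spans K frames with
  `P(K = k | K ≥ 2) = (1 − q) q^(k−2)`, `q = e^(−Δ/τ)`; the estimator is
  the geometric MLE `τ̂ = −Δ / ln((k̄−2)/(k̄−1))`.
* **Digital bioassay**: each ~600 nm origami sensor shows its control
  spot pattern (target absent) or one extra spot (target RNA captured);
  the detection fraction carries a Wilson 95% interval.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Simulate a small smartphone-preset DNA-PAINT acquisition of 256 nm
nanorulers, localize it, and measure the site distance:

```python
from phonescope import simcam, presets, rawproc, locfit, metrology

camera = presets.camera("smartphone")          # 430 nm/px RGGB, 250 ms
optics = presets.optics("smartphone")          # PSF FWHM 1.3 um
field = 64 * camera.pixel_size_nm

layout = simcam.make_layout("8HB", (field, field),
                            6 / (field / 1000) ** 2, seed=7)
kin = simcam.KineticsModel(event_rate=0.2)     # mean dwell 1.05 s
schedule = simcam.simulate_schedule(layout, kin, 300.0,
                                    camera.frame_time, seed=8)
sim = simcam.render_video(schedule, layout, optics, camera, seed=9,
                          background_photons_px_s=50.0)

green = rawproc.split_bayer(
    rawproc.subtract_baseline(sim.stack, camera.baseline))["G"]
table = locfit.localize_stack(green, box_px=7, threshold_k=6.0,
                              pre_average_n=3, gain=camera.gain)
table = locfit.filter_sigma(table, 275.0, 1110.0)

clusters = metrology.cluster_structures(table, eps_nm=300.0, min_pts=40)
_, _, pooled = metrology.align_and_average(clusters, table, bin_size_nm=25.0)
fit = metrology.axis_profile_fit(pooled[:, 0], bin_size_nm=25.0)
print(f"{len(table)} localizations, {len(clusters)} nanorulers")
print(f"site distance {fit.distance:.1f} nm, sigma {fit.sigma_shared:.1f} nm, "
      f"FWHM {fit.fwhm:.1f} nm")
```

prints

```
569 localizations, 4 nanorulers
site distance 249.7 nm, sigma 31.6 nm, FWHM 74.4 nm
```

i.e. at this small scale (six rulers, five minutes of video) the
pipeline recovers the 256 nm design distance to within a few
nanometres; `sigma` is the effective localization spread (precision
plus the 28 nm docking-site size), and `FWHM = 2.35σ` is the
super-resolved feature width that enters the resolution-gain ratio.

The same chain is available from the shell:

```sh
phonescope simulate --design 8HB --preset smartphone --frames 400 \
    --density 0.01 --seed 7 --out sim/
phonescope localize --stack sim/stack.tif --channel G --gain 1.8 \
    --pre-average 3 --out locs.csv
phonescope distance --table locs.csv --bin 25
```

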