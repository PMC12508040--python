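"""Instrument presets for the two microscopes used throughout the package.

``smartphone``: a phone telephoto camera behind a low-NA objective.  The
PSF FWHM is 1.3 µm and the sample-plane pixel pitch 430 nm, so a
diffraction-limited spot covers about 3 x 3 sensor pixels.  Frames are
250 ms, the sensor is an RGGB Bayer mosaic, and a 550 nm long-pass
emission filter blocks the blue channel.

``high_end``: a research-grade widefield microscope with a monochrome
sCMOS camera: PSF FWHM 0.27 µm, 108 nm pixels, 100 ms frames.

Pixel pitches on the sample plane are package assumptions (instrument
magnifications are not part of the configuration surface); both are
overridable through the model dataclasses.
"""

from __future__ import annotations

from .simcam import CameraModel, DriftModel, KineticsModel, OpticsModel

_CAMERAS = {
    "smartphone": CameraModel(
        pixel_size_nm=430.0,
        bayer_pattern="RGGB",
        baseline=512.0,
        read_noise_sd=6.0,
        gain=1.8,
        channel_sensitivity={"R": 0.45, "G": 1.0, "B": 0.0},
        bit_depth=16,
        frame_time=0.25,
    ),
    "high_end": CameraModel(
        pixel_size_nm=108.0,
        bayer_pattern="mono",
        baseline=100.0,
        read_noise_sd=3.2,
        gain=2.0,
        channel_sensitivity={"mono": 1.0},
        bit_depth=16,
        frame_time=0.10,
    ),
}

_OPTICS = {
    "smartphone": OpticsModel(psf_fwhm_nm=1300.0, name="smartphone"),
    "high_end": OpticsModel(psf_fwhm_nm=270.0, name="high_end"),
}

#: super-resolved docking-site FWHM of each instrument mode (nm); used as
#: the spot-merging scale by the bioassay caller.
SITE_FWHM_NM = {"smartphone": 197.4, "high_end": 56.4}

#: default rendering bin sizes (nm) for super-resolved histograms.
RENDER_BIN_NM = {"smartphone": 25.0, "high_end": 10.0}


def camera(name: str) -> CameraModel:
    try:
        return _CAMERAS[name]
    except KeyError:
        raise ValueError(f"unknown camera preset {name!r}") from None


def optics(name: str) -> OpticsModel:
    try:
        return _OPTICS[name]
    except KeyError:
        raise ValueError(f"unknown optics preset {name!r}") from None


def kinetics() -> KineticsModel:
    """DNA-PAINT kinetics with the fluorogenic imager: 1.05 s mean dwell."""
    return KineticsModel()


def desk_drift() -> DriftModel:
    """Slow stage drift of a portable setup on a desk: ~3.5 µm per hour."""
    v = 3500.0 / 3600.0  # nm/s
    return DriftModel(linear_velocity=(v / 2 ** 0.5, v / 2 ** 0.5),
                      random_walk_sd=1.0)
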