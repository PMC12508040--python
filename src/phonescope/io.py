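"""Reading and writing of stacks, tables and simulation sidecars.

Stacks are multi-page TIFF (one page per frame, 16-bit little-endian for
integer data); acquisition metadata travels in a YAML sidecar next to the
TIFF.  Localization tables and ground-truth tables are CSV.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simcam import MosaicStack, SimulationResult


def save_stack(path, stack: MosaicStack, extra_meta: dict | None = None) -> None:
    path = Path(path)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.floating):
        data = frames.astype(np.float32)
    else:
        data = frames.astype("<u2")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "bayer_pattern": stack.bayer_pattern,
        "frame_time": float(stack.frame_time),
        "bit_depth": int(stack.bit_depth),
        "pixel_size_nm": None if stack.pixel_size_nm is None
        else float(stack.pixel_size_nm),
        "baseline": None if stack.baseline is None else float(stack.baseline),
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_stack(path) -> MosaicStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return MosaicStack(frames=frames,
                       bayer_pattern=meta.get("bayer_pattern", "mono"),
                       frame_time=meta.get("frame_time", 1.0),
                       bit_depth=meta.get("bit_depth", 16),
                       pixel_size_nm=meta.get("pixel_size_nm"),
                       baseline=meta.get("baseline"))


def save_simulation(outdir, result: SimulationResult, models: dict,
                    seed: int | None = None) -> None:
    """Write stack TIFF + ground-truth CSV + YAML sidecar of all models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {name: asdict(model) for name, model in models.items()
              if model is not None}
    for m in params.values():
        for k, v in m.items():
            if isinstance(v, tuple):
                m[k] = list(v)
    params["seed"] = seed
    save_stack(outdir / "stack.tif", result.stack, extra_meta=params)
    result.truth.to_csv(outdir / "truth.csv", index=False)
    np.savetxt(outdir / "drift.csv",
               np.column_stack([np.arange(len(result.drift_nm)),
                                result.drift_nm]),
               delimiter=",", header="frame,dx_nm,dy_nm", comments="")
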