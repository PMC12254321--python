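"""File I/O: multi-page TIFF stacks, trajectory CSVs, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from nucphase.config import SimConfig


def write_stack(path: str | Path, frames: np.ndarray, config: SimConfig, axis: str = "T") -> None:
    """Write a (N, H, W) stack as multi-page TIFF with basic OME-ish metadata."""
    meta = {
        "axes": f"{axis}YX",
        "pixel_size_um": config.pixel_size,
        "frame_interval_s": config.frame_interval,
        "z_step_um": config.z_step,
    }
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32), metadata=meta)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path: str | Path, config: SimConfig, ground_truth: dict) -> None:
    """JSON sidecar bundling the full SimConfig with generator ground truth."""
    payload = {"config": _jsonable(config), "ground_truth": _jsonable(ground_truth)}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
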