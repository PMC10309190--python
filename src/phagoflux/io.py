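"""Reading and writing stacks and their sidecar metadata.

Stacks are stored as multi-page TIFF with axes (frame, channel, y, x);
a JSON sidecar (``<stem>.json``) carries pixel size, frame interval,
channel names and, for synthetic data, the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import GroundTruth

__all__ = ["save_stack", "load_stack", "sidecar_path"]


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def save_stack(
    path,
    stack: np.ndarray,
    *,
    pixel_size: float,
    frame_interval: float | None,
    channels: list[str],
    ground_truth: GroundTruth | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a (T, C, H, W) or (C, H, W) stack plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(stack)
    axes = "TCYX" if arr.ndim == 4 else "CYX"
    tifffile.imwrite(path, arr, metadata={"axes": axes})
    meta = {
        "pixel_size": pixel_size,
        "frame_interval": frame_interval,
        "channels": list(channels),
    }
    if extra:
        meta.update(extra)
    side = {"meta": meta}
    if ground_truth is not None:
        side["ground_truth"] = json.loads(ground_truth.to_json())
    sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def load_stack(path):
    """Load a TIFF plus sidecar -> (stack, meta dict, GroundTruth | None).

    A 3-D array is interpreted as (C, H, W) when the sidecar names that
    many channels, else as a single-channel (T, H, W) time series.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    side_file = sidecar_path(path)
    if not side_file.exists():
        raise FileNotFoundError(
            f"no metadata sidecar for {path.name}: expected {side_file.name} "
            "with pixel_size, frame_interval and channel names"
        )
    side = json.loads(side_file.read_text())
    meta = side["meta"]
    truth = None
    if "ground_truth" in side:
        gt = side["ground_truth"]
        truth = GroundTruth(gt["kind"], gt["objects"], gt.get("meta", {}))
    if arr.ndim == 3 and len(meta["channels"]) == 1:
        arr = arr[:, None]
    return arr, meta, truth
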