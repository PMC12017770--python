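"""File round-tripping: multi-page TIFF stacks, CSV traces, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import ImageStack, LineScan
from .traces import DiameterTrace, RoiTrace

__all__ = [
    "save_stack",
    "load_stack",
    "save_linescan",
    "load_linescan",
    "diameter_trace_to_csv",
    "diameter_trace_from_csv",
    "roi_trace_to_csv",
    "roi_trace_from_csv",
    "write_sidecar",
    "read_sidecar",
]


def save_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF, one page per frame; calibration in the sidecar."""
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    write_sidecar(
        Path(path).with_suffix(".json"),
        {
            "pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
            **{k: v for k, v in stack.meta.items()},
        },
    )


def load_stack(path, pixel_size: float | None = None, frame_interval: float | None = None) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = read_sidecar(sidecar)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)
    frame_interval = (
        frame_interval if frame_interval is not None else meta.get("frame_interval_s", 1.0)
    )
    return ImageStack(frames, pixel_size, frame_interval, meta)


def save_linescan(ls: LineScan, path) -> None:
    tifffile.imwrite(path, ls.lines.astype(np.float32), photometric="minisblack")
    write_sidecar(
        Path(path).with_suffix(".json"),
        {
            "pixel_size_um": ls.pixel_size,
            "line_interval_s": ls.line_interval,
            **{k: v for k, v in ls.meta.items()},
        },
    )


def load_linescan(path, pixel_size: float | None = None, line_interval: float | None = None) -> LineScan:
    lines = tifffile.imread(path)
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = read_sidecar(sidecar)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)
    line_interval = (
        line_interval if line_interval is not None else meta.get("line_interval_s", 1.0)
    )
    return LineScan(lines, line_interval, pixel_size, meta)


def diameter_trace_to_csv(trace: DiameterTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "diameter_um": trace.diameter, "valid": trace.valid.astype(int)}
    ).to_csv(path, index=False)
    write_sidecar(
        Path(path).with_suffix(".json"),
        {
            "baseline_window_s": list(trace.baseline_window),
            "stim_onset_s": trace.stim_onset,
            "stim_duration_s": trace.stim_duration,
        },
    )


def diameter_trace_from_csv(
    path,
    baseline_window: tuple[float, float] | None = None,
    stim_onset: float | None = None,
    stim_duration: float | None = None,
) -> DiameterTrace:
    df = pd.read_csv(path)
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = read_sidecar(sidecar)
    if baseline_window is None:
        baseline_window = tuple(meta["baseline_window_s"])
    if stim_onset is None:
        stim_onset = meta["stim_onset_s"]
    if stim_duration is None:
        stim_duration = meta.get("stim_duration_s", 0.0)
    valid = df["valid"].astype(bool).to_numpy() if "valid" in df else None
    return DiameterTrace(
        df["time_s"].to_numpy(),
        df["diameter_um"].to_numpy(),
        baseline_window,
        stim_onset,
        stim_duration,
        valid=valid,
    )


def roi_trace_to_csv(trace: RoiTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "value": trace.value, "valid": trace.valid_mask.astype(int)}
    ).to_csv(path, index=False)
    write_sidecar(
        Path(path).with_suffix(".json"),
        {
            "baseline_window_s": list(trace.baseline_window),
            "roi_descriptor": trace.roi_descriptor,
            **{k: v for k, v in trace.meta.items() if _is_jsonable(v)},
        },
    )


def roi_trace_from_csv(path, baseline_window: tuple[float, float] | None = None) -> RoiTrace:
    df = pd.read_csv(path)
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = read_sidecar(sidecar)
    if baseline_window is None:
        baseline_window = tuple(meta["baseline_window_s"])
    valid = df["valid"].astype(bool).to_numpy() if "valid" in df else None
    return RoiTrace(
        df["time_s"].to_numpy(),
        df["value"].to_numpy(),
        baseline_window,
        valid_mask=valid,
        roi_descriptor=meta.get("roi_descriptor", ""),
        meta=meta,
    )


def _is_jsonable(v) -> bool:
    try:
        json.dumps(v, default=_default)
        return True
    except TypeError:
        return False


def _default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_sidecar(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
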