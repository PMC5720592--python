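"""Readers and writers for trace tables, ROI specs and synthetic stacks.

Trace tables are CSV with a ``time_s`` column followed by one column per
ROI (or ``left``/``right`` for bilateral pairs); round-trips are lossless
at float64 (values are written with ``repr`` precision).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BilateralPair, DeltaFTrace, ROIMatrix, RoiSpec, Trace
from .synthetic import GroundTruth

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_pair_csv",
    "read_pair_csv",
    "write_roi_matrix_csv",
    "read_roi_matrix_csv",
    "write_ground_truth",
    "read_ground_truth",
    "read_roi_specs",
    "write_synthetic_tiff",
]

_FLOAT_FMT = "%.17g"


def write_trace_csv(trace: Trace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(path, sampling_rate: float | None = None, **meta) -> Trace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    value_cols = [c for c in df.columns if c != "time_s"]
    if len(value_cols) != 1:
        raise ValueError(f"{path}: expected exactly one value column, got {value_cols}")
    times = df["time_s"].to_numpy(float)
    rate = sampling_rate or (1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 1.0)
    return Trace(times=times, values=df[value_cols[0]].to_numpy(float),
                 sampling_rate=rate, meta=meta)


def write_pair_csv(pair: BilateralPair, path) -> None:
    df = pd.DataFrame({"time_s": pair.times, "left": pair.left.dff,
                       "right": pair.right.dff})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pair_csv(path, sampling_rate: float = 1.0, **meta) -> BilateralPair:
    df = pd.read_csv(path)
    for col in ("time_s", "left", "right"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    times = df["time_s"].to_numpy(float)
    n = times.size
    win = (0, max(1, min(10, n)))

    def mk(col):
        return DeltaFTrace(times=times, dff=df[col].to_numpy(float), baseline_f=1.0,
                           baseline_window=win, sampling_rate=sampling_rate,
                           meta={**meta, "side": col})
    return BilateralPair(left=mk("left"), right=mk("right"), meta=meta)


def write_roi_matrix_csv(mat: ROIMatrix, path) -> None:
    df = pd.DataFrame(mat.values, columns=mat.roi_labels)
    df.insert(0, "time_s", mat.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_roi_matrix_csv(path, sampling_rate: float = 1.0, **meta) -> ROIMatrix:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    labels = [c for c in df.columns if c != "time_s"]
    return ROIMatrix(times=df["time_s"].to_numpy(float),
                     values=df[labels].to_numpy(float),
                     roi_labels=labels, sampling_rate=sampling_rate, meta=meta)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "onsets": _jsonable(gt.onsets),
        "trace_end_s": gt.trace_end_s,
        "phase_freq_hz": _jsonable(gt.phase_freq_hz),
        "phase_amp": _jsonable(gt.phase_amp),
        "bilateral_offset_s": _jsonable(gt.bilateral_offset_s),
        "event_times": _jsonable(gt.event_times),
        "event_times_right": _jsonable(gt.event_times_right),
        "roi_classes": list(gt.roi_classes),
        "roi_active_phases": [list(a) for a in gt.roi_active_phases],
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        onsets=payload["onsets"],
        trace_end_s=payload["trace_end_s"],
        phase_freq_hz=payload["phase_freq_hz"],
        phase_amp=payload["phase_amp"],
        bilateral_offset_s=payload["bilateral_offset_s"],
        event_times={k: np.asarray(v) for k, v in payload["event_times"].items()},
        event_times_right={k: np.asarray(v)
                           for k, v in payload["event_times_right"].items()},
        roi_classes=payload.get("roi_classes", []),
        roi_active_phases=[tuple(a) for a in payload.get("roi_active_phases", [])],
    )


def read_roi_specs(path) -> list[RoiSpec]:
    """ROI definitions from YAML or JSON: a list of mappings with keys
    label, x0, y0, x1, y1 and optional is_background."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of ROI mappings")
    return [RoiSpec(label=d["label"], x0=int(d["x0"]), y0=int(d["y0"]),
                    x1=int(d["x1"]), y1=int(d["y1"]),
                    is_background=bool(d.get("is_background", False)))
            for d in data]


def write_synthetic_tiff(mat: ROIMatrix, path, block: int = 4,
                         background_level: float = 10.0,
                         scale: float = 100.0, offset: float = 500.0,
                         ) -> list[RoiSpec]:
    """Render an ROI ensemble as a synthetic multi-page TIFF stack.

    Each ROI becomes a ``block x block`` pixel square of uniform intensity
    ``offset + scale * value`` laid out on a dark background of constant
    ``background_level``; a background ROI strip is reserved at the top of
    the frame.  Returns the matching :class:`RoiSpec` list (including the
    background ROI) for round-trip extraction tests.
    """
    import tifffile

    n = mat.n_rois
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    gap = 2
    H = gap + block + rows * (block + gap)  # top strip reserved for background
    W = max(cols * (block + gap) + gap, block + 2 * gap)
    T = len(mat.times)

    stack = np.full((T, H, W), background_level, dtype=np.float32)
    specs = [RoiSpec("background", gap, gap, gap + block, gap + block,
                     is_background=True)]
    y0_base = gap + block + gap
    for i in range(n):
        r, c = divmod(i, cols)
        x0 = gap + c * (block + gap)
        y0 = y0_base + r * (block + gap)
        specs.append(RoiSpec(mat.roi_labels[i], x0, y0, x0 + block, y0 + block))
        vals = background_level + offset + scale * mat.values[:, i]
        stack[:, y0:y0 + block, x0:x0 + block] = vals[:, None, None].astype(np.float32)
    tifffile.imwrite(path, stack)
    return specs
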