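"""ΔF/F normalization, ROI extraction from image stacks, and resampling.

Two baseline conventions are supported, matching how neuronal and muscle
GCaMP records are normalized in this assay: neuronal traces use the mean
signal over the 5-min window preceding hormone application; muscle traces
use the mean of the first 250 frames.  An explicit index window is also
accepted.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import DeltaFTrace, RoiSpec, Trace

__all__ = [
    "DeltaFNormalizer",
    "normalize_dff",
    "extract_roi_traces",
    "resample_uniform",
]

NEURON_BASELINE_S = 300.0     # 5-min pre-stimulus window
MUSCLE_BASELINE_FRAMES = 250  # first 250 frames


class DeltaFNormalizer(BaseEstimator, TransformerMixin):
    """Transformer computing ΔF/F = (raw - F)/F with a scalar baseline F.

    Parameters
    ----------
    mode : {"neuron", "muscle", "explicit"}
        ``neuron`` averages the 5-min window ending at ``stimulus_time_s``;
        ``muscle`` averages the first 250 frames; ``explicit`` averages
        ``explicit_window`` (half-open index range).
    stimulus_time_s : float, required for ``neuron`` mode.
    explicit_window : (int, int), required for ``explicit`` mode.
    sampling_rate : float
        Used to convert the neuron-mode window to indices when ``fit``
        receives a bare array rather than a :class:`Trace`.

    Attributes
    ----------
    baseline_f_ : float
        The scalar F divided by.
    baseline_window_ : (int, int)
        The index range averaged.
    """

    def __init__(self, mode: str = "neuron", stimulus_time_s: float | None = None,
                 explicit_window: tuple[int, int] | None = None,
                 sampling_rate: float = 1.0):
        self.mode = mode
        self.stimulus_time_s = stimulus_time_s
        self.explicit_window = explicit_window
        self.sampling_rate = sampling_rate

    def _resolve_window(self, times: np.ndarray) -> tuple[int, int]:
        n = times.size
        if self.mode == "neuron":
            if self.stimulus_time_s is None:
                raise ValueError("neuron mode requires stimulus_time_s")
            lo_t = self.stimulus_time_s - NEURON_BASELINE_S
            if lo_t < times[0] - 1e-9:
                raise ValueError(
                    f"neuron mode requires >= {NEURON_BASELINE_S:.0f} s of "
                    f"pre-stimulus record (stimulus at {self.stimulus_time_s} s)"
                )
            lo = int(np.searchsorted(times, lo_t - 1e-9))
            hi = int(np.searchsorted(times, self.stimulus_time_s - 1e-9))
            if hi - lo < 2:
                raise ValueError("pre-stimulus baseline window is empty")
            return lo, hi
        if self.mode == "muscle":
            if n < MUSCLE_BASELINE_FRAMES:
                raise ValueError(
                    f"muscle mode requires >= {MUSCLE_BASELINE_FRAMES} frames, got {n}"
                )
            return 0, MUSCLE_BASELINE_FRAMES
        if self.mode == "explicit":
            if self.explicit_window is None:
                raise ValueError("explicit mode requires explicit_window")
            lo, hi = self.explicit_window
            if not (0 <= lo < hi <= n):
                raise ValueError(f"explicit_window {self.explicit_window} out of range")
            return int(lo), int(hi)
        raise ValueError(f"unknown mode {self.mode!r}")

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, np.ndarray, float, dict]:
        if isinstance(X, Trace):
            return X.times, X.values, X.sampling_rate, dict(X.meta)
        arr = np.asarray(X, dtype=float).ravel()
        return None, arr, None, {}

    def fit(self, X, y=None):
        times, values, rate, _ = self._coerce(X)
        if times is None:
            rate = self.sampling_rate
            times = np.arange(values.size) / rate
        self.baseline_window_ = self._resolve_window(times)
        lo, hi = self.baseline_window_
        f = float(np.mean(values[lo:hi]))
        if f <= 0:
            raise ValueError(f"degenerate baseline: F = {f} <= 0")
        self.baseline_f_ = f
        return self

    def transform(self, X) -> DeltaFTrace:
        times, values, rate, meta = self._coerce(X)
        if times is None:
            rate = self.sampling_rate
            times = np.arange(values.size) / rate
        f = self.baseline_f_
        return DeltaFTrace(
            times=times, dff=(values - f) / f, baseline_f=f,
            baseline_window=self.baseline_window_,
            sampling_rate=rate, meta=meta,
        )

    def fit_transform(self, X, y=None, **kwargs) -> DeltaFTrace:
        return self.fit(X).transform(X)


def normalize_dff(trace: Trace, mode: str = "neuron",
                  stimulus_time_s: float | None = None,
                  explicit_window: tuple[int, int] | None = None) -> DeltaFTrace:
    """Functional wrapper over :class:`DeltaFNormalizer`."""
    norm = DeltaFNormalizer(mode=mode, stimulus_time_s=stimulus_time_s,
                            explicit_window=explicit_window,
                            sampling_rate=trace.sampling_rate)
    return norm.fit_transform(trace)


def extract_roi_traces(stack: np.ndarray, rois: list[RoiSpec],
                       sampling_rate: float = 1.0) -> list[Trace]:
    """Background-subtracted mean-intensity traces from a T x H x W stack.

    For each non-background ROI, ``value(t)`` is the mean pixel intensity
    inside the ROI at frame t minus the mean intensity of the (single)
    background ROI at frame t.  Negative values are retained.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be T x H x W with T >= 1")
    T, H, W = stack.shape

    bg = [r for r in rois if r.is_background]
    if len(bg) != 1:
        raise ValueError(f"exactly one background ROI required, got {len(bg)}")
    for r in rois:
        if not (0 <= r.x0 < r.x1 <= W and 0 <= r.y0 < r.y1 <= H):
            raise ValueError(
                f"ROI {r.label!r} ({r.x0},{r.y0})-({r.x1},{r.y1}) out of "
                f"frame bounds {W}x{H}"
            )

    def roi_mean(r: RoiSpec) -> np.ndarray:
        return stack[:, r.y0:r.y1, r.x0:r.x1].mean(axis=(1, 2))

    bg_trace = roi_mean(bg[0])
    times = np.arange(T) / sampling_rate
    out = []
    for r in rois:
        if r.is_background:
            continue
        out.append(Trace(times=times, values=roi_mean(r) - bg_trace,
                         sampling_rate=sampling_rate, meta={"roi": r.label}))
    return out


def resample_uniform(trace: Trace, rate_hz: float = 1.0) -> Trace:
    """Linear interpolation onto a uniform grid spanning the trace.

    Passes through unchanged when the timestamps are already uniform at
    ``rate_hz`` (to float tolerance).
    """
    if len(trace) < 2:
        raise ValueError("resampling requires at least 2 samples")
    dt = 1.0 / rate_hz
    diffs = np.diff(trace.times)
    if np.allclose(diffs, dt, rtol=0, atol=1e-9):
        return trace
    n = int(np.floor((trace.times[-1] - trace.times[0]) / dt + 1e-9)) + 1
    grid = trace.times[0] + np.arange(n) * dt
    values = np.interp(grid, trace.times, trace.values)
    return Trace(times=grid, values=values, sampling_rate=rate_hz,
                 meta=dict(trace.meta))


def maybe_resample(trace: Trace, rate_hz: float | None = None,
                   jitter_tol: float = 0.01) -> Trace:
    """Resample only when timestamp jitter exceeds ``jitter_tol`` of the
    sampling interval; downstream analysis assumes a uniform grid."""
    rate = rate_hz or trace.sampling_rate
    dt = 1.0 / rate
    diffs = np.diff(trace.times)
    if diffs.size == 0 or np.max(np.abs(diffs - dt)) <= jitter_tol * dt:
        return trace
    return resample_uniform(trace, rate)
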