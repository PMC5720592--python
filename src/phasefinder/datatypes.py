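"""Core containers for calcium-trace phase analysis.

All time quantities are seconds, all fluorescence-derived quantities are
either raw arbitrary units (``Trace``) or dimensionless ΔF/F
(``DeltaFTrace`` and everything downstream).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Trace",
    "DeltaFTrace",
    "BilateralPair",
    "ROIMatrix",
    "RoiSpec",
    "PeakSet",
    "WindowConfig",
    "WindowStatSeries",
    "PhaseBounds",
    "OscillationStats",
    "FrequencyProfile",
    "PrepSummary",
    "GroupSummary",
    "NoResponseError",
]

PHASE_NAMES = ("phase1", "phase2", "transition", "late3")


class NoResponseError(RuntimeError):
    """Raised when no post-stimulus peak exists (control-like preparation)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Trace:
    """One ROI's raw fluorescence time series.

    Attributes
    ----------
    times : array of seconds, strictly increasing.
    values : raw fluorescence, arbitrary units, finite.
    sampling_rate : nominal acquisition rate in Hz (~1 Hz in the assays
        this package models).
    meta : free-form metadata (preparation id, side tag, modality).
    """

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DeltaFTrace:
    """ΔF/F-normalized trace plus the baseline it was divided by.

    ``dff = (raw - baseline_f) / baseline_f`` so the mean of ``dff`` over
    ``baseline_window`` is zero up to rounding.
    """

    times: np.ndarray
    dff: np.ndarray
    baseline_f: float
    baseline_window: tuple[int, int]
    sampling_rate: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.dff = _as_float_array(self.dff, "dff")
        if self.times.shape != self.dff.shape:
            raise ValueError("times and dff must have equal length")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= self.times.size):
            raise ValueError("baseline_window out of range")

    def __len__(self) -> int:
        return self.times.size

    def shifted(self, offset_s: float) -> "DeltaFTrace":
        return replace(self, times=self.times + offset_s)


@dataclass
class BilateralPair:
    """Left/right ΔF/F traces on a shared time grid."""

    left: DeltaFTrace
    right: DeltaFTrace
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.array_equal(self.left.times, self.right.times):
            raise ValueError("left and right traces must share a time grid")

    @property
    def times(self) -> np.ndarray:
        return self.left.times


@dataclass
class ROIMatrix:
    """T x N matrix of per-ROI ΔF/F values on a shared time base."""

    times: np.ndarray
    values: np.ndarray
    roi_labels: list[str]
    sampling_rate: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x ROI)")
        if self.values.shape[0] != self.times.size:
            raise ValueError("row count must match times")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("column count must match roi_labels")

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def global_trace(self) -> DeltaFTrace:
        """Column-sum ('global') trace, the substrate for shared phase bounds."""
        summed = self.values.sum(axis=1)
        return DeltaFTrace(
            times=self.times,
            dff=summed,
            baseline_f=1.0,
            baseline_window=(0, max(1, min(10, self.times.size))),
            sampling_rate=self.sampling_rate,
            meta={**self.meta, "roi": "global"},
        )


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular pixel ROI, 0-based half-open [x0,x1) x [y0,y1)."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int
    is_background: bool = False

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"ROI {self.label!r}: need x1 > x0 and y1 > y0")


@dataclass
class PeakSet:
    """Detected oscillation peaks of a ΔF/F trace."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peak_times = _as_float_array(self.peak_times, "peak_times")
        self.peak_amplitudes = _as_float_array(self.peak_amplitudes, "peak_amplitudes")
        if self.peak_times.shape != self.peak_amplitudes.shape:
            raise ValueError("peak_times and peak_amplitudes must have equal length")
        if self.peak_times.size >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be strictly increasing")
        if np.any(self.peak_amplitudes <= 0):
            raise ValueError("peak amplitudes must be positive")

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window configuration for peak summaries.

    ``k_sd`` is the standard-deviation multiplier of the onset thresholds
    (1 in the published procedure). Defaults tile the trace with
    non-overlapping 300-s windows, the neuronal configuration; muscle data
    use 170-s windows (see ``phasefinder.segment``).
    """

    window_s: float = 300.0
    step_s: float = 300.0
    k_sd: float = 1.0

    def __post_init__(self):
        if not (self.window_s >= self.step_s > 0):
            raise ValueError("need window_s >= step_s > 0")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")


@dataclass
class WindowStatSeries:
    """Per-window peak frequency and mean amplitude, plus forward differences."""

    window_start_times: np.ndarray
    freq: np.ndarray
    mean_amp: np.ndarray
    config: WindowConfig

    def __post_init__(self):
        self.window_start_times = _as_float_array(self.window_start_times, "window_start_times")
        self.freq = _as_float_array(self.freq, "freq")
        self.mean_amp = _as_float_array(self.mean_amp, "mean_amp")
        n = self.window_start_times.size
        if self.freq.size != n or self.mean_amp.size != n:
            raise ValueError("inconsistent lengths in WindowStatSeries")

    @property
    def dfreq(self) -> np.ndarray:
        """Forward differences freq[i+1] - freq[i]."""
        return np.diff(self.freq)

    @property
    def damp(self) -> np.ndarray:
        """Forward differences mean_amp[i+1] - mean_amp[i]."""
        return np.diff(self.mean_amp)

    def __len__(self) -> int:
        return self.window_start_times.size


@dataclass
class PhaseBounds:
    """Detected phase onsets (s) and derived durations.

    Any onset other than phase 1 may be ``None`` when its rule did not
    fire; durations involving an absent onset are ``None`` as well.
    ``trace_end_s`` closes the late-phase-3 interval.
    """

    onset_phase1: Optional[float]
    onset_phase2: Optional[float]
    onset_phase3: Optional[float]
    onset_late3: Optional[float]
    trace_end_s: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        onsets = [t for t in (self.onset_phase1, self.onset_phase2,
                              self.onset_phase3, self.onset_late3) if t is not None]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"onsets must be strictly increasing, got {onsets}")

    def _dur(self, a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None:
            return None
        return b - a

    @property
    def duration_phase1(self) -> Optional[float]:
        return self._dur(self.onset_phase1, self.onset_phase2)

    @property
    def duration_phase2(self) -> Optional[float]:
        return self._dur(self.onset_phase2, self.onset_phase3)

    @property
    def duration_transition(self) -> Optional[float]:
        return self._dur(self.onset_phase3, self.onset_late3)

    @property
    def duration_late3(self) -> Optional[float]:
        return self._dur(self.onset_late3, self.trace_end_s)

    def interval(self, phase: str) -> tuple[float, float]:
        """Time interval [start, end) of a named phase.

        For ``"phase3"`` this is the *late* uniform segment only, matching
        how per-phase frequencies are reported for Phase 3.
        """
        table = {
            "phase1": (self.onset_phase1, self.onset_phase2),
            "phase2": (self.onset_phase2, self.onset_phase3),
            "transition": (self.onset_phase3, self.onset_late3),
            "late3": (self.onset_late3, self.trace_end_s),
            "phase3": (self.onset_late3, self.trace_end_s),
        }
        if phase not in table:
            raise KeyError(f"unknown phase {phase!r}; expected one of {sorted(table)}")
        start, end = table[phase]
        if start is None or end is None:
            raise ValueError(f"phase {phase!r} is absent from these bounds")
        return float(start), float(end)

    def to_dict(self) -> dict:
        return {
            "onset_phase1_s": self.onset_phase1,
            "onset_phase2_s": self.onset_phase2,
            "onset_phase3_s": self.onset_phase3,
            "onset_late3_s": self.onset_late3,
            "trace_end_s": self.trace_end_s,
            "duration_phase1_s": self.duration_phase1,
            "duration_phase2_s": self.duration_phase2,
            "duration_transition_s": self.duration_transition,
            "duration_late3_s": self.duration_late3,
            "diagnostics": self.diagnostics,
        }


@dataclass
class OscillationStats:
    """Rhythm metrics of one interval of a bilateral pair."""

    pearson_r: Optional[float] = None
    p_value: Optional[float] = None
    n_samples: Optional[int] = None
    frequency_hz: Optional[float] = None
    cycle_count: Optional[int] = None
    epoch: Optional[tuple[float, float]] = None

    @property
    def epoch_duration_s(self) -> Optional[float]:
        if self.epoch is None:
            return None
        return self.epoch[1] - self.epoch[0]


@dataclass
class FrequencyProfile:
    """Per-ROI 3-phase frequency vectors plus the global trace's own profile.

    ``frequencies`` is an (N, 3) array ordered (phase1, phase2, late
    phase 3); entries are NaN where the phase was absent or the ROI could
    not be profiled.
    """

    roi_labels: list[str]
    frequencies: np.ndarray
    global_frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.global_frequencies = np.asarray(self.global_frequencies, dtype=float)
        if self.frequencies.shape != (len(self.roi_labels), 3):
            raise ValueError("frequencies must be (n_rois, 3)")
        if self.global_frequencies.shape != (3,):
            raise ValueError("global_frequencies must have length 3")
        with np.errstate(invalid="ignore"):
            if np.any(self.frequencies[np.isfinite(self.frequencies)] < 0):
                raise ValueError("frequencies must be non-negative")


@dataclass
class PrepSummary:
    """Per-preparation report: bounds, durations and rhythm metrics."""

    prep_id: str
    bounds: Optional[PhaseBounds]
    phase_durations_min: dict
    phase_frequencies_hz: dict
    phase_pearson: dict
    no_response: bool = False
    provenance: dict = field(default_factory=dict)


@dataclass
class GroupSummary:
    """Group-level mean +/- SD per phase and optional two-group comparison."""

    n: int
    duration_mean_min: dict
    duration_sd_min: dict
    frequency_mean_hz: dict
    frequency_sd_hz: dict
    pearson_mean: dict
    pearson_sd: dict
    comparison: Optional[dict] = None
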