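"""The four phase-onset rules and their composition.

The detector works on peak statistics in sliding windows:

* **Phase 1** starts at the first peak after stimulus (hormone) addition.
* **Phase 2** starts at the first window pair whose forward difference in
  mean peak amplitude exceeds mean + k_sd·SD of the per-window mean
  amplitudes (the sudden amplitude increase).
* **Phase 3** starts where peak frequency decrements moving forward in
  time; it is found by scanning windows in reverse from the end of the
  trace and stopping at the first (i.e. latest) positive reverse
  difference.  The scan is restricted to windows after the phase-2 onset,
  since pre-stimulus quiescence would otherwise trigger spurious
  decrements.
* **Late phase 3** (end of the mixed "transition period") starts at the
  first window pair after the phase-3 onset whose absolute frequency
  difference exceeds mean + k_sd·SD of the absolute frequency differences
  across all window pairs.

Onsets are assigned to the start of the *later* window of a qualifying
pair, where the change is first fully expressed.  Absent onsets are
reported as ``None``, never imputed.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import (DeltaFTrace, NoResponseError, PeakSet, PhaseBounds,
                        WindowConfig, WindowStatSeries)
from .peaks import PeakDetector, window_stats

__all__ = [
    "find_phase1_onset",
    "find_phase2_onset",
    "find_phase3_onset",
    "find_late3_onset",
    "PhaseSegmenter",
    "segment",
    "MODALITY_WINDOWS",
]

# A single window configuration is used for all neuronal data and a second
# one for muscle data, whose much larger integrated amplitudes ride on a
# slower alternation rhythm.
MODALITY_WINDOWS = {
    "neuron": WindowConfig(window_s=300.0, step_s=300.0, k_sd=1.0),
    "muscle": WindowConfig(window_s=170.0, step_s=170.0, k_sd=1.0),
}


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size >= 2 else 0.0


def find_phase1_onset(peaks: PeakSet, stimulus_time_s: float) -> float:
    """Time of the first peak strictly after the stimulus."""
    after = peaks.peak_times[peaks.peak_times > stimulus_time_s]
    if after.size == 0:
        raise NoResponseError(
            f"no peak after stimulus at {stimulus_time_s:.1f} s (no response)"
        )
    return float(after[0])


def find_phase2_onset(ws: WindowStatSeries, after: float | None = None,
                      ) -> Optional[float]:
    """First window pair whose amplitude increment exceeds mean + k·SD of
    the per-window mean amplitudes; ``None`` when no pair qualifies."""
    if len(ws) < 3:
        raise ValueError("phase-2 rule requires >= 3 windows")
    theta = float(np.mean(ws.mean_amp)) + ws.config.k_sd * _sd(ws.mean_amp)
    damp = ws.damp
    starts = ws.window_start_times
    for i in range(damp.size):
        if damp[i] > theta and (after is None or starts[i + 1] > after):
            return float(starts[i + 1])
    return None


def find_phase3_onset(ws: WindowStatSeries, after: float | None = None,
                      ) -> Optional[float]:
    """Latest (in forward time) frequency decrement, found by reverse scan.

    Scans window pairs last-to-first and returns the start of the later
    window of the first pair encountered with ``freq[i] - freq[i+1] > 0``;
    only pairs whose earlier window starts at or after ``after`` are
    considered.
    """
    if len(ws) < 3:
        raise ValueError("phase-3 rule requires >= 3 windows")
    freq = ws.freq
    starts = ws.window_start_times
    for i in range(freq.size - 2, -1, -1):
        if after is not None and starts[i] < after:
            break
        if freq[i] - freq[i + 1] > 0:
            return float(starts[i + 1])
    return None


def find_late3_onset(ws: WindowStatSeries, after: float | None = None,
                     ) -> Optional[float]:
    """First window pair at/after ``after`` whose |Δfreq| exceeds
    mean + k·SD of the |Δfreq| distribution across all window pairs."""
    if len(ws) < 3:
        raise ValueError("late-3 rule requires >= 3 windows")
    adf = np.abs(ws.dfreq)
    theta = float(np.mean(adf)) + ws.config.k_sd * _sd(adf)
    starts = ws.window_start_times
    for i in range(adf.size):
        if after is not None and starts[i] < after:
            continue
        if adf[i] > theta:
            return float(starts[i + 1])
    return None


class PhaseSegmenter(BaseEstimator):
    """Estimator running peak detection, window statistics and the four
    onset rules in order, each onset constrained to follow the previous.

    Parameters
    ----------
    stimulus_time_s : float
        Hormone/ATP application time (s).
    modality : {"neuron", "muscle"}
        Selects the window configuration when ``window_s`` is None.
    window_s, step_s, k_sd : float, optional
        Explicit window configuration overriding the modality default.
    min_prominence, min_separation_s : peak-detection parameters.

    Fitted attributes: ``peaks_``, ``window_stats_``, ``bounds_`` and the
    individual ``onset_*_`` values (seconds or None).
    """

    def __init__(self, stimulus_time_s: float = 300.0, modality: str = "neuron",
                 window_s: float | None = None, step_s: float | None = None,
                 k_sd: float = 1.0, min_prominence: float | str = "auto",
                 min_separation_s: float = 5.0):
        self.stimulus_time_s = stimulus_time_s
        self.modality = modality
        self.window_s = window_s
        self.step_s = step_s
        self.k_sd = k_sd
        self.min_prominence = min_prominence
        self.min_separation_s = min_separation_s

    def _config(self) -> WindowConfig:
        if self.window_s is not None:
            step = self.step_s if self.step_s is not None else self.window_s
            return WindowConfig(window_s=self.window_s, step_s=step, k_sd=self.k_sd)
        if self.modality not in MODALITY_WINDOWS:
            raise ValueError(f"unknown modality {self.modality!r}")
        base = MODALITY_WINDOWS[self.modality]
        return WindowConfig(window_s=base.window_s, step_s=base.step_s, k_sd=self.k_sd)

    def fit(self, X: DeltaFTrace, y=None):
        dff = X
        if not isinstance(dff, DeltaFTrace):
            raise TypeError("PhaseSegmenter.fit expects a DeltaFTrace")
        cfg = self._config()
        det = PeakDetector(min_prominence=self.min_prominence,
                           min_separation_s=self.min_separation_s)
        peaks = det.fit(dff).to_peakset()
        dt = 1.0 / dff.sampling_rate
        span = (float(dff.times[0]), float(dff.times[-1]) + dt)
        ws = window_stats(peaks, span, cfg)

        onset1 = find_phase1_onset(peaks, self.stimulus_time_s)
        onset2 = find_phase2_onset(ws, after=onset1)
        onset3 = find_phase3_onset(ws, after=onset2) if onset2 is not None else None
        onset4 = find_late3_onset(ws, after=onset3) if onset3 is not None else None

        adf = np.abs(ws.dfreq)
        diagnostics = {
            "window_s": cfg.window_s,
            "step_s": cfg.step_s,
            "k_sd": cfg.k_sd,
            "peak_threshold": peaks.detection_params.get("min_prominence"),
            "min_separation_s": self.min_separation_s,
            "amp_threshold": float(np.mean(ws.mean_amp)) + cfg.k_sd * _sd(ws.mean_amp),
            "freq_diff_threshold": (float(np.mean(adf)) + cfg.k_sd * _sd(adf)
                                    if adf.size else None),
            "n_windows": len(ws),
            "n_peaks": len(peaks),
            "amp_rule": "damp > mean(mean_amp) + k_sd*sd(mean_amp)",
            "freq_rule": "|dfreq| > mean(|dfreq|) + k_sd*sd(|dfreq|)",
        }
        self.peaks_ = peaks
        self.window_stats_ = ws
        self.onset_phase1_ = onset1
        self.onset_phase2_ = onset2
        self.onset_phase3_ = onset3
        self.onset_late3_ = onset4
        self.bounds_ = PhaseBounds(
            onset_phase1=onset1, onset_phase2=onset2, onset_phase3=onset3,
            onset_late3=onset4, trace_end_s=span[1], diagnostics=diagnostics,
        )
        return self


def segment(dff: DeltaFTrace, stimulus_time_s: float = 300.0,
            cfg: WindowConfig | None = None, modality: str = "neuron",
            min_prominence: float | str = "auto",
            min_separation_s: float = 5.0) -> PhaseBounds:
    """Run the full detector on a ΔF/F trace and return :class:`PhaseBounds`.

    Raises :class:`NoResponseError` when no post-stimulus peak exists
    (control-like preparations).
    """
    seg = PhaseSegmenter(
        stimulus_time_s=stimulus_time_s, modality=modality,
        window_s=cfg.window_s if cfg else None,
        step_s=cfg.step_s if cfg else None,
        k_sd=cfg.k_sd if cfg else 1.0,
        min_prominence=min_prominence, min_separation_s=min_separation_s,
    )
    return seg.fit(dff).bounds_
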