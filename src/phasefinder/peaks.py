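"""Peak detection and sliding-window summaries of ΔF/F traces.

These are the two primitives every phase-onset rule consumes: the set of
oscillation peaks, and per-window peak frequency / mean peak amplitude
with their consecutive-window differences.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .datatypes import DeltaFTrace, PeakSet, WindowConfig, WindowStatSeries

__all__ = ["PeakDetector", "detect_peaks", "window_stats"]


def _robust_noise_sd(x: np.ndarray) -> float:
    """Robust estimate of the per-sample noise SD from first differences.

    MAD(diff)/0.6745 estimates the SD of the differenced series; dividing
    by sqrt(2) converts back to the per-sample noise scale.
    """
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6745 / np.sqrt(2.0))


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    sm = np.convolve(padded, kernel, mode="same")
    return sm[pad:pad + x.size]


class PeakDetector(BaseEstimator):
    """Prominence-based peak detector for uniformly sampled ΔF/F traces.

    The trace is lightly smoothed (boxcar, ``smooth_samples`` wide) before
    local maxima are extracted with :func:`scipy.signal.find_peaks`; the
    prominence threshold defaults to 3x the robust per-sample noise SD
    estimated from the first-differenced raw trace.  Peak amplitude is the
    topographic prominence, which makes it invariant to baseline shifts.

    Fitted attributes: ``peak_times_``, ``peak_amplitudes_``,
    ``threshold_``.
    """

    def __init__(self, min_prominence: float | str = "auto",
                 min_separation_s: float = 5.0, smooth_samples: int = 9):
        self.min_prominence = min_prominence
        self.min_separation_s = min_separation_s
        self.smooth_samples = smooth_samples

    def fit(self, X, y=None):
        if isinstance(X, DeltaFTrace):
            times, values = X.times, X.dff
        else:
            values = np.asarray(X, dtype=float).ravel()
            times = np.arange(values.size, dtype=float)
        if values.size < 3:
            raise ValueError("peak detection requires >= 3 samples")
        dt = float(np.median(np.diff(times)))
        if not np.allclose(np.diff(times), dt, rtol=0, atol=1e-6 * dt):
            raise ValueError("peak detection requires a uniformly sampled trace")

        if self.min_prominence == "auto":
            threshold = 3.0 * _robust_noise_sd(values)
            threshold = max(threshold, np.finfo(float).eps)
        else:
            threshold = float(self.min_prominence)

        smoothed = _boxcar(values, int(self.smooth_samples))
        distance = max(1, int(round(self.min_separation_s / dt)))
        idx, props = find_peaks(smoothed, prominence=threshold, distance=distance)

        self.threshold_ = threshold
        self.peak_times_ = times[idx]
        self.peak_amplitudes_ = props["prominences"] if idx.size else np.empty(0)
        return self

    def to_peakset(self) -> PeakSet:
        return PeakSet(
            peak_times=self.peak_times_,
            peak_amplitudes=self.peak_amplitudes_,
            detection_params={
                "min_prominence": self.threshold_,
                "min_separation_s": self.min_separation_s,
                "smooth_samples": self.smooth_samples,
            },
        )


def detect_peaks(dff: DeltaFTrace, min_prominence: float | str = "auto",
                 min_separation_s: float = 5.0) -> PeakSet:
    """Detect oscillation peaks; an empty :class:`PeakSet` is a valid result."""
    det = PeakDetector(min_prominence=min_prominence,
                       min_separation_s=min_separation_s)
    return det.fit(dff).to_peakset()


def window_stats(peaks: PeakSet, span: tuple[float, float],
                 cfg: WindowConfig | None = None) -> WindowStatSeries:
    """Per-window peak frequency and mean amplitude over ``span``.

    Windows are the full-length windows ``[t0 + k*step, t0 + k*step +
    window)`` contained in ``span``; a trailing remainder shorter than one
    window is ignored.  ``freq`` is peaks-per-second in the window (a
    rate); ``mean_amp`` is the mean amplitude of those peaks, defined as 0
    for empty windows so sustained quiescence reads as an amplitude drop.
    """
    cfg = cfg or WindowConfig()
    t0, tend = span
    if tend - t0 < cfg.window_s:
        raise ValueError(
            f"span of {tend - t0:.1f} s is shorter than one window ({cfg.window_s:.1f} s)"
        )
    if peaks.peak_times.size and (
            peaks.peak_times[0] < t0 - 1e-9 or peaks.peak_times[-1] > tend + 1e-9):
        raise ValueError("span must cover all peaks")

    n_win = int(np.floor((tend - t0 - cfg.window_s) / cfg.step_s + 1e-9)) + 1
    starts = t0 + cfg.step_s * np.arange(n_win)
    freq = np.zeros(n_win)
    mean_amp = np.zeros(n_win)
    pt = peaks.peak_times
    pa = peaks.peak_amplitudes
    for i, s in enumerate(starts):
        lo = np.searchsorted(pt, s, side="left")
        hi = np.searchsorted(pt, s + cfg.window_s, side="left")
        count = hi - lo
        freq[i] = count / cfg.window_s
        mean_amp[i] = float(pa[lo:hi].mean()) if count else 0.0
    return WindowStatSeries(window_start_times=starts, freq=freq,
                            mean_amp=mean_amp, config=cfg)
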