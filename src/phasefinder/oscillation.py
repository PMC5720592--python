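"""Rhythm metrics: bilateral correlation, per-phase frequency, alternation
cycles and detection of sustained antiphase epochs.

Left-right alternation (the fictive "swinging" motor program) shows up as
negative Pearson correlation between the two sides of the midline and as
regular sign alternation of the dominance signal ``d(t) = left - right``.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats

from .datatypes import BilateralPair, OscillationStats, PeakSet, PhaseBounds

__all__ = [
    "pearson",
    "phase_frequency",
    "count_alternation_cycles",
    "detect_antiphase_epoch",
]


def _slice_interval(times: np.ndarray, interval: tuple[float, float]) -> slice:
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError(f"empty interval {interval}")
    lo = int(np.searchsorted(times, t0, side="left"))
    hi = int(np.searchsorted(times, t1, side="left"))
    return slice(lo, hi)


def pearson(pair: BilateralPair, interval: tuple[float, float] | None = None,
            ) -> tuple[float, float, int]:
    """Pearson correlation between the two sides over ``interval``.

    Implemented from the definition
    ``r = Σ(x-x̄)(y-ȳ) / sqrt(Σ(x-x̄)² Σ(y-ȳ)²)`` with a two-sided p-value
    from the t distribution with n-2 degrees of freedom.
    """
    if interval is None:
        interval = (float(pair.times[0]), float(pair.times[-1]) + 1e-9)
    sl = _slice_interval(pair.times, interval)
    x = pair.left.dff[sl]
    y = pair.right.dff[sl]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 samples in interval, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance on one side; correlation undefined")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _scipy_stats.t.sf(abs(tstat), df=n - 2))
    return r, p, n


def phase_frequency(peaks: PeakSet, bounds: PhaseBounds, phase: str) -> float:
    """Peak rate (Hz) over a phase interval: count / duration.

    For phase 3 only the uniform late segment is used (``phase="phase3"``
    maps to the late-3 interval), matching how phase-3 frequencies are
    reported.
    """
    start, end = bounds.interval(phase)
    count = int(np.sum((peaks.peak_times >= start) & (peaks.peak_times < end)))
    return count / (end - start)


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(mad / 0.6745)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad:pad + x.size]


def count_alternation_cycles(pair: BilateralPair,
                             interval: tuple[float, float] | None = None,
                             min_separation_s: float = 5.0) -> int:
    """Count full left-right alternation cycles in ``interval``.

    The dominance signal ``d = left - right`` is smoothed with a moving
    average one minimum-peak-separation long and thresholded with a
    hysteresis dead-band of 3x the (robust, pre-smoothing) noise scale, so
    noise chatter around zero is not counted.  Dominance excursions beyond
    the band form an alternating left/right state sequence; one full cycle
    is a matched pair of left- and right-dominant excursions, so the count
    is ``min(#left excursions, #right excursions)`` after collapsing
    repeats.  For a sinusoidal dominance signal with n periods this
    returns exactly n.
    """
    if interval is None:
        interval = (float(pair.times[0]), float(pair.times[-1]) + 1e-9)
    sl = _slice_interval(pair.times, interval)
    d = pair.left.dff[sl] - pair.right.dff[sl]
    if d.size < 3:
        return 0
    dt = float(np.median(np.diff(pair.times[sl]))) if d.size > 1 else 1.0
    width = max(1, int(round(min_separation_s / dt)))
    # per-sample noise scale estimated before smoothing; the moving average
    # shrinks it by sqrt(width)
    sigma = _robust_sd(np.diff(d)) / np.sqrt(2.0)
    d = _smooth(d, width)
    band = 3.0 * sigma / np.sqrt(width)

    states = []
    for v in d:
        if v > band:
            s = 1
        elif v < -band:
            s = -1
        else:
            continue
        if not states or states[-1] != s:
            states.append(s)
    n_pos = states.count(1)
    n_neg = states.count(-1)
    return min(n_pos, n_neg)


def detect_antiphase_epoch(pair: BilateralPair, expected_period_s: float = 60.0,
                           r_threshold: float = -0.2, min_cycles: int = 3,
                           step_s: float | None = None,
                           ) -> Optional[tuple[float, float]]:
    """Find the maximal sustained epoch of bilateral antiphase activity.

    A correlation window of length ``2 * expected_period_s`` slides over
    the pair; the epoch is the longest contiguous run of windows with
    windowed Pearson r below ``r_threshold``.  Epoch bounds are the
    centers of the first and last qualifying windows.  Returns ``None``
    when no run contains at least ``min_cycles`` alternation cycles.
    """
    win = 2.0 * expected_period_s
    step = step_s if step_s is not None else max(win / 6.0, 1.0)
    t0 = float(pair.times[0])
    tend = float(pair.times[-1])
    if tend - t0 < win:
        return None

    starts = np.arange(t0, tend - win + 1e-9, step)
    qualifies = np.zeros(starts.size, dtype=bool)
    for i, s in enumerate(starts):
        sl = _slice_interval(pair.times, (s, s + win))
        x = pair.left.dff[sl]
        y = pair.right.dff[sl]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        qualifies[i] = r < r_threshold

    # longest contiguous run of qualifying windows
    best_len, best_range = 0, None
    run_start = None
    for i, q in enumerate(np.append(qualifies, False)):
        if q and run_start is None:
            run_start = i
        elif not q and run_start is not None:
            if i - run_start > best_len:
                best_len, best_range = i - run_start, (run_start, i - 1)
            run_start = None
    if best_range is None:
        return None
    lo, hi = best_range
    epoch = (float(starts[lo] + win / 2), float(starts[hi] + win / 2))
    if epoch[1] <= epoch[0]:
        return None
    if count_alternation_cycles(pair, epoch) < min_cycles:
        return None
    return epoch


def oscillation_stats(pair: BilateralPair, interval: tuple[float, float],
                      peaks: PeakSet | None = None,
                      bounds: PhaseBounds | None = None,
                      phase: str | None = None) -> OscillationStats:
    """Bundle the rhythm metrics of one interval into OscillationStats."""
    r, p, n = pearson(pair, interval)
    freq = None
    if peaks is not None and bounds is not None and phase is not None:
        freq = phase_frequency(peaks, bounds, phase)
    cycles = count_alternation_cycles(pair, interval)
    return OscillationStats(pearson_r=r, p_value=p, n_samples=n,
                            frequency_hz=freq, cycle_count=cycles)
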