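"""Onset rules against brute-force oracles, plus segmentation properties."""
import dataclasses
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasefinder.datatypes import (NoResponseError, PeakSet, PhaseBounds,
                                   WindowConfig, WindowStatSeries)
from phasefinder.segment import (PhaseSegmenter, find_late3_onset,
                                 find_phase1_onset, find_phase2_onset,
                                 find_phase3_onset, segment)
from phasefinder.synthetic import make_preset, generate_trace
from phasefinder.preprocess import normalize_dff


# --------------------------------------------------------------------------
# independent rule oracles: literal exhaustive evaluation of the rule text
# --------------------------------------------------------------------------

def oracle_phase2(starts, amps, k=1.0, after=None):
    theta = statistics.mean(amps) + k * (statistics.stdev(amps) if len(amps) > 1 else 0.0)
    for i in range(len(amps) - 1):
        if amps[i + 1] - amps[i] > theta and (after is None or starts[i + 1] > after):
            return starts[i + 1]
    return None


def oracle_phase3(starts, freqs, after=None):
    qualifying = [i for i in range(len(freqs) - 1)
                  if (after is None or starts[i] >= after) and freqs[i] > freqs[i + 1]]
    return starts[max(qualifying) + 1] if qualifying else None


def oracle_late3(starts, freqs, k=1.0, after=None):
    adf = [abs(freqs[i + 1] - freqs[i]) for i in range(len(freqs) - 1)]
    theta = statistics.mean(adf) + k * (statistics.stdev(adf) if len(adf) > 1 else 0.0)
    for i in range(len(adf)):
        if (after is None or starts[i] >= after) and adf[i] > theta:
            return starts[i + 1]
    return None


def _ws(freqs, amps, step=300.0):
    n = len(freqs)
    return WindowStatSeries(
        window_start_times=step * np.arange(n),
        freq=np.asarray(freqs, float), mean_amp=np.asarray(amps, float),
        config=WindowConfig(step, step, 1.0),
    )


def _random_series(rng):
    n = int(rng.integers(3, 51))
    # piecewise-constant levels with jumps, the structure the rules scan for
    n_seg = int(rng.integers(1, 5))
    edges = np.sort(rng.choice(np.arange(1, n), size=min(n_seg - 1, n - 1),
                               replace=False)) if n_seg > 1 else []
    freq = np.zeros(n)
    amp = np.zeros(n)
    lo = 0
    for hi in list(edges) + [n]:
        freq[lo:hi] = rng.uniform(0, 0.05)
        amp[lo:hi] = rng.uniform(0, 8.0)
        lo = hi
    freq += rng.normal(0, 0.002, n)
    amp += rng.normal(0, 0.2, n)
    return _ws(np.clip(freq, 0, None), np.clip(amp, 0, None))


class TestPhase1Rule:
    def test_first_peak_after_stimulus(self):
        pk = PeakSet(peak_times=np.array([100.0, 400.0, 500.0]),
                     peak_amplitudes=np.ones(3))
        assert find_phase1_onset(pk, 300.0) == 400.0

    def test_no_post_stimulus_peak_is_no_response(self):
        pk = PeakSet(peak_times=np.array([100.0]), peak_amplitudes=np.ones(1))
        with pytest.raises(NoResponseError):
            find_phase1_onset(pk, 300.0)


class TestPhase2Rule:
    def test_constant_amplitude_gives_absent(self):
        assert find_phase2_onset(_ws([1] * 6, [2.0] * 6)) is None

    @pytest.mark.parametrize("amps", [[1, 1, 1, 5, 5, 5], [1, 1, 1, 9, 9, 9],
                                      [0, 0, 0, 9, 9, 9], [0.1, 0.1, 8, 8, 8, 8]])
    def test_hand_series_agree_with_exhaustive_rule(self, amps):
        ws = _ws([1] * len(amps), amps)
        assert find_phase2_onset(ws) == oracle_phase2(
            ws.window_start_times.tolist(), amps)


class TestPhase3Rule:
    def test_monotone_nondecreasing_freq_gives_absent(self):
        assert find_phase3_onset(_ws([1, 2, 2, 3, 5], [1] * 5)) is None

    def test_latest_decrement_wins(self):
        ws = _ws([2, 2, 5, 5, 3, 3], [1] * 6)
        # reverse scan flags the 5 -> 3 drop; onset = start of the window
        # holding the lower frequency
        assert find_phase3_onset(ws) == 1200.0
        assert find_phase3_onset(ws) == oracle_phase3(
            ws.window_start_times.tolist(), [2, 2, 5, 5, 3, 3])

    def test_restriction_skips_earlier_decrements(self):
        ws = _ws([5, 1, 1, 2, 2, 2], [1] * 6)
        # the only decrement is before `after`; restricted scan finds none
        assert find_phase3_onset(ws, after=600.0) is None
        assert find_phase3_onset(ws) == 300.0


class TestLate3Rule:
    def test_constant_freq_gives_absent(self):
        assert find_late3_onset(_ws([2] * 8, [1] * 8)) is None

    def test_single_step_change_matches_exhaustive_rule(self):
        freqs = [6, 6, 6, 1, 1, 1, 4, 4, 4]
        ws = _ws(freqs, [1] * 9)
        expected = oracle_late3(ws.window_start_times.tolist(), freqs, after=900.0)
        assert find_late3_onset(ws, after=900.0) == expected
        assert expected is not None


class TestOracleEquivalenceRandom:
    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rules_equal_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        ws = _random_series(rng)
        starts = ws.window_start_times.tolist()
        after = (None if rng.random() < 0.5
                 else float(rng.choice(ws.window_start_times)))
        assert find_phase2_onset(ws, after=after) == oracle_phase2(
            starts, ws.mean_amp.tolist(), after=after)
        assert find_phase3_onset(ws, after=after) == oracle_phase3(
            starts, ws.freq.tolist(), after=after)
        assert find_late3_onset(ws, after=after) == oracle_late3(
            starts, ws.freq.tolist(), after=after)


class TestSegment:
    def test_control_preset_reads_no_response(self, trace_cache):
        trace, _ = trace_cache("control", 1)
        dff = normalize_dff(trace, mode="neuron", stimulus_time_s=300.0)
        with pytest.raises(NoResponseError):
            segment(dff, 300.0, modality="neuron")

    def test_vnc_seed42_recovers_all_onsets_within_one_window(self, trace_cache):
        trace, gt = trace_cache("vnc_rk", 42)
        dff = normalize_dff(trace, mode="neuron", stimulus_time_s=300.0)
        b = segment(dff, 300.0, modality="neuron")
        step = 300.0
        assert abs(b.onset_phase1 - gt.onsets["phase1"]) <= step
        assert abs(b.onset_phase2 - gt.onsets["phase2"]) <= step
        assert abs(b.onset_phase3 - gt.onsets["transition"]) <= step
        assert abs(b.onset_late3 - gt.onsets["late3"]) <= step

    def test_muscle_phase2_duration_close_to_17_min(self, segmented_cache):
        _, bounds, _ = segmented_cache("muscle_24b", 1)
        assert bounds.duration_phase2 / 60.0 == pytest.approx(17.0, abs=2.0)

    def test_idempotence(self, segmented_cache):
        dff, bounds, _ = segmented_cache("vnc_rk", 1)
        again = segment(dff, 300.0, modality="neuron")
        assert again.to_dict() == bounds.to_dict()

    def test_translation_covariance(self, trace_cache):
        """Shifting trace and stimulus by T shifts every onset by exactly T."""
        trace, _ = trace_cache("vnc_rk", 1)
        dff = normalize_dff(trace, mode="neuron", stimulus_time_s=300.0)
        b0 = segment(dff, 300.0, modality="neuron")
        T = 600.0
        shifted = dataclasses.replace(dff, times=dff.times + T)
        b1 = segment(shifted, 300.0 + T, modality="neuron")
        for attr in ("onset_phase1", "onset_phase2", "onset_phase3", "onset_late3"):
            assert getattr(b1, attr) == pytest.approx(getattr(b0, attr) + T)

    def test_durations_recompute_from_onsets(self, segmented_cache):
        _, b, _ = segmented_cache("vnc_rk", 1)
        assert b.duration_phase1 == b.onset_phase2 - b.onset_phase1
        assert b.duration_phase2 == b.onset_phase3 - b.onset_phase2
        assert b.duration_transition == b.onset_late3 - b.onset_phase3
        assert b.duration_late3 == b.trace_end_s - b.onset_late3

    def test_diagnostics_record_thresholds(self, segmented_cache):
        _, b, _ = segmented_cache("vnc_rk", 1)
        for key in ("window_s", "step_s", "k_sd", "amp_threshold",
                    "freq_diff_threshold", "peak_threshold"):
            assert key in b.diagnostics

    def test_inconsistent_onsets_rejected_by_bounds(self):
        with pytest.raises(ValueError, match="increasing"):
            PhaseBounds(onset_phase1=500.0, onset_phase2=400.0,
                        onset_phase3=None, onset_late3=None, trace_end_s=1000.0)

    def test_sklearn_estimator_api(self, trace_cache):
        trace, _ = trace_cache("vnc_rk", 1)
        dff = normalize_dff(trace, mode="neuron", stimulus_time_s=300.0)
        seg = PhaseSegmenter(stimulus_time_s=300.0, modality="neuron")
        assert seg.get_params()["modality"] == "neuron"
        seg.set_params(k_sd=1.0).fit(dff)
        assert seg.onset_phase2_ == seg.bounds_.onset_phase2
        assert hasattr(seg, "window_stats_") and hasattr(seg, "peaks_")
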