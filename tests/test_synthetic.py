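"""Generator correctness: presets, determinism, event-rate bookkeeping and
bilateral coupling structure."""
import numpy as np
import pytest

from phasefinder.datatypes import BilateralPair, DeltaFTrace
from phasefinder.synthetic import (PHASE_ORDER, generate_bilateral,
                                   generate_roi_ensemble, generate_trace,
                                   make_preset)


class TestPresets:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="vnc_rk"):
            make_preset("nonesuch")

    def test_atp_epoch_is_9_minutes_with_15_cycles(self):
        spec = make_preset("atp_bilateral")
        p2 = spec.phase("phase2")
        assert p2.duration_s == 540.0
        assert p2.duration_s * p2.osc_freq_hz == pytest.approx(15.0)
        assert p2.bilateral_mode == "antiphase"

    def test_muscle_phase2_is_17_minutes_with_18_cycles(self):
        spec = make_preset("muscle_24b")
        p2 = spec.phase("phase2")
        assert p2.duration_s == 1020.0
        assert round(p2.duration_s * p2.osc_freq_hz) == 18
        assert p2.bilateral_mode == "antiphase"

    def test_vnc_preset_structure(self):
        spec = make_preset("vnc_rk")
        assert spec.total_span_s == 5400.0
        assert spec.phase("phase2").osc_freq_hz == pytest.approx(0.02)
        assert spec.phase("phase2").duration_s == 1200.0
        assert spec.phase("late3").bilateral_mode == "coincident"
        # amplitude ordering: phase 2 and late 3 dwarf phase 1
        assert spec.phase("phase2").osc_amp > 10 * spec.phase("phase1").osc_amp
        assert spec.phase("late3").osc_amp > spec.phase("phase1").osc_amp

    def test_control_has_flat_baseline_everywhere(self):
        spec = make_preset("control")
        for p in spec.phases:
            assert p.baseline_start == 0.0 and p.baseline_end == 0.0


class TestGenerateTrace:
    def test_determinism_same_seed_bit_identical(self, trace_cache):
        spec = make_preset("vnc_rk", seed=7)
        t1, g1 = generate_trace(spec)
        t2, g2 = generate_trace(spec)
        assert np.array_equal(t1.values, t2.values)
        for ph in g1.event_times:
            assert np.array_equal(g1.event_times[ph], g2.event_times[ph])

    def test_noise_free_single_phase_zero_amp_is_pure_envelope(self):
        spec = make_preset("vnc_rk", seed=0).replace(noise_sd=0.0)
        for name in PHASE_ORDER:
            spec = spec.replace_phase(name, osc_amp=0.0)
        trace, _ = generate_trace(spec)
        t = trace.times
        # inside phase 2 the envelope is the 1.5 plateau
        sel = (t >= 1000) & (t < 2000)
        assert np.allclose(trace.values[sel], spec.f0 * 2.5, atol=1e-9)
        # pre-stimulus is flat at F0 up to the tiny control-level transients
        assert np.allclose(trace.values[t < 290], spec.f0, atol=0.02 * spec.f0)

    def test_trace_length_and_span(self):
        spec = make_preset("vnc_rk")
        trace, gt = generate_trace(spec)
        assert len(trace) == int(spec.total_span_s * spec.sampling_rate)
        assert gt.trace_end_s == spec.total_span_s

    def test_event_rate_matches_osc_freq(self):
        """Emitted events per phase match osc_freq_hz via direct bookkeeping."""
        spec = make_preset("vnc_rk", seed=3).replace(noise_sd=0.0)
        _, gt = generate_trace(spec)
        onsets = spec.phase_onsets()
        for p in spec.phases:
            ev = gt.event_times[p.name]
            n_expected = np.floor(p.duration_s * p.osc_freq_hz + 1e-9)
            assert len(ev) == n_expected
            assert np.all(ev >= onsets[p.name])
            assert np.all(ev <= onsets[p.name] + p.duration_s)

    def test_phase2_mean_inter_event_interval_is_50s(self):
        spec = make_preset("vnc_rk", seed=11).replace(noise_sd=0.0)
        _, gt = generate_trace(spec)
        intervals = np.diff(gt.event_times["phase2"])
        assert np.mean(intervals) == pytest.approx(50.0, rel=0.05)


class TestGenerateBilateral:
    def test_antiphase_oscillation_components_anticorrelated(self):
        """Noise-free antiphase phase-2 left/right are strongly negative;
        with non-overlapping transients r = -m^2/Var, the analytic bound."""
        spec = make_preset("vnc_rk", seed=5).replace(noise_sd=0.0)
        spec = spec.replace_phase("phase2", amp_jitter=0.0, freq_jitter=0.0)
        pair, gt = generate_bilateral(spec)
        t = pair.times
        sel = (t >= 900) & (t < 2100)
        r = np.corrcoef(pair.left.dff[sel], pair.right.dff[sel])[0, 1]
        # duty 0.3 half-sines: m = 2A*0.3/pi, E[o^2] = A^2*0.15
        expected = -(0.6 / np.pi) ** 2 / (0.15 - (0.6 / np.pi) ** 2)
        assert r == pytest.approx(expected, abs=0.02)

    def test_coincident_zero_jitter_perfectly_correlated(self):
        spec = make_preset("vnc_rk", seed=5).replace(noise_sd=0.0)
        spec = spec.replace_phase("late3", amp_jitter=0.0)
        pair, _ = generate_bilateral(spec)
        t = pair.times
        sel = (t >= 3400) & (t < 5300)
        r = np.corrcoef(pair.left.dff[sel], pair.right.dff[sel])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_uncorrelated_mode_mean_r_near_zero(self):
        """Monte-Carlo under independence: with the shared baseline held
        flat, the uncorrelated oscillation components have mean r ~ 0."""
        rs = []
        for seed in range(30):
            spec = make_preset("vnc_rk", seed=seed).replace(noise_sd=0.02)
            spec = spec.replace_phase("phase1", baseline_start=0.0,
                                      baseline_end=0.0, osc_amp=1.0)
            pair, _ = generate_bilateral(spec)
            t = pair.times
            sel = (t >= 310) & (t < 890)
            rs.append(np.corrcoef(pair.left.dff[sel], pair.right.dff[sel])[0, 1])
        rs = np.asarray(rs)
        sem = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 3 * sem + 0.05

    def test_sides_share_time_grid_and_baseline(self, pair_cache):
        pair, _ = pair_cache("vnc_rk", 1)
        assert isinstance(pair, BilateralPair)
        assert isinstance(pair.left, DeltaFTrace)
        assert np.array_equal(pair.left.times, pair.right.times)


class TestRoiEnsemble:
    def test_global_trace_is_exact_column_sum(self):
        spec = make_preset("vnc_rk", seed=2)
        mat, _ = generate_roi_ensemble(spec, n_rois=8, fraction_baseline_class=0.5)
        assert np.array_equal(mat.global_trace().dff, mat.values.sum(axis=1))

    def test_95_rois_with_class_labels(self):
        spec = make_preset("vnc_rk", seed=4)
        mat, gt = generate_roi_ensemble(spec, n_rois=95, fraction_baseline_class=0.5)
        assert mat.values.shape[1] == 95
        assert len(gt.roi_classes) == 95
        assert set(gt.roi_classes) <= {"baseline", "oscillatory"}
        assert all(1 <= len(a) <= 3 for a in gt.roi_active_phases)

    def test_fraction_one_makes_all_baseline_class(self):
        spec = make_preset("vnc_rk", seed=4)
        _, gt = generate_roi_ensemble(spec, n_rois=6, fraction_baseline_class=1.0)
        assert gt.roi_classes == ["baseline"] * 6

    def test_ensemble_determinism(self):
        spec = make_preset("vnc_rk", seed=9)
        m1, _ = generate_roi_ensemble(spec, n_rois=5)
        m2, _ = generate_roi_ensemble(spec, n_rois=5)
        assert np.array_equal(m1.values, m2.values)

    def test_global_trace_segmentation_recovers_onsets(self, ):
        from phasefinder.segment import segment
        spec = make_preset("vnc_rk", seed=3)
        mat, gt = generate_roi_ensemble(spec, n_rois=10, fraction_baseline_class=0.4)
        b = segment(mat.global_trace(), 300.0, modality="neuron")
        assert abs(b.onset_phase2 - gt.onsets["phase2"]) <= 300.0
        assert abs(b.onset_phase3 - gt.onsets["transition"]) <= 300.0
        assert abs(b.onset_late3 - gt.onsets["late3"]) <= 300.0
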