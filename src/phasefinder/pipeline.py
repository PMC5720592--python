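"""End-to-end runs over one or many preparations and group summaries.

``run_preparation`` chains preprocessing, segmentation and rhythm metrics
for a single preparation (synthetic preset or CSV input) and produces a
serializable :class:`PrepSummary`.  ``summarize_group`` aggregates
summaries into per-phase mean ± SD and, when a second group is given,
compares per-phase frequencies with Welch t-tests under a Šidák
family-wise correction over the three phases (the standard one-way-ANOVA
contract for two groups).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats

from .datatypes import (BilateralPair, DeltaFTrace, GroupSummary, NoResponseError,
                        PeakSet, PhaseBounds, PrepSummary)
from .oscillation import pearson, phase_frequency
from .peaks import detect_peaks
from .preprocess import maybe_resample, normalize_dff
from .segment import segment
from . import synthetic as _synth
from . import io as _io

__all__ = ["run_preparation", "summarize_group", "write_prep_summary",
           "read_prep_summary"]

_DURATION_PHASES = ("phase1", "phase2", "transition", "late3")
_FREQ_PHASES = ("phase1", "phase2", "phase3")
_R_PHASES = ("phase1", "phase2", "late3")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _metrics(dff: DeltaFTrace, pair: Optional[BilateralPair],
             bounds: Optional[PhaseBounds], peaks: Optional[PeakSet]):
    durations, freqs, rs = {}, {}, {}
    if bounds is not None:
        for ph in _DURATION_PHASES:
            dur = getattr(bounds, f"duration_{ph}")
            durations[ph] = dur / 60.0 if dur is not None else None
        for ph in _FREQ_PHASES:
            try:
                freqs[ph] = phase_frequency(peaks, bounds, ph)
            except ValueError:
                freqs[ph] = None
        if pair is not None:
            for ph in _R_PHASES:
                try:
                    r, p, n = pearson(pair, bounds.interval(ph))
                    rs[ph] = {"r": r, "p": p, "n": n}
                except ValueError:
                    rs[ph] = None
    return durations, freqs, rs


def run_preparation(config: dict) -> PrepSummary:
    """Run preprocess → segment → oscillation metrics for one preparation.

    ``config`` names either a synthetic preset (``preset``, ``seed``,
    optional ``noise_sd``) or input files (``trace_csv`` or ``pair_csv``
    with ``modality`` and ``stimulus_time_s``).  Control-like runs with no
    post-stimulus peak are reported with ``no_response=True`` rather than
    raised.  Deterministic given its inputs.
    """
    config = dict(config)
    stimulus = float(config.get("stimulus_time_s", 300.0))
    pair = None
    if "preset" in config:
        spec = _synth.make_preset(config["preset"], seed=int(config.get("seed", 0)))
        if config.get("noise_sd") is not None:
            spec = spec.replace(noise_sd=float(config["noise_sd"]))
        modality = spec.modality
        stimulus = spec.stimulus_time_s
        if config.get("bilateral", True):
            pair, _ = _synth.generate_bilateral(spec)
            dff = pair.left
        else:
            trace, _ = _synth.generate_trace(spec)
            dff = normalize_dff(trace, mode=("muscle" if modality == "muscle" else "neuron"),
                                stimulus_time_s=stimulus)
        prep_id = config.get("prep_id", f"{spec.label}-seed{spec.seed}")
    elif "pair_csv" in config:
        modality = config.get("modality", "neuron")
        pair = _io.read_pair_csv(config["pair_csv"])
        dff = pair.left
        prep_id = config.get("prep_id", Path(config["pair_csv"]).stem)
    elif "trace_csv" in config:
        modality = config.get("modality", "neuron")
        trace = maybe_resample(_io.read_trace_csv(config["trace_csv"]))
        dff = normalize_dff(trace, mode=("muscle" if modality == "muscle" else "neuron"),
                            stimulus_time_s=stimulus)
        prep_id = config.get("prep_id", Path(config["trace_csv"]).stem)
    else:
        raise ValueError("config must name a 'preset', 'pair_csv' or 'trace_csv'")

    provenance = {"config_hash": _config_hash(config), "config": config,
                  "modality": modality, "stimulus_time_s": stimulus}

    try:
        bounds = segment(dff, stimulus_time_s=stimulus, modality=modality)
    except NoResponseError:
        return PrepSummary(prep_id=prep_id, bounds=None, phase_durations_min={},
                           phase_frequencies_hz={}, phase_pearson={},
                           no_response=True, provenance=provenance)
    peaks = detect_peaks(dff)
    durations, freqs, rs = _metrics(dff, pair, bounds, peaks)
    provenance["diagnostics"] = bounds.diagnostics
    return PrepSummary(prep_id=prep_id, bounds=bounds,
                       phase_durations_min=durations,
                       phase_frequencies_hz=freqs, phase_pearson=rs,
                       no_response=False, provenance=provenance)


def _mean_sd(values):
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return mean, sd


def _sidak(p: float, m: int) -> float:
    return float(1.0 - (1.0 - p) ** m)


def summarize_group(summaries: list[PrepSummary],
                    compare_to: Optional[list[PrepSummary]] = None,
                    alpha: float = 0.05) -> GroupSummary:
    """Per-phase mean ± SD of durations, frequencies and R values.

    Order-invariant in the input lists.  With ``compare_to``, per-phase
    frequencies are compared by Welch t-test with Šidák correction over
    the three phase comparisons.
    """
    responders = [s for s in summaries if not s.no_response]
    if not responders:
        raise ValueError("empty group (no responding preparations)")

    dur_mean, dur_sd, f_mean, f_sd, r_mean, r_sd = {}, {}, {}, {}, {}, {}
    for ph in _DURATION_PHASES:
        dur_mean[ph], dur_sd[ph] = _mean_sd(
            [s.phase_durations_min.get(ph) for s in responders])
    for ph in _FREQ_PHASES:
        f_mean[ph], f_sd[ph] = _mean_sd(
            [s.phase_frequencies_hz.get(ph) for s in responders])
    for ph in _R_PHASES:
        r_mean[ph], r_sd[ph] = _mean_sd(
            [(s.phase_pearson.get(ph) or {}).get("r") for s in responders])

    comparison = None
    if compare_to is not None:
        other = [s for s in compare_to if not s.no_response]
        if not other:
            raise ValueError("empty comparison group")
        comparison = {"alpha": alpha, "correction": "sidak", "phases": {}}
        m = len(_FREQ_PHASES)
        for ph in _FREQ_PHASES:
            a = [s.phase_frequencies_hz.get(ph) for s in responders]
            b = [s.phase_frequencies_hz.get(ph) for s in other]
            a = [v for v in a if v is not None]
            b = [v for v in b if v is not None]
            if len(a) < 2 or len(b) < 2:
                comparison["phases"][ph] = None
                continue
            stat, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
            p_corr = _sidak(float(p), m)
            comparison["phases"][ph] = {
                "statistic": float(stat), "p": float(p), "p_corrected": p_corr,
                "significant": bool(p_corr < alpha),
            }
    return GroupSummary(n=len(responders), duration_mean_min=dur_mean,
                        duration_sd_min=dur_sd, frequency_mean_hz=f_mean,
                        frequency_sd_hz=f_sd, pearson_mean=r_mean,
                        pearson_sd=r_sd, comparison=comparison)


def write_prep_summary(summary: PrepSummary, outdir) -> Path:
    """Serialize a PrepSummary as JSON (durations kept in both min and s)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "prep_id": summary.prep_id,
        "no_response": summary.no_response,
        "bounds": summary.bounds.to_dict() if summary.bounds else None,
        "phase_durations_min": summary.phase_durations_min,
        "phase_frequencies_hz": summary.phase_frequencies_hz,
        "phase_pearson": summary.phase_pearson,
        "provenance": summary.provenance,
    }
    path = outdir / f"{summary.prep_id}.json"
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


def read_prep_summary(path) -> PrepSummary:
    payload = json.loads(Path(path).read_text())
    bounds = None
    if payload.get("bounds"):
        b = payload["bounds"]
        bounds = PhaseBounds(
            onset_phase1=b["onset_phase1_s"], onset_phase2=b["onset_phase2_s"],
            onset_phase3=b["onset_phase3_s"], onset_late3=b["onset_late3_s"],
            trace_end_s=b["trace_end_s"], diagnostics=b.get("diagnostics", {}),
        )
    return PrepSummary(
        prep_id=payload["prep_id"], bounds=bounds,
        phase_durations_min=payload.get("phase_durations_min", {}),
        phase_frequencies_hz=payload.get("phase_frequencies_hz", {}),
        phase_pearson=payload.get("phase_pearson", {}),
        no_response=payload.get("no_response", False),
        provenance=payload.get("provenance", {}),
    )
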