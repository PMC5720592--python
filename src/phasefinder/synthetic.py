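"""Synthetic GCaMP recordings of the fictive pupal-ecdysis motor program.

The generator emulates ~90-min, ~1 Hz GCaMP6s records with the triphasic
structure seen in hormone-stimulated excised CNS preparations: a rising
baseline carrying low-amplitude/high-frequency oscillations (phase 1), a
plateau with large-amplitude bilaterally alternating oscillations
(phase 2), a declining baseline with a mixed-amplitude "transition
period", and uniform slow coincident oscillations (late phase 3).
Flat-baseline control recordings and a short ATP-stimulation record with a
single 9-min antiphase epoch are also provided as presets.

Model
-----
``raw(t) = F0 * (1 + baseline(t) + osc(t) + noise(t))``

* ``baseline`` — piecewise linear between per-phase start/end levels
  (ΔF/F units), zero before the stimulus.
* ``osc`` — a sum of half-sine transients of width ``duty/osc_freq_hz``
  (capped at ``max_width_s``); one transient per oscillation period, so
  the realized event rate equals ``osc_freq_hz`` exactly.  Event centers
  are anchored to the period grid with truncated-Gaussian jitter
  (``placement="grid"``), or placed uniformly inside period-length blocks
  (``placement="uniform"``, used for the mixed transition period).
* ``noise`` — i.i.d. Gaussian, SD ``noise_sd`` in ΔF/F units.

Every draw is a function of ``(spec, seed)`` only: identical inputs give
bit-identical outputs, including the returned :class:`GroundTruth`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datatypes import BilateralPair, DeltaFTrace, ROIMatrix, Trace

__all__ = [
    "PhaseSpec",
    "SyntheticSpec",
    "GroundTruth",
    "PRESET_NAMES",
    "make_preset",
    "generate_trace",
    "generate_bilateral",
    "generate_roi_ensemble",
    "calibrate_noise_sd",
]

PHASE_ORDER = ("phase1", "phase2", "transition", "late3")
PRESET_NAMES = ("vnc_rk", "muscle_24b", "atp_bilateral", "control")

_BILATERAL_MODES = ("antiphase", "coincident", "uncorrelated")
_PLACEMENTS = ("grid", "uniform")


@dataclass(frozen=True)
class PhaseSpec:
    """Parameterization of one activity phase.

    ``baseline_start``/``baseline_end`` are ΔF/F levels joined linearly;
    ``osc_amp`` is the mean transient peak amplitude in ΔF/F units;
    ``freq_jitter``/``amp_jitter`` are fractional coefficients of
    variation.  ``duty`` sets the transient width as a fraction of the
    oscillation period.
    """

    name: str
    duration_s: float
    baseline_start: float
    baseline_end: float
    osc_freq_hz: float
    osc_amp: float
    freq_jitter: float = 0.02
    amp_jitter: float = 0.2
    duty: float = 0.3
    max_width_s: float = 30.0
    placement: str = "grid"
    bilateral_mode: str = "coincident"

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError(f"{self.name}: duration_s must be > 0")
        if self.osc_freq_hz <= 0:
            raise ValueError(f"{self.name}: osc_freq_hz must be > 0")
        if self.osc_amp < 0 or self.freq_jitter < 0 or self.amp_jitter < 0:
            raise ValueError(f"{self.name}: amplitudes and jitters must be >= 0")
        if not 0 < self.duty <= 0.5:
            raise ValueError(f"{self.name}: duty must be in (0, 0.5]")
        if self.bilateral_mode not in _BILATERAL_MODES:
            raise ValueError(f"{self.name}: unknown bilateral_mode {self.bilateral_mode!r}")
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"{self.name}: unknown placement {self.placement!r}")

    @property
    def period_s(self) -> float:
        return 1.0 / self.osc_freq_hz

    @property
    def width_s(self) -> float:
        return min(self.duty * self.period_s, self.max_width_s)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one simulated preparation."""

    label: str
    phases: tuple[PhaseSpec, ...]
    sampling_rate: float = 1.0
    pre_stimulus_s: float = 300.0
    noise_sd: float = 0.05
    seed: int = 0
    f0: float = 1000.0
    modality: str = "neuron"

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.pre_stimulus_s <= 0:
            raise ValueError("pre_stimulus_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if len(self.phases) != len(PHASE_ORDER) or tuple(p.name for p in self.phases) != PHASE_ORDER:
            raise ValueError(f"phases must be the ordered tuple {PHASE_ORDER}")
        for p in self.phases:
            if p.osc_freq_hz >= self.sampling_rate / 2:
                raise ValueError(f"{p.name}: osc_freq_hz must be < sampling_rate/2")

    @property
    def stimulus_time_s(self) -> float:
        return self.pre_stimulus_s

    @property
    def total_span_s(self) -> float:
        return self.pre_stimulus_s + sum(p.duration_s for p in self.phases)

    def phase_onsets(self) -> dict:
        t = self.pre_stimulus_s
        onsets = {}
        for p in self.phases:
            onsets[p.name] = t
            t += p.duration_s
        return onsets

    def phase(self, name: str) -> PhaseSpec:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)

    def replace_phase(self, name: str, **kwargs) -> "SyntheticSpec":
        phases = tuple(
            dataclasses.replace(p, **kwargs) if p.name == name else p for p in self.phases
        )
        return dataclasses.replace(self, phases=phases)


@dataclass
class GroundTruth:
    """What the generator actually did — the parameter-recovery oracle."""

    onsets: dict
    trace_end_s: float
    phase_freq_hz: dict
    phase_amp: dict
    bilateral_offset_s: dict
    event_times: dict = field(default_factory=dict)
    event_times_right: dict = field(default_factory=dict)
    roi_classes: list = field(default_factory=list)
    roi_active_phases: list = field(default_factory=list)

    def __post_init__(self):
        vals = [self.onsets[k] for k in PHASE_ORDER if k in self.onsets]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("ground-truth onsets must be strictly increasing")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _control_phase(name: str, duration_s: float) -> PhaseSpec:
    """Flat baseline with slow, low-amplitude coincident oscillations."""
    return PhaseSpec(
        name=name, duration_s=duration_s,
        baseline_start=0.0, baseline_end=0.0,
        osc_freq_hz=0.01, osc_amp=0.01,
        freq_jitter=0.05, amp_jitter=0.2, duty=0.3,
        bilateral_mode="coincident",
    )


def _vnc_rk(seed: int) -> SyntheticSpec:
    # 90-min neuronal record; phase-2 rhythm at 0.02 Hz in antiphase.
    # Durations are multiples of the 300-s neuronal analysis window so the
    # window grid is commensurate with the phase structure.
    phases = (
        PhaseSpec("phase1", 600.0, 0.0, 1.5, 8 / 300.0, 0.35,
                  freq_jitter=0.05, amp_jitter=0.2, placement="uniform",
                  bilateral_mode="uncorrelated"),
        PhaseSpec("phase2", 1200.0, 1.5, 1.5, 0.02, 8.0,
                  freq_jitter=0.02, amp_jitter=0.2, bilateral_mode="antiphase"),
        PhaseSpec("transition", 1200.0, 1.5, 0.5, 1 / 300.0, 2.0,
                  freq_jitter=0.0, amp_jitter=0.6, placement="uniform",
                  bilateral_mode="uncorrelated"),
        PhaseSpec("late3", 2100.0, 0.5, 0.2, 5 / 300.0, 3.0,
                  freq_jitter=0.02, amp_jitter=0.2, bilateral_mode="coincident"),
    )
    return SyntheticSpec("vnc_rk", phases, noise_sd=0.05, seed=seed, modality="neuron")


def _muscle_24b(seed: int) -> SyntheticSpec:
    # 90-min muscle record: larger amplitudes, 18 alternation cycles over a
    # 17-min phase 2 (period 1020/18 s).  Durations are commensurate with
    # the 170-s muscle analysis window.
    phases = (
        PhaseSpec("phase1", 720.0, 0.0, 2.0, 6 / 170.0, 1.2,
                  freq_jitter=0.05, amp_jitter=0.2, placement="uniform",
                  bilateral_mode="uncorrelated"),
        PhaseSpec("phase2", 1020.0, 2.0, 2.0, 3 / 170.0, 14.0,
                  freq_jitter=0.02, amp_jitter=0.2, bilateral_mode="antiphase"),
        PhaseSpec("transition", 1020.0, 2.0, 0.8, 1 / 170.0, 4.0,
                  freq_jitter=0.0, amp_jitter=0.6, placement="uniform",
                  bilateral_mode="uncorrelated"),
        PhaseSpec("late3", 2340.0, 0.8, 0.3, 4 / 170.0, 6.0,
                  freq_jitter=0.02, amp_jitter=0.75, bilateral_mode="coincident"),
    )
    return SyntheticSpec("muscle_24b", phases, noise_sd=0.1, seed=seed, modality="muscle")


def _atp_bilateral(seed: int) -> SyntheticSpec:
    # 30-min record: a single 9-min antiphase epoch (15 alternation cycles,
    # period 36 s) on an otherwise control-like background.  duty=0.5 makes
    # left/right half-sines contiguous, i.e. a sine-like alternation.
    ctrl = _control_phase("x", 1.0)
    phases = (
        PhaseSpec("phase1", 100.0, 0.0, 0.0, ctrl.osc_freq_hz, ctrl.osc_amp,
                  freq_jitter=ctrl.freq_jitter, amp_jitter=ctrl.amp_jitter,
                  bilateral_mode="coincident"),
        PhaseSpec("phase2", 540.0, 0.0, 0.0, 15 / 540.0, 3.0,
                  freq_jitter=0.02, amp_jitter=0.1, duty=0.5,
                  bilateral_mode="antiphase"),
        PhaseSpec("transition", 430.0, 0.0, 0.0, ctrl.osc_freq_hz, ctrl.osc_amp,
                  freq_jitter=ctrl.freq_jitter, amp_jitter=ctrl.amp_jitter,
                  bilateral_mode="coincident"),
        PhaseSpec("late3", 430.0, 0.0, 0.0, ctrl.osc_freq_hz, ctrl.osc_amp,
                  freq_jitter=ctrl.freq_jitter, amp_jitter=ctrl.amp_jitter,
                  bilateral_mode="coincident"),
    )
    return SyntheticSpec("atp_bilateral", phases, noise_sd=0.05, seed=seed, modality="neuron")


def _control(seed: int) -> SyntheticSpec:
    phases = (
        _control_phase("phase1", 600.0),
        _control_phase("phase2", 1200.0),
        _control_phase("transition", 1200.0),
        _control_phase("late3", 2100.0),
    )
    return SyntheticSpec("control", phases, noise_sd=0.05, seed=seed, modality="neuron")


_PRESETS = {
    "vnc_rk": _vnc_rk,
    "muscle_24b": _muscle_24b,
    "atp_bilateral": _atp_bilateral,
    "control": _control,
}

# Documented population-level bilateral correlation targets each preset was
# designed to embody (phase -> Pearson r); used by the noise-calibration
# oracle.
PRESET_TARGET_R = {
    "vnc_rk": {"phase2": -0.30},
    "muscle_24b": {"late3": 0.57},
}


def make_preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Return a fully populated :class:`SyntheticSpec` for a named preset.

    Presets embody the study conditions: ``vnc_rk`` (neuronal 90-min record,
    0.02 Hz antiphase phase 2), ``muscle_24b`` (muscle record, 17-min
    phase 2 with 18 alternation cycles), ``atp_bilateral`` (9-min antiphase
    epoch of 15 cycles) and ``control`` (flat baseline, sub-threshold slow
    oscillations).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory(seed)


# ---------------------------------------------------------------------------
# event drawing and rendering
# ---------------------------------------------------------------------------

def _draw_centers(rng: np.random.Generator, phase: PhaseSpec, start_s: float,
                  offset_frac: float = 0.0) -> np.ndarray:
    """Event centers for one side of one phase.

    One event per oscillation period; ``offset_frac`` shifts the anchor
    grid by a fraction of the period (0.5 realizes antiphase).
    """
    T = phase.period_s
    n = int(np.floor(phase.duration_s / T + 1e-9))
    if n == 0:
        return np.empty(0)
    k = np.arange(n)
    w = phase.width_s
    if phase.placement == "uniform":
        lo = k * T + w / 2
        hi = (k + 1) * T - w / 2
        centers = rng.uniform(lo, np.maximum(hi, lo + 1e-9))
    else:
        anchors = (k + 0.5 + offset_frac) * T
        jitter_sd = phase.freq_jitter * T
        trunc = max((T - w) / 2 * 0.8, 0.0)
        jitter = np.clip(rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n),
                         -trunc, trunc)
        centers = anchors + jitter
    return start_s + np.sort(centers)


def _draw_amps(rng: np.random.Generator, phase: PhaseSpec, n: int) -> np.ndarray:
    """Log-normal amplitudes with mean osc_amp and CV amp_jitter."""
    if phase.osc_amp == 0 or n == 0:
        return np.zeros(n)
    cv = phase.amp_jitter
    if cv == 0:
        return np.full(n, phase.osc_amp)
    sigma = np.sqrt(np.log1p(cv * cv))
    amps = phase.osc_amp * rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=n)
    # transients are not arbitrarily small: floor the jitter at 15% of the
    # mean so every emitted event stays a genuine event
    return np.maximum(amps, 0.15 * phase.osc_amp)


def _render_events(t: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                   width_s: float) -> np.ndarray:
    """Sum of half-sine transients a·sin(pi·(t-c+w/2)/w) on their supports."""
    osc = np.zeros_like(t)
    half = width_s / 2
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for c, a in zip(centers, amps):
        i0 = max(0, int(np.ceil((c - half - t[0]) / dt)))
        i1 = min(t.size, int(np.floor((c + half - t[0]) / dt)) + 1)
        if i1 <= i0:
            continue
        seg = t[i0:i1]
        osc[i0:i1] += a * np.sin(np.pi * (seg - c + half) / width_s)
    return osc


def _baseline_envelope(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    env = np.zeros_like(t)
    start = spec.pre_stimulus_s
    for p in spec.phases:
        end = start + p.duration_s
        sel = (t >= start) & (t < end)
        if np.any(sel):
            frac = (t[sel] - start) / p.duration_s
            env[sel] = p.baseline_start + frac * (p.baseline_end - p.baseline_start)
        start = end
    env[t >= start] = spec.phases[-1].baseline_end
    return env


def _pre_stimulus_phase(spec: SyntheticSpec) -> PhaseSpec:
    """The pre-stimulus segment carries control-phase statistics."""
    return _control_phase("pre", spec.pre_stimulus_s)


def _side_events(rng: np.random.Generator, spec: SyntheticSpec):
    """Draw (centers, amps, width) per phase for the reference (left) side."""
    out = {}
    start = spec.pre_stimulus_s
    pre = _pre_stimulus_phase(spec)
    out["pre"] = (_draw_centers(rng, pre, 0.0), None, pre)
    out["pre"] = (out["pre"][0], _draw_amps(rng, pre, out["pre"][0].size), pre)
    for p in spec.phases:
        centers = _draw_centers(rng, p, start)
        amps = _draw_amps(rng, p, centers.size)
        out[p.name] = (centers, amps, p)
        start += p.duration_s
    return out


def _assemble(spec: SyntheticSpec, events: dict, noise: np.ndarray,
              t: np.ndarray, side: str | None) -> Trace:
    osc = np.zeros_like(t)
    for centers, amps, phase in events.values():
        osc += _render_events(t, centers, amps, phase.width_s)
    env = _baseline_envelope(spec, t)
    values = spec.f0 * (1.0 + env + osc + noise)
    meta = {"prep": spec.label, "modality": spec.modality,
            "side": side if side is not None else "none"}
    return Trace(times=t, values=values, sampling_rate=spec.sampling_rate, meta=meta)


def _ground_truth(spec: SyntheticSpec, left_events: dict,
                  right_events: dict | None = None) -> GroundTruth:
    onsets = spec.phase_onsets()
    freq = {p.name: p.osc_freq_hz for p in spec.phases}
    amp = {p.name: p.osc_amp for p in spec.phases}
    offsets = {}
    for p in spec.phases:
        if p.bilateral_mode == "antiphase":
            offsets[p.name] = p.period_s / 2
        elif p.bilateral_mode == "coincident":
            offsets[p.name] = 0.0
        else:
            offsets[p.name] = float("nan")
    return GroundTruth(
        onsets=onsets,
        trace_end_s=spec.total_span_s,
        phase_freq_hz=freq,
        phase_amp=amp,
        bilateral_offset_s=offsets,
        event_times={k: v[0].copy() for k, v in left_events.items()},
        event_times_right=(
            {k: v[0].copy() for k, v in right_events.items()} if right_events else {}
        ),
    )


def _time_grid(spec: SyntheticSpec) -> np.ndarray:
    n = int(round(spec.total_span_s * spec.sampling_rate))
    return np.arange(n) / spec.sampling_rate


def generate_trace(spec: SyntheticSpec) -> tuple[Trace, GroundTruth]:
    """Generate one raw-fluorescence trace and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec)
    events = _side_events(rng, spec)
    noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else np.zeros_like(t)
    trace = _assemble(spec, events, noise, t, side=None)
    return trace, _ground_truth(spec, events)


def generate_bilateral(spec: SyntheticSpec) -> tuple[BilateralPair, GroundTruth]:
    """Generate a left/right pair sharing the baseline envelope.

    Within each phase the right side is offset by half the oscillation
    period (``antiphase``), shares event times with independent amplitudes
    (``coincident``), or is drawn independently (``uncorrelated``).
    """
    from .preprocess import normalize_dff  # local import to avoid a cycle

    seq = np.random.SeedSequence(spec.seed)
    rng_l, rng_r, rng_n = [np.random.default_rng(s) for s in seq.spawn(3)]
    t = _time_grid(spec)

    left_events = _side_events(rng_l, spec)
    right_events = {}
    start = spec.pre_stimulus_s
    pre = _pre_stimulus_phase(spec)
    lc, la, _ = left_events["pre"]
    right_events["pre"] = (lc, _draw_amps(rng_r, pre, lc.size), pre)
    for p in spec.phases:
        lc, la, _ = left_events[p.name]
        if p.bilateral_mode == "antiphase":
            rc = _draw_centers(rng_r, p, start, offset_frac=0.5)
            ra = _draw_amps(rng_r, p, rc.size)
        elif p.bilateral_mode == "coincident":
            rc = lc.copy()
            ra = _draw_amps(rng_r, p, rc.size)
        else:  # uncorrelated
            rc = _draw_centers(rng_r, p, start)
            ra = _draw_amps(rng_r, p, rc.size)
        right_events[p.name] = (rc, ra, p)
        start += p.duration_s

    noise_l = rng_n.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else np.zeros_like(t)
    noise_r = rng_n.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else np.zeros_like(t)
    trace_l = _assemble(spec, left_events, noise_l, t, side="left")
    trace_r = _assemble(spec, right_events, noise_r, t, side="right")

    mode = "muscle" if spec.modality == "muscle" else "neuron"
    dff_l = normalize_dff(trace_l, mode=mode, stimulus_time_s=spec.stimulus_time_s)
    dff_r = normalize_dff(trace_r, mode=mode, stimulus_time_s=spec.stimulus_time_s)
    pair = BilateralPair(left=dff_l, right=dff_r, meta={"prep": spec.label})
    return pair, _ground_truth(spec, left_events, right_events)


# ---------------------------------------------------------------------------
# multi-ROI ensembles
# ---------------------------------------------------------------------------

_ROI_PHASE_GROUPS = {
    "phase1": ("phase1",),
    "phase2": ("phase2",),
    "phase3": ("transition", "late3"),
}


def generate_roi_ensemble(spec: SyntheticSpec, n_rois: int,
                          fraction_baseline_class: float = 0.5,
                          ) -> tuple[ROIMatrix, GroundTruth]:
    """Generate a T x N matrix of per-ROI ΔF/F traces.

    ROIs belong to one of two classes observed in real preparations:
    ``baseline`` ROIs carry large, slow baseline changes with no
    oscillatory events, while ``oscillatory`` ROIs carry the shared event
    schedule of their active phases on a flat baseline.  Each ROI is
    active in a seeded random subset of 1-3 of the principal phases
    (phase 1, phase 2, phase 3 = transition + late 3); oscillatory gains
    within a phase sum to 1 so the column-sum ("global") trace retains the
    spec's triphasic structure.  Per-ROI noise is ``noise_sd / sqrt(N)``
    so the pooled global trace has the spec's noise level.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if not 0 <= fraction_baseline_class <= 1:
        raise ValueError("fraction_baseline_class must be in [0, 1]")

    seq = np.random.SeedSequence(spec.seed)
    rng_ev, rng_assign, rng_noise = [np.random.default_rng(s) for s in seq.spawn(3)]
    t = _time_grid(spec)

    events = _side_events(rng_ev, spec)
    gt = _ground_truth(spec, events)

    n_baseline = int(round(fraction_baseline_class * n_rois))
    classes = ["baseline"] * n_baseline + ["oscillatory"] * (n_rois - n_baseline)

    groups = list(_ROI_PHASE_GROUPS)
    active: list[tuple[str, ...]] = []
    for _ in range(n_rois):
        k = int(rng_assign.integers(1, len(groups) + 1))
        chosen = tuple(sorted(rng_assign.choice(groups, size=k, replace=False),
                              key=groups.index))
        active.append(chosen)
    # every phase group must be covered by at least one oscillatory ROI so
    # the global trace keeps all phases
    osc_idx = [i for i, c in enumerate(classes) if c == "oscillatory"]
    if osc_idx:
        for gi, g in enumerate(groups):
            if not any(g in active[i] for i in osc_idx):
                j = osc_idx[gi % len(osc_idx)]
                active[j] = tuple(sorted(set(active[j]) | {g}, key=groups.index))

    # per-phase oscillatory gains, normalized to sum to 1
    gains = {g: np.zeros(n_rois) for g in groups}
    for g in groups:
        members = [i for i in osc_idx if g in active[i]]
        if members:
            raw = rng_assign.uniform(0.5, 1.5, size=len(members))
            raw /= raw.sum()
            for i, w in zip(members, raw):
                gains[g][i] = w

    env = _baseline_envelope(spec, t)
    base_members = [i for i, c in enumerate(classes) if c == "baseline"]
    base_gain = np.zeros(n_rois)
    if base_members:
        raw = rng_assign.uniform(0.5, 1.5, size=len(base_members))
        raw /= raw.sum()
        for i, w in zip(base_members, raw):
            base_gain[i] = w

    phase_osc = {}
    for g, names in _ROI_PHASE_GROUPS.items():
        comp = np.zeros_like(t)
        for nm in names:
            centers, amps, phase = events[nm]
            comp += _render_events(t, centers, amps, phase.width_s)
        phase_osc[g] = comp
    pre_centers, pre_amps, pre_phase = events["pre"]
    pre_osc = _render_events(t, pre_centers, pre_amps, pre_phase.width_s)

    sd = spec.noise_sd / np.sqrt(n_rois)
    values = np.zeros((t.size, n_rois))
    for i in range(n_rois):
        col = base_gain[i] * env + pre_osc / n_rois
        for g in groups:
            col = col + gains[g][i] * phase_osc[g]
        if sd > 0:
            col = col + rng_noise.normal(0.0, sd, size=t.size)
        values[:, i] = col

    labels = [f"roi{i:03d}" for i in range(n_rois)]
    mat = ROIMatrix(times=t, values=values, roi_labels=labels,
                    sampling_rate=spec.sampling_rate,
                    meta={"prep": spec.label, "modality": spec.modality})
    gt.roi_classes = classes
    gt.roi_active_phases = active
    return mat, gt


# ---------------------------------------------------------------------------
# noise calibration oracle
# ---------------------------------------------------------------------------

def calibrate_noise_sd(preset: str, phase: str, target_r: float,
                       candidates=None, n_reps: int = 4, seed: int = 0) -> float:
    """Monte-Carlo calibration of the additive noise level.

    Simulates bilateral pairs of ``preset`` over a grid of candidate
    ``noise_sd`` values and returns the candidate whose mean Pearson
    correlation over the *true* interval of ``phase`` (ground truth, not
    segmentation) is closest to ``target_r``.  This is the independent
    oracle used to fix the noise level of the correlation analyses.
    """
    from .oscillation import pearson

    if candidates is None:
        candidates = (0.02, 0.05, 0.08, 0.12)
    best_sd, best_err = None, np.inf
    for sd in candidates:
        rs = []
        for rep in range(n_reps):
            spec = make_preset(preset, seed=seed * 1000 + rep).replace(noise_sd=sd)
            pair, gt = generate_bilateral(spec)
            names = list(gt.onsets) + ["end"]
            onsets = list(gt.onsets.values()) + [gt.trace_end_s]
            i = names.index(phase)
            r, _, _ = pearson(pair, (onsets[i], onsets[i + 1]))
            rs.append(r)
        err = abs(float(np.mean(rs)) - target_r)
        if err < best_err:
            best_sd, best_err = sd, err
    return float(best_sd)
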