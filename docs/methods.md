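# Methods

This note documents the model behind the package's analyses, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and preprocessing

A raw fluorescence trace is modeled as F(t) = F₀·(1 + b(t) + o(t) + ε(t)),
where b is a slow baseline envelope, o a train of oscillation transients
and ε additive noise, all in ΔF/F units.  ΔF/F normalization divides by a
scalar baseline F and is therefore invariant to the overall scale F₀.
Two baseline conventions are supported, matching the two recording
modalities: neurons use the mean over the 5-min window ending at the
stimulus time (so a stimulus time ≥ 300 s of recorded baseline is
required); muscle uses the mean of the first 250 frames.  Background
subtraction during ROI extraction is per-frame (ROI mean minus background
ROI mean at the same frame), which removes frame-wide drift; negative
values are retained, since clipping would bias ΔF/F.  All downstream
analysis assumes a uniform ~1 Hz grid; traces whose timestamp jitter
exceeds 1% of the sampling interval are linearly interpolated onto a
uniform grid first.

## Peak detection

Peaks are local maxima of the lightly smoothed trace (boxcar, 9 samples)
with topographic prominence at least 3·σ̂ and pairwise separation at
least 5 s.  σ̂ = MAD(diff x)/(0.6745·√2) is a robust estimate of the
per-sample noise SD.  The smoothing step is essential, not cosmetic: over
a 5400-sample record the extreme-value prominence of i.i.d. noise alone
exceeds 3·σ̂ (the expected range of ~5400 Gaussian draws is ≈ 7σ), so an
unsmoothed detector can never report an empty result on a control trace.
After 9-sample smoothing the noise floor drops threefold while transients
tens of seconds wide are barely attenuated, and control recordings with
sub-threshold slow oscillations correctly yield "no response".  Peak
amplitude is the topographic prominence, making amplitudes invariant to
baseline shifts.  Both threshold and separation are exposed
(`min_prominence`, `min_separation_s`) and recorded in diagnostics.

## Window statistics and the onset rules

Windows tile the trace without overlap (a trailing remainder shorter than
one window is ignored).  Defaults: 300 s for neuronal data, 170 s for
muscle; one configuration is used for all neuronal datasets and one for
all muscle datasets.  Non-overlapping tiling is a deliberate choice: the
onset rules compare *consecutive-window differences* against thresholds
built from window-level statistics, and with heavily overlapping windows
(e.g. step = window/5) any real jump is spread over several small
differences, none of which can clear a threshold of order
mean + SD of the window levels.  With non-overlapping windows the full
jump lands in a single difference.

The four rules are stated in `phasefinder.segment`; two numerical
interpretations deserve comment.

* The phase-2 threshold uses the window-level mean amplitudes
  (mean + k·SD over all windows, k = 1, sample SD).  This rule can only
  fire when the phase-2 amplitude jump exceeds the typical window
  amplitude — which is exactly the "sudden increase in amplitude" the
  rule is meant to find.
* The late-3 rule thresholds |Δf| against mean + k·SD of the |Δf|
  distribution itself, not of the frequency levels.  A threshold built
  from frequency *levels* can be shown to be unreachable by any
  frequency *difference* whenever a substantial fraction of windows is
  oscillatory (the jump is at most the larger level, while the threshold
  includes the mean of all levels plus their SD), so the mean + 1 SD
  construction is applied to the statistic actually being tested.  The
  rule used is recorded in the output diagnostics.

The phase-3 reverse scan is restricted to windows after the phase-2
onset; without this restriction, the quiescent pre-stimulus segment
produces spurious frequency decrements.  Onsets are assigned to the start
of the later window of a qualifying pair (where the change is first fully
expressed), ties go to the first qualifying pair in scan order, and
absent onsets are reported as None, never imputed — downstream metrics
skip absent phases explicitly.

A structural property of the reverse-scan rule is worth stating: it finds
the phase-2→3 boundary only if the windowed peak counts are
non-decreasing from the phase-3 onset to the end of the trace, since any
later decrement is found first.  The rule is therefore exquisitely
sensitive to single missed events.  This is a faithful property of the
detector, and the synthetic presets are constructed so that their
late-interval counts are stable (see below); on real data the same
sensitivity would appear as occasional phase-3 onsets placed late in the
transition.

## Rhythm metrics

Pearson's r is computed from the definition with a two-sided p-value
from the t distribution (n − 2 df); it is cross-checked against an
independent implementation in the tests.  Per-phase frequency is peak
count divided by phase duration; for Phase 3 only the uniform late
segment is counted, matching how phase-3 frequencies are reported.
Alternation cycles are counted on the smoothed dominance signal
d = left − right with a hysteresis dead-band of three (pre-smoothing,
robust) noise SDs scaled by √(smoothing width): excursions beyond the
band form an alternating left/right sequence and one cycle is a matched
left/right pair.  This count returns exactly n for a sinusoidal dominance
signal with n periods, whereas a bare sign-change count is off by one
(n periods have 2n − 1 interior crossings) and chatters on noise at epoch
edges.  The antiphase-epoch detector slides a window of twice the
expected period (step = window/6), marks windows with r < −0.2, takes the
longest contiguous qualifying run, and reports the first/last window
*centers* as the epoch bounds; start-based bounds would overshoot by up
to a full window because against a quiet background even a slightly
overlapping window correlates strongly.  Epochs containing fewer than 3
alternation cycles are rejected.

## The synthetic generator

The generator emulates 90-min, 1 Hz GCaMP6s records with the triphasic
structure described above, plus flat-baseline controls and a short
ATP-stimulation record containing a single 9-min antiphase epoch.  Its
components:

* **Baseline** — piecewise linear between per-phase start/end levels
  (rise to ~1.5 ΔF/F through Phase 1, plateau in Phase 2, decline in
  Phase 3); the pre-stimulus segment is flat with control-level activity.
* **Transients** — half-sines of width duty/f (duty 0.3 by default,
  capped at 30 s), one per oscillation period.  Event centers are
  anchored to the period grid with truncated-Gaussian jitter, so the
  realized rate equals the nominal frequency exactly; the mixed
  transition period instead places its events uniformly within
  period-length blocks, producing wildly irregular inter-event intervals
  (the "mixed frequency" appearance) while keeping per-window counts
  pinned.  A cumulative random-walk of intervals was rejected because the
  accumulated phase drift makes window counts stochastic, which the
  reverse-scan rule cannot tolerate (see above).
* **Amplitudes** — log-normal with mean osc_amp and CV amp_jitter,
  floored at 15% of the mean so that every emitted event remains above
  the detection floor; the mixed transition uses CV 0.6, the muscle late
  phase CV 0.75.
* **Bilateral coupling** — per phase: antiphase (right events offset by
  half a period; with duty ≤ 0.5 the two sides' transients never
  overlap), coincident (shared event times, independent amplitudes), or
  uncorrelated (independent placements).  Both sides always share the
  baseline envelope and have independent noise.
* **Noise** — i.i.d. Gaussian in ΔF/F units (0.05 neurons, 0.1 muscle).

For non-overlapping half-sine trains the bilateral Pearson correlation
has a closed form: with m = 2·A·duty/π (mean of the oscillation
component) and E[o²] = A²·duty/2, antiphase sides give
r = −m²/(Var(o) + σ²) and coincident sides with independent amplitude CV
c give r = (E[o²] − m²)/(E[o²](1 + c²) − m² + σ²).  The preset constants
follow from these identities: duty 0.3 with amplitude CV 0.2 puts the
phase-2 antiphase correlation at ≈ −0.30, and amplitude CV 0.75 puts the
coincident late-phase muscle correlation at ≈ +0.57 — the population
values the presets are designed to embody.  The ATP preset uses duty 0.5
(contiguous left/right half-sines, a sine-like alternation), which
deepens the windowed correlation to ≈ −0.68 so the epoch detector's
−0.2 threshold is crossed decisively.

Phase durations are commensurate with the analysis windows (neuronal
onsets at 300/900/2100/3300 s on the 300-s grid; muscle at
300/1020/2040/3060 s on the 170-s grid) and event rates are integer
counts per window (e.g. 6/window in neuronal Phase 2 = 0.02 Hz; 3/window
in muscle Phase 2 = 18 alternations over 17 min).  Phase 1 lasts 10 min
(neurons) / 12 min (muscle), inside the reported 10–15 min rise.

Multi-ROI ensembles assign each ROI to a baseline-modulated or
oscillatory class; oscillatory ROIs carry the shared event schedule of
their active phases (1–3 of phase 1 / phase 2 / phase 3) with per-phase
gains normalized to sum to one, so the column-sum trace retains the
preset's structure exactly, and per-ROI noise is noise_sd/√N so the
pooled global trace has the single-trace noise level.

**What the generator does not emulate** — GCaMP kinetics (rise/decay
asymmetry, saturation), photobleaching (the paper's normalization removes
it), movement artifacts, spatially realistic ROIs, correlated noise, or
waveform diversity beyond half-sines.  Passing recovery tests therefore
demonstrates that the detector implements its rules correctly and
recovers structure of the kind the rules were designed for; it does not
certify performance on real recordings with baseline drift inside phases
or strongly varying event shapes.  Two further honest caveats: the
phase-1 bilateral correlation of the synthetic preparations is dominated
by the shared baseline rise (strongly positive), so "poorly correlated"
applies to the oscillatory component, not the raw phase-1 trace; and the
late-3 event rate sits above the sparse transition rate (while below
phase 2's), because the reverse-scan rule requires non-decreasing counts
after the phase-3 onset.

## Group summaries

Per-phase durations (minutes), frequencies (Hz) and r values are
aggregated as mean ± sample SD (SD reported as absent for n < 2).  Two
groups are compared per phase by Welch's t-test with Šidák correction
over the three phase comparisons (family-wise α = 0.05 by default); the
type-I error of this procedure is verified by a 200-replicate null
calibration in the tests.  Preparations with no post-stimulus peak are
reported as "no response" and excluded from responder statistics.

## Problem sizes

The test suite and the acceptance script run full-length preparations
(5400-sample records).  Parameter recovery uses 50 seeds at the default
noise level plus 15 seeds at each of three noise levels (0.05, 0.12,
0.3 ΔF/F); the bilateral correlation analyses use 8 neuronal and 11
muscle preparations, with the noise level fixed by a small Monte-Carlo
calibration grid (4 candidate SDs × 4 replicates) evaluated on the true
phase intervals.  These sizes were chosen to keep Monte-Carlo error well
inside the tolerances being tested.

## Known limitations

The reverse-scan phase-3 rule's sensitivity to single missed events means
a few percent of seeded preparations yield an absent phase-3 or late-3
onset; these are reported as absent (never imputed) and population
analyses are taken over preparations with detected phases.  The
similarity criterion for ROI profiles (per-phase relative tolerance,
default 0.25) is an explicit stand-in for an undefined published
criterion and the resulting fraction should be read qualitatively.  No
probabilistic change-point machinery is provided by design; the package
reproduces a rule-based detector.
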