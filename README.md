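# phasefinder

Phase segmentation and rhythm metrics for GCaMP calcium-imaging traces of
the fictive *Drosophila* pupal-ecdysis motor program.

When an excised pupal CNS is stimulated with ecdysis-triggering hormone
(ETH), the ventral nerve cord produces a stereotyped, roughly 90-minute
triphasic Ca²⁺ activity pattern: a rising baseline with low-amplitude,
high-frequency oscillations (Phase 1), a plateau carrying large
left–right *antiphase* oscillations (Phase 2, the fictive abdominal
swinging rhythm), and a declining baseline whose mixed-amplitude
"transition period" gives way to slow, uniform, bilaterally coincident
oscillations (late Phase 3).  This package implements the rule-based
detector that finds those phase onsets in a ΔF/F trace, the rhythm
metrics used to quantify them, and a ground-truth synthetic generator so
that every stage can be validated by parameter recovery.  It is written
for physiologists analyzing ~1 Hz GCaMP6s recordings of neuronal or
muscle activity, and for anyone who needs a tested, scriptable version of
this style of sliding-window change-point analysis.

## The method

Traces are normalized as ΔF/F = (F(t) − F)/F, with F the mean over the
5-min pre-stimulus window (neurons) or the first 250 frames (muscle).
Oscillation peaks are local maxima with topographic prominence above
3·σ̂ (σ̂ a robust noise scale from the differenced trace).  Peaks are
summarized in non-overlapping windows (length *w* = 300 s for neurons,
170 s for muscle) as a frequency fᵢ (peaks/s) and mean amplitude aᵢ, and
the four onsets are:

* **Phase 1** — time of the first peak after stimulus addition;
* **Phase 2** — first window pair with a_{i+1} − aᵢ > mean(a) + k·SD(a),
  k = 1 (the sudden amplitude increase);
* **Phase 3** — scanning windows in reverse from the end of the trace,
  the first pair with fᵢ − f_{i+1} > 0, i.e. the latest frequency
  decrement moving forward in time;
* **late Phase 3** — first window pair after the Phase-3 onset with
  |Δf| > mean(|Δf|) + k·SD(|Δf|) (end of the mixed transition period).

Phase durations are onset differences.  Bilateral coordination is
quantified by Pearson's r between left and right ΔF/F (two-sided p from
the t distribution, n − 2 df), alternation cycles are matched left/right
dominance excursions of d(t) = left − right, and sustained antiphase
epochs are maximal runs of sliding windows with r < −0.2.

## Worked example

```python
import numpy as np
from phasefinder import make_preset, generate_bilateral, segment, \
    pearson, count_alternation_cycles, phase_frequency, detect_peaks

spec = make_preset("vnc_rk", seed=1)          # 90-min neuronal preparation
pair, truth = generate_bilateral(spec)        # left/right ΔF/F + ground truth
bounds = segment(pair.left, stimulus_time_s=300, modality="neuron")
print("onsets (s):", bounds.onset_phase1, bounds.onset_phase2,
      bounds.onset_phase3, bounds.onset_late3)
r, p, n = pearson(pair, bounds.interval("phase2"))
print("phase-2 r = %.3f (p = %.2e, n = %d)" % (r, p, n))
f2 = phase_frequency(detect_peaks(pair.left), bounds, "phase2")
print("phase-2 frequency = %.3f Hz, cycles = %d" %
      (f2, count_alternation_cycles(pair, bounds.interval("phase2"))))
```

prints

```
onsets (s): 365.0 900.0 2100.0 3300.0
phase-2 r = -0.303 (p = 5.61e-27, n = 1200)
phase-2 frequency = 0.020 Hz, cycles = 24
```

The detected onsets sit on the analysis-window grid next to the
generator's true onsets (300, 900, 2100, 3300 s); the phase-2 rhythm is
recovered at 0.02 Hz with ~24 left–right alternations, and the negative r
reflects the antiphase coupling of the two sides.

A command-line interface wraps the same pipeline:

```bash
phasefinder simulate --preset muscle_24b --seed 1 -o prep1/
phasefinder segment --input prep1/trace.csv --modality muscle --stimulus-s 300
phasefinder run --config run.yaml -o reports/
phasefinder summarize reports/
```

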