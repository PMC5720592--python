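import numpy as np
import pytest

from phasefinder.preprocess import normalize_dff
from phasefinder.segment import segment
from phasefinder.synthetic import generate_bilateral, generate_trace, make_preset


@pytest.fixture(scope="session")
def trace_cache():
    """Session cache of (preset, seed) -> (Trace, GroundTruth)."""
    cache = {}

    def get(preset, seed, **overrides):
        key = (preset, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            spec = make_preset(preset, seed=seed)
            if overrides:
                spec = spec.replace(**overrides)
            cache[key] = generate_trace(spec)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def pair_cache():
    """Session cache of (preset, seed) -> (BilateralPair, GroundTruth)."""
    cache = {}

    def get(preset, seed, **overrides):
        key = (preset, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            spec = make_preset(preset, seed=seed)
            if overrides:
                spec = spec.replace(**overrides)
            cache[key] = generate_bilateral(spec)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def segmented_cache(trace_cache):
    """Session cache of (preset, seed) -> (DeltaFTrace, PhaseBounds, GroundTruth)."""
    cache = {}

    def get(preset, seed):
        key = (preset, seed)
        if key not in cache:
            spec = make_preset(preset, seed=seed)
            trace, gt = trace_cache(preset, seed)
            mode = "muscle" if spec.modality == "muscle" else "neuron"
            dff = normalize_dff(trace, mode=mode, stimulus_time_s=spec.stimulus_time_s)
            bounds = segment(dff, spec.stimulus_time_s, modality=spec.modality)
            cache[key] = (dff, bounds, gt)
        return cache[key]

    return get
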