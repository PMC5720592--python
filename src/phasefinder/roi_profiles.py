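"""Per-ROI, per-phase frequency profiling and similarity classification.

Phase bounds are always derived from the global (column-sum) trace; each
ROI's peaks are then counted inside those shared bounds, so profiles are
comparable across ROIs.  The three profile entries are (phase 1, phase 2,
late phase 3).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DeltaFTrace, FrequencyProfile, PhaseBounds, ROIMatrix
from .oscillation import phase_frequency
from .peaks import detect_peaks

__all__ = ["roi_frequency_profiles", "classify_similarity", "export_heatmap"]

_PROFILE_PHASES = ("phase1", "phase2", "phase3")


def _trace_profile(dff: DeltaFTrace, bounds: PhaseBounds,
                   min_prominence, min_separation_s) -> np.ndarray:
    peaks = detect_peaks(dff, min_prominence=min_prominence,
                         min_separation_s=min_separation_s)
    out = np.full(3, np.nan)
    for j, phase in enumerate(_PROFILE_PHASES):
        try:
            out[j] = phase_frequency(peaks, bounds, phase)
        except ValueError:
            pass  # absent phase stays NaN
    return out


def roi_frequency_profiles(mat: ROIMatrix, bounds: PhaseBounds,
                           min_prominence: float | str = "auto",
                           min_separation_s: float = 5.0) -> FrequencyProfile:
    """Per-ROI 3-phase peak-rate profiles using the global trace's bounds.

    ``bounds`` must come from segmenting the column-sum trace, not any
    individual ROI.  Detection parameters are shared across ROIs so the
    profiles are mutually comparable.
    """
    glob = mat.global_trace()
    global_prof = _trace_profile(glob, bounds, min_prominence, min_separation_s)

    profs = np.full((mat.n_rois, 3), np.nan)
    for i in range(mat.n_rois):
        dff = DeltaFTrace(times=mat.times, dff=mat.values[:, i],
                          baseline_f=1.0, baseline_window=(0, min(10, len(mat.times))),
                          sampling_rate=mat.sampling_rate,
                          meta={"roi": mat.roi_labels[i]})
        profs[i] = _trace_profile(dff, bounds, min_prominence, min_separation_s)
    return FrequencyProfile(roi_labels=list(mat.roi_labels), frequencies=profs,
                            global_frequencies=global_prof)


def classify_similarity(profiles: FrequencyProfile, rel_tol: float = 0.25,
                        ) -> tuple[float, np.ndarray]:
    """Fraction of ROIs whose profile matches the global profile per-phase.

    An ROI is flagged similar when ``|f_roi - f_global| <= rel_tol *
    f_global`` in every phase.  Returns ``(fraction, flags)``.
    """
    g = profiles.global_frequencies
    if not np.all(np.isfinite(g)):
        raise ValueError("global profile must have all three phases present")
    f = profiles.frequencies
    with np.errstate(invalid="ignore"):
        ok = np.abs(f - g[None, :]) <= rel_tol * g[None, :]
    ok[~np.isfinite(f)] = False
    flags = ok.all(axis=1)
    return float(flags.mean()), flags


def _profile_frame(profiles: FrequencyProfile) -> pd.DataFrame:
    order = np.argsort(profiles.roi_labels)
    df = pd.DataFrame(
        profiles.frequencies[order],
        index=[profiles.roi_labels[i] for i in order],
        columns=["phase1_hz", "phase2_hz", "phase3_hz"],
    )
    df.loc["population"] = profiles.global_frequencies
    df.index.name = "roi"
    return df


def export_heatmap(profiles: FrequencyProfile, path) -> None:
    """Write an ROI x phase frequency heatmap (PNG) plus its CSV twin.

    Rows are label-sorted ROIs with the whole-population profile appended;
    absent phases are written as empty cells in the CSV and rendered as
    masked cells in the image.  Repeated exports are byte-identical.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = str(path)
    df = _profile_frame(profiles)
    csv_path = path + ".csv" if not path.endswith(".csv") else path
    png_path = (path[:-4] if path.endswith(".csv") else path)
    if not png_path.endswith(".png"):
        png_path = png_path + ".png"
    df.to_csv(csv_path, float_format="%.6g", na_rep="")

    data = np.ma.masked_invalid(df.to_numpy())
    fig, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(df))))
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(3), ["Phase 1", "Phase 2", "Phase 3"])
    ax.set_yticks(range(len(df)), df.index.tolist())
    ax.tick_params(labelsize=6)
    fig.colorbar(im, ax=ax, label="peak rate (Hz)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=100, metadata={"Software": None})
    plt.close(fig)
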