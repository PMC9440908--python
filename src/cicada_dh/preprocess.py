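"""Raw fluorescence to dF/F: rolling-percentile baseline and drift QC.

The baseline for frame i is the 30th percentile of the surrounding 5 min of
frames ("rolling ball"), which tracks slow photobleaching without following
stimulus transients.  Percentiles use linear interpolation between order
statistics; windows shrink at the recording edges instead of padding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .data import DffSet, TraceSet
from .errors import ConfigError, NumericError


def rolling_baseline(
    trace: np.ndarray,
    window_s: float = 300.0,
    percentile: float = 30.0,
    frame_rate_hz: float = 1.0,
) -> np.ndarray:
    """Centered rolling-percentile baseline, truncated at the edges.

    For each frame i the baseline is the ``percentile`` of the trace values
    in the window of ``window_s`` seconds centered on i; at the recording
    edges the window shrinks to what is available.
    """
    if window_s <= 0:
        raise ConfigError("window_s must be > 0")
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n < 2:
        raise ConfigError("trace must contain at least 2 frames")
    w = min(int(round(window_s * frame_rate_hz)), n)
    w = max(w, 1)
    half_lo = w // 2
    half_hi = w - half_lo  # window is [i - half_lo, i + half_hi)
    out = np.empty(n)
    first_full = half_lo
    last_full = n - half_hi  # inclusive upper bound for full windows
    if last_full >= first_full:
        windows = np.lib.stride_tricks.sliding_window_view(trace, w)
        out[first_full : last_full + 1] = np.percentile(windows, percentile, axis=1)
    for i in range(min(first_full, n)):
        out[i] = np.percentile(trace[: min(n, i + half_hi)], percentile)
    for i in range(max(last_full + 1, 0), n):
        out[i] = np.percentile(trace[max(0, i - half_lo) :], percentile)
    return out


def compute_dff(trace: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Element-wise (F - F_b) / F_b; requires a strictly positive baseline."""
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if trace.shape != baseline.shape:
        raise NumericError("trace and baseline must have the same shape")
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise NumericError(f"baseline is non-positive at frame {bad[0]}")
    return (trace - baseline) / baseline


def drift_qc(
    trace: np.ndarray,
    bin_s: float = 300.0,
    limit: float = 2.0,
    frame_rate_hz: float = 1.0,
    reference_first_bin: bool = False,
) -> tuple[bool, str, float]:
    """Binned-median drift filter; returns (keep, reason, drift).

    The default rule computes the median raw fluorescence in consecutive
    ``bin_s`` bins and discards the cell when max/min - 1 exceeds ``limit``
    (a >200% swing at the default limit of 2).  With
    ``reference_first_bin=True`` the drift is instead the largest relative
    deviation of any bin median from the first bin.
    """
    if bin_s <= 0 or limit <= 0:
        raise ConfigError("bin_s and limit must be > 0")
    trace = np.asarray(trace, dtype=float)
    bin_frames = max(int(round(bin_s * frame_rate_hz)), 1)
    n_bins = trace.size // bin_frames
    if n_bins < 2:
        raise ConfigError("trace must span at least 2 drift bins")
    medians = np.median(
        trace[: n_bins * bin_frames].reshape(n_bins, bin_frames), axis=1
    )
    if np.any(medians <= 0):
        raise NumericError("non-positive binned median fluorescence")
    if reference_first_bin:
        drift = float(np.max(np.abs(medians / medians[0] - 1.0)))
    else:
        drift = float(medians.max() / medians.min() - 1.0)
    keep = drift <= limit
    reason = "ok" if keep else f"drift {drift * 100:.0f}% exceeds {limit * 100:.0f}% limit"
    return keep, reason, drift


def preprocess_traces(traces: TraceSet, config: PipelineConfig | None = None) -> DffSet:
    """Apply baseline, dF/F and drift QC to every cell of a TraceSet."""
    cfg = config or PipelineConfig()
    baselines = np.empty_like(traces.F)
    dff = np.empty_like(traces.F)
    qc_rows = []
    for i, cid in enumerate(traces.cell_ids):
        baselines[i] = rolling_baseline(
            traces.F[i], cfg.baseline_window_s, cfg.baseline_percentile, traces.frame_rate_hz
        )
        dff[i] = compute_dff(traces.F[i], baselines[i])
        if traces.n_frames >= 2 * int(round(cfg.drift_bin_s * traces.frame_rate_hz)):
            keep, reason, drift = drift_qc(
                traces.F[i],
                cfg.drift_bin_s,
                cfg.drift_limit,
                traces.frame_rate_hz,
                cfg.drift_reference_first_bin,
            )
        else:  # recording shorter than two bins: nothing to compare
            keep, reason, drift = True, "recording shorter than 2 drift bins", 0.0
        qc_rows.append({"cell_id": cid, "keep": keep, "reason": reason, "drift": drift})
    qc = pd.DataFrame(qc_rows)
    return DffSet(list(traces.cell_ids), dff, baselines, qc, traces.frame_rate_hz)
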