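"""Stimulus- and ligand-evoked response detection and threshold calibration.

A cell responds to an event when the peak dF/F in the response window
exceeds both an absolute amplitude threshold (1.25, i.e. 125% dF/F) and a
multiple (6x) of the noise SD measured in the 30 s before the event.
Ligand responses use the identical rule with a 120 s window to match the
2-min bath application.  The thresholds themselves can be re-derived from
an annotated set by a ROC sweep that slightly favors specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import PipelineConfig
from .data import (
    DYNAMIC_FAMILIES,
    GRID_FAMILIES,
    LIGANDS,
    STIMULUS_FAMILIES,
    DffSet,
    Event,
    EventTimeline,
    time_to_frame,
)
from .errors import AssignmentError, CalibrationError, WindowOutOfRange

#: Minimum number of unmasked noise frames before falling back to the full window.
_MIN_NOISE_FRAMES = 3


@dataclass
class ResponseCall:
    """Outcome of the responder rule for one (cell, event) pair."""

    peak_amp: float
    noise_sigma: float
    responder: bool
    cell_id: Optional[str] = None
    event_index: Optional[int] = None


def detect_response(
    dff: np.ndarray,
    onset_s: float,
    frame_rate_hz: float = 1.0,
    window_s: float = 5.0,
    noise_window_s: float = 30.0,
    amp_threshold: float = 1.25,
    sigma_mult: float = 6.0,
    exclude_mask: Optional[np.ndarray] = None,
) -> ResponseCall:
    """Apply the amplitude + sigma responder rule to one event.

    ``exclude_mask`` marks frames (True = exclude) that must not enter the
    noise-SD estimate, e.g. frames inside an earlier event's response
    window; if masking leaves fewer than 3 frames the full window is used.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    start = time_to_frame(onset_s, frame_rate_hz)
    stop = time_to_frame(onset_s + window_s, frame_rate_hz)
    nstart = time_to_frame(onset_s - noise_window_s, frame_rate_hz)
    if nstart < 0 or stop > n or stop <= start:
        raise WindowOutOfRange(
            f"event at {onset_s:g}s: response window [{start}, {stop}) or noise "
            f"window start {nstart} falls outside the {n}-frame recording"
        )
    peak = float(np.max(dff[start:stop]))
    noise = dff[nstart:start]
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)[nstart:start]
        if keep.sum() >= _MIN_NOISE_FRAMES:
            noise = noise[keep]
    sigma = float(np.std(noise, ddof=1)) if noise.size > 1 else 0.0
    responder = peak > amp_threshold and peak > sigma_mult * sigma
    return ResponseCall(peak, sigma, responder)


def detect_ligand_response(
    dff: np.ndarray,
    onset_s: float,
    frame_rate_hz: float = 1.0,
    window_s: float = 120.0,
    noise_window_s: float = 30.0,
    amp_threshold: float = 1.25,
    sigma_mult: float = 6.0,
    exclude_mask: Optional[np.ndarray] = None,
) -> ResponseCall:
    """Responder rule with the wide (120 s) window used for bath ligands."""
    return detect_response(
        dff, onset_s, frame_rate_hz, window_s, noise_window_s,
        amp_threshold, sigma_mult, exclude_mask,
    )


def response_window_mask(
    timeline: EventTimeline | Iterable[Event],
    n_frames: int,
    frame_rate_hz: float = 1.0,
    window_s: float = 5.0,
    ligand_window_s: float = 120.0,
) -> np.ndarray:
    """Boolean mask of frames lying inside any event's response window.

    Used to keep real evoked signal out of the pre-event noise-SD estimate
    when stimuli are closely spaced (grid mapping runs at 15 s intervals).
    """
    mask = np.zeros(n_frames, dtype=bool)
    for ev in timeline:
        w = ligand_window_s if ev.kind == "ligand" else window_s
        if ev.kind == "injection":
            w = max(w, ev.duration_s)
        a = max(time_to_frame(ev.onset_s, frame_rate_hz), 0)
        b = min(time_to_frame(ev.onset_s + w, frame_rate_hz), n_frames)
        mask[a:b] = True
    return mask


def build_response_table(
    dffset: DffSet,
    timeline: EventTimeline,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score every QC-passing cell against every stimulus and ligand event.

    Returns a tidy table with one row per (cell, event): peak amplitude,
    noise sigma, responder flag, plus the event's family/block/trial/grid
    coordinates for downstream grouping.
    """
    cfg = config or PipelineConfig()
    mask = response_window_mask(
        timeline, dffset.n_frames, dffset.frame_rate_hz,
        cfg.response_window_s, cfg.ligand_window_s,
    )
    rows = []
    kept = dffset.kept()
    for ci, cid in enumerate(kept.cell_ids):
        trace = kept.dff[ci]
        for ei, ev in enumerate(timeline):
            if ev.kind == "injection":
                continue
            window = cfg.ligand_window_s if ev.kind == "ligand" else cfg.response_window_s
            call = detect_response(
                trace, ev.onset_s, kept.frame_rate_hz, window,
                cfg.noise_window_s, cfg.amp_threshold, cfg.sigma_mult,
                exclude_mask=mask,
            )
            rows.append(
                {
                    "cell_id": cid,
                    "event_index": ei,
                    "kind": ev.kind,
                    "family": ev.family,
                    "block": ev.block,
                    "trial_index": ev.trial_index,
                    "grid_row": ev.grid_row,
                    "grid_col": ev.grid_col,
                    "peak_amp": call.peak_amp,
                    "noise_sigma": call.noise_sigma,
                    "responder": call.responder,
                }
            )
    return pd.DataFrame(rows)


def assign_family_response(
    calls: pd.DataFrame,
    families: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Collapse per-trial calls to per (cell, family, block) responder flags.

    Dynamic mechanical stimuli (brush, airpuff) require hits on at least
    2 of 3 applications; thermal ramps and static filament sites count a
    cell as a responder after a single hit, because those trials probe
    distinct ramp parameters or skin sites.  ``max_peak`` carries the
    maximum amplitude across all of the family's trials for vector tuning.
    """
    if families is not None:
        present = set(zip(calls["family"], calls["block"])) if len(calls) else set()
        for fam in families:
            if not any(f == fam for f, _ in present):
                raise AssignmentError(f"no trials recorded for family '{fam}'")
    if not len(calls):
        return pd.DataFrame(
            columns=["cell_id", "family", "block", "responder", "n_trials", "n_hits", "max_peak"]
        )
    grouped = calls.groupby(["cell_id", "family", "block"], sort=False)
    out = grouped.agg(
        n_trials=("responder", "size"),
        n_hits=("responder", "sum"),
        max_peak=("peak_amp", "max"),
    ).reset_index()
    dynamic = out["family"].isin(DYNAMIC_FAMILIES)
    out["responder"] = np.where(dynamic, out["n_hits"] >= 2, out["n_hits"] >= 1)
    return out[["cell_id", "family", "block", "responder", "n_trials", "n_hits", "max_peak"]]


@dataclass
class ThresholdCalibration:
    """Result of the ROC sweep over (amplitude, sigma-multiple) thresholds."""

    amp_threshold: float
    sigma_mult: float
    sensitivity: float
    specificity: float
    auc: float
    roc_curve: pd.DataFrame = field(repr=False)


def calibrate_thresholds(
    annotated: pd.DataFrame,
    amp_grid: Sequence[float],
    sigma_grid: Sequence[float],
    specificity_weight: float = 1.25,
) -> ThresholdCalibration:
    """Re-derive responder thresholds from an annotated (ground-truth) set.

    ``annotated`` needs columns ``peak_amp``, ``noise_sigma`` and a boolean
    ``label``.  Every (amp, sigma-multiple) grid point is scored for
    sensitivity and specificity against the labels; the chosen point
    maximizes ``sensitivity + specificity_weight * specificity`` (weights
    above 1 deliberately favor specificity, minimizing false positives).
    Ties break toward higher specificity, then a higher amplitude
    threshold.  The reported AUC is that of the peak-amplitude score.
    """
    labels = annotated["label"].to_numpy(dtype=bool)
    if labels.all() or not labels.any():
        raise CalibrationError("annotations must contain both classes")
    peaks = annotated["peak_amp"].to_numpy(dtype=float)
    sigmas = annotated["noise_sigma"].to_numpy(dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rows = []
    for amp in amp_grid:
        for sm in sigma_grid:
            pred = (peaks > amp) & (peaks > sm * sigmas)
            tp = int(np.sum(pred & labels))
            tn = int(np.sum(~pred & ~labels))
            sens = tp / n_pos
            spec = tn / n_neg
            rows.append(
                {
                    "amp_threshold": float(amp),
                    "sigma_mult": float(sm),
                    "sensitivity": sens,
                    "specificity": spec,
                    "fpr": 1.0 - spec,
                    "objective": sens + specificity_weight * spec,
                }
            )
    roc = pd.DataFrame(rows)
    best = roc.sort_values(
        ["objective", "specificity", "amp_threshold"],
        ascending=[False, False, False],
        kind="mergesort",
    ).iloc[0]
    auc = float(roc_auc_score(labels, peaks))
    return ThresholdCalibration(
        amp_threshold=float(best["amp_threshold"]),
        sigma_mult=float(best["sigma_mult"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        auc=auc,
        roc_curve=roc,
    )


@dataclass
class CapsaicinCall:
    """Pre/post activity comparison around the capsaicin injection."""

    responder: bool
    pre_mean: float
    post_mean: float
    indeterminate: bool = False

    @property
    def ratio(self) -> float:
        return self.post_mean / self.pre_mean if self.pre_mean > 0 else float("nan")


def capsaicin_responder(
    dff: np.ndarray,
    injection_s: float,
    frame_rate_hz: float = 1.0,
    avg_window_s: float = 120.0,
    factor: float = 1.5,
    blind_s: float = 30.0,
    floor: float = 1e-6,
) -> CapsaicinCall:
    """Classify a capsaicin responder from 2-min activity averages.

    The pre window ends ``blind_s`` before the injection and the post
    window starts ``blind_s`` after it, excluding the imaging blind spot
    around needle placement.  A cell responds when the post-window mean
    dF/F exceeds ``factor`` times the pre-window mean.  A pre mean at or
    below ``floor`` cannot anchor a ratio: the call is flagged
    indeterminate and is not a responder.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    pre_a = time_to_frame(injection_s - blind_s - avg_window_s, frame_rate_hz)
    pre_b = time_to_frame(injection_s - blind_s, frame_rate_hz)
    post_a = time_to_frame(injection_s + blind_s, frame_rate_hz)
    post_b = time_to_frame(injection_s + blind_s + avg_window_s, frame_rate_hz)
    if pre_a < 0 or post_b > n:
        raise WindowOutOfRange(
            f"capsaicin averaging windows [{pre_a}, {pre_b}) / [{post_a}, {post_b}) "
            f"fall outside the {n}-frame recording"
        )
    pre_mean = float(np.mean(dff[pre_a:pre_b]))
    post_mean = float(np.mean(dff[post_a:post_b]))
    if pre_mean <= floor:
        return CapsaicinCall(False, pre_mean, post_mean, indeterminate=True)
    return CapsaicinCall(post_mean > factor * pre_mean, pre_mean, post_mean)


def capsaicin_calls(
    dffset: DffSet, timeline: EventTimeline, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Capsaicin-responder classification for every QC-passing cell."""
    cfg = config or PipelineConfig()
    inj = timeline.injection
    if inj is None:
        return pd.DataFrame(
            columns=["cell_id", "capsaicin_responder", "pre_mean", "post_mean", "indeterminate"]
        )
    kept = dffset.kept()
    rows = []
    for ci, cid in enumerate(kept.cell_ids):
        call = capsaicin_responder(
            kept.dff[ci], inj.onset_s, kept.frame_rate_hz,
            cfg.capsaicin_window_s, cfg.capsaicin_factor, cfg.capsaicin_blind_s,
        )
        rows.append(
            {
                "cell_id": cid,
                "capsaicin_responder": call.responder,
                "pre_mean": call.pre_mean,
                "post_mean": call.post_mean,
                "indeterminate": call.indeterminate,
            }
        )
    return pd.DataFrame(rows)
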