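"""Vector tuning, preference scores, receptive fields, and locus inference.

Tuning treats the three compared modalities as unit directions 120 degrees
apart (heat/brush +90, mechanical/LT +210, cold/HT +330, CCW from +x).
Each cell's amplitudes are normalized by their own mean, placed along the
basis directions, and summed: the resulting angle is the modality
preference and the length the strength of that preference (an equally
trimodal cell sums to the zero vector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .config import BASIS_ANGLES_CARDINAL
from .errors import ExcludedCell, FormatError


@dataclass
class TuningVector:
    """Summed tuning vector: direction (deg CCW from +x) and magnitude."""

    angle_deg: float
    magnitude: float
    components: dict[str, tuple[float, float]] = field(default_factory=dict)


def tuning_vector(
    amplitudes: Mapping[str, float],
    basis_angles: Mapping[str, float] | None = None,
) -> TuningVector:
    """Compute the vector tuning of one cell from three modality amplitudes.

    Amplitudes are first normalized by the mean of the three (so uniform
    scaling of a cell's responses leaves its tuning unchanged), then summed
    as vectors along the basis directions.

    Raises
    ------
    ExcludedCell
        If every amplitude is zero; such cells carry no tuning information
        and are excluded upstream.
    """
    basis = dict(basis_angles or BASIS_ANGLES_CARDINAL)
    if set(amplitudes) != set(basis):
        raise FormatError(
            f"amplitude keys {sorted(amplitudes)} do not match basis {sorted(basis)}"
        )
    amps = np.array([float(amplitudes[m]) for m in basis], dtype=float)
    if np.any(amps < 0):
        raise FormatError("amplitudes must be non-negative")
    mean = amps.mean()
    if mean == 0:
        raise ExcludedCell("cell has no responses in any compared modality")
    normed = amps / mean
    comps: dict[str, tuple[float, float]] = {}
    x = y = 0.0
    for modality, a in zip(basis, normed):
        theta = math.radians(basis[modality])
        vx, vy = a * math.cos(theta), a * math.sin(theta)
        comps[modality] = (vx, vy)
        x += vx
        y += vy
    magnitude = math.hypot(x, y)
    angle = math.degrees(math.atan2(y, x)) % 360.0
    return TuningVector(angle_deg=angle, magnitude=magnitude, components=comps)


def standardize_angles(
    angles: np.ndarray | float, reference_angle: float
) -> np.ndarray | float:
    """Signed smallest rotation from a reference axis, in (-180, 180].

    Circular data: +1 deg and -359 deg are the same direction and both map
    to +1 relative to axis 0.  Adding any multiple of 360 to the input
    leaves the output unchanged.
    """
    a = np.asarray(angles, dtype=float)
    d = (a - reference_angle) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if np.isscalar(angles) or d.ndim == 0 else d


def preference_score(amplitudes: Sequence[float] | Mapping[str, float]) -> np.ndarray:
    """Per-modality preference: (X_i - X_avg) / X_max.

    Positive scores mark preferred modalities; for three modalities the
    score is bounded above by 2/3 (reached by a perfectly selective cell).
    """
    if isinstance(amplitudes, Mapping):
        amps = np.array([float(v) for v in amplitudes.values()])
    else:
        amps = np.asarray(amplitudes, dtype=float)
    mx = amps.max() if amps.size else 0.0
    if mx <= 0:
        raise ExcludedCell("preference score undefined for all-zero amplitudes")
    return (amps - amps.mean()) / mx


@dataclass
class ReceptiveField:
    """Grid receptive field: per-trial 4x4 responder grids and their size.

    ``size`` is the mean responsive-site count over trials (0..16);
    ``area_mm2`` converts it to skin area via the per-site area.
    """

    grids: np.ndarray  # (n_trials, 4, 4) boolean
    size: float
    area_mm2: float


def rf_size(per_trial_grids: np.ndarray, per_site_area_mm2: float = 3.75) -> ReceptiveField:
    """Average the responsive-site counts of the per-trial 4x4 grids."""
    grids = np.asarray(per_trial_grids, dtype=bool)
    if grids.ndim == 2:
        grids = grids[None]
    if grids.ndim != 3 or grids.shape[1:] != (4, 4):
        raise FormatError(f"expected (n_trials, 4, 4) grids, got shape {grids.shape}")
    size = float(grids.reshape(grids.shape[0], -1).sum(axis=1).mean())
    return ReceptiveField(grids=grids, size=size, area_mm2=rf_area(size, per_site_area_mm2))


def rf_area(size: float, per_site_area_mm2: float = 3.75) -> float:
    """Convert a responsive-site count to skin area (mm^2).

    The 16 mapping sites tile a 225 mm^2 region at ~3.75 mm spacing, so a
    cell responding at 4 sites covers an estimated 15 mm^2.
    """
    if size < 0:
        raise FormatError("receptive-field size must be >= 0")
    return float(size) * float(per_site_area_mm2)


def rf_from_calls(
    calls: pd.DataFrame, per_site_area_mm2: float = 3.75
) -> pd.DataFrame:
    """Build per (cell, family, block) receptive fields from grid-site calls.

    ``calls`` is the per-event response table restricted to grid families
    (static_LT / static_HT); trials are the repeated passes over the grid.
    """
    rows = []
    grid_calls = calls[calls["grid_row"].notna()]
    for (cid, fam, block), g in grid_calls.groupby(["cell_id", "family", "block"], sort=False):
        trials = sorted(g["trial_index"].unique())
        grids = np.zeros((len(trials), 4, 4), dtype=bool)
        for ti, trial in enumerate(trials):
            sub = g[g["trial_index"] == trial]
            grids[
                ti,
                sub["grid_row"].astype(int).to_numpy(),
                sub["grid_col"].astype(int).to_numpy(),
            ] = sub["responder"].to_numpy(dtype=bool)
        rf = rf_size(grids, per_site_area_mm2)
        rows.append(
            {
                "cell_id": cid,
                "family": fam,
                "block": block,
                "size": rf.size,
                "area_mm2": rf.area_mm2,
                "n_trials": len(trials),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "family", "block", "size", "area_mm2", "n_trials"])


def tuning_from_families(
    family_table: pd.DataFrame,
    modality_map: Mapping[str, Sequence[str]],
    basis_angles: Mapping[str, float],
    block: str = "pre",
) -> pd.DataFrame:
    """Per-cell tuning vectors from the family-level response table.

    ``modality_map`` maps each basis modality to the stimulus families it
    aggregates (e.g. ``mechanical -> (brush, static_LT, static_HT)`` for
    cardinal tuning); the amplitude is the maximum responding-family peak.
    Cells with no responses across the compared modalities are skipped.
    """
    sub = family_table[family_table["block"] == block]
    rows = []
    for cid, g in sub.groupby("cell_id", sort=False):
        amps = {}
        for modality, fams in modality_map.items():
            sel = g[g["family"].isin(fams) & g["responder"]]
            amps[modality] = float(sel["max_peak"].max()) if len(sel) else 0.0
        try:
            tv = tuning_vector(amps, basis_angles)
        except ExcludedCell:
            continue
        rows.append(
            {"cell_id": cid, "block": block, "angle_deg": tv.angle_deg, "magnitude": tv.magnitude}
        )
    return pd.DataFrame(rows, columns=["cell_id", "block", "angle_deg", "magnitude"])


@dataclass
class LocusEstimate:
    """Inferred injection locus from mediolateral responder positions."""

    locus_col: Optional[int]
    spread_cols: list[int]
    confidence: float
    low_confidence: bool
    distances: dict[int, float]


def infer_injection_locus(
    responder_ml: Sequence[float],
    reference_ml_by_col: Mapping[int, Sequence[float]],
    min_responders: int = 5,
    spread_factor: float = 1.5,
    confidence_threshold: float = 0.1,
) -> LocusEstimate:
    """Locate the injection along the proximal-distal axis by somatotopy.

    Compares the mediolateral (ML) distribution of capsaicin responders to
    the ML distributions of cells driven by HT stimulation at each grid
    column, using the first Wasserstein distance.  The locus is the
    best-matching column; the spread is every column within
    ``spread_factor`` times the minimum distance; confidence is the
    relative margin between the best and second-best match.
    """
    responder_ml = np.asarray(responder_ml, dtype=float)
    if not reference_ml_by_col:
        raise FormatError("at least one reference distribution is required")
    if responder_ml.size < min_responders:
        return LocusEstimate(None, [], 0.0, True, {})
    distances = {
        int(col): float(wasserstein_distance(responder_ml, np.asarray(ref, dtype=float)))
        for col, ref in reference_ml_by_col.items()
    }
    ordered = sorted(distances.items(), key=lambda kv: kv[1])
    locus, d1 = ordered[0]
    d2 = ordered[1][1] if len(ordered) > 1 else float("inf")
    spread = sorted(c for c, d in distances.items() if d <= spread_factor * max(d1, 1e-12))
    confidence = (d2 - d1) / d2 if np.isfinite(d2) and d2 > 0 else 1.0
    return LocusEstimate(
        locus_col=locus,
        spread_cols=spread,
        confidence=float(confidence),
        low_confidence=bool(confidence < confidence_threshold),
        distances=distances,
    )
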