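"""Shared in-memory data model: traces, event timelines, ROI tables.

All downstream stages consume these containers.  Time is seconds from
recording start; a time maps to a frame as ``round(t * frame_rate_hz)`` and
every analysis window is half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

#: Cutaneous stimulus families.
STIMULUS_FAMILIES = ("brush", "airpuff", "static_LT", "static_HT", "heat", "cold")

#: The eight CICADA ligands, in canonical order.
LIGANDS = ("SP", "OXT", "GRP", "Oxo", "taltirelin", "NMB", "CCK", "NKB")

#: Families whose events carry a 4x4 grid site.
GRID_FAMILIES = ("static_LT", "static_HT")

#: Dynamic mechanical families scored with the 2-of-3 assignment rule.
DYNAMIC_FAMILIES = ("brush", "airpuff")

VALID_KINDS = ("stimulus", "ligand", "injection")
VALID_BLOCKS = ("pre", "post")


def time_to_frame(t_s: float, frame_rate_hz: float) -> int:
    """Map a time in seconds to the nearest frame index."""
    return int(round(t_s * frame_rate_hz))


@dataclass
class TraceSet:
    """Raw fluorescence matrix, cells x frames, plus the frame rate.

    Invariants: rectangular, finite, non-negative F; frame_rate_hz > 0.
    """

    cell_ids: list[str]
    F: np.ndarray
    frame_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.F.ndim != 2:
            raise FormatError("F must be a 2-D cells x frames matrix")
        if len(self.cell_ids) != self.F.shape[0]:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {self.F.shape[0]} trace rows"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids must be unique")
        if not self.frame_rate_hz > 0:
            raise FormatError("frame_rate_hz must be > 0")
        if not np.all(np.isfinite(self.F)):
            bad = np.argwhere(~np.isfinite(self.F))[0]
            raise FormatError(
                f"non-finite fluorescence for cell '{self.cell_ids[bad[0]]}' "
                f"(row {bad[0]}) at frame {bad[1]}"
            )
        if np.any(self.F < 0):
            bad = np.argwhere(self.F < 0)[0]
            raise FormatError(
                f"negative fluorescence for cell '{self.cell_ids[bad[0]]}' "
                f"at frame {bad[1]}"
            )

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def trace(self, cell_id: str) -> np.ndarray:
        return self.F[self.cell_ids.index(cell_id)]


@dataclass(frozen=True)
class Event:
    """One protocol event: a cutaneous stimulus, a bath ligand, or an injection."""

    kind: str
    family: str
    onset_s: float
    duration_s: float = 1.0
    grid_row: Optional[int] = None
    grid_col: Optional[int] = None
    trial_index: int = 0
    block: str = "pre"

    def validate(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"unknown event kind '{self.kind}'")
        if self.kind == "stimulus" and self.family not in STIMULUS_FAMILIES:
            raise SchemaError(f"unknown stimulus family '{self.family}'")
        if self.kind == "ligand" and self.family not in LIGANDS:
            raise SchemaError(f"unknown ligand '{self.family}'")
        if self.kind == "injection" and self.family != "capsaicin":
            raise SchemaError(f"unknown injection family '{self.family}'")
        has_grid = self.grid_row is not None or self.grid_col is not None
        if self.family in GRID_FAMILIES:
            if self.grid_row is None or self.grid_col is None:
                raise SchemaError(
                    f"{self.family} event at {self.onset_s:g}s requires grid_row/grid_col"
                )
            if not (0 <= self.grid_row <= 3 and 0 <= self.grid_col <= 3):
                raise SchemaError("grid coordinates must lie in 0..3")
        elif has_grid:
            raise SchemaError(
                f"grid site given on non-grid family '{self.family}'"
            )
        if self.trial_index < 0:
            raise SchemaError("trial_index must be >= 0")
        if self.block not in VALID_BLOCKS:
            raise SchemaError(f"unknown block '{self.block}'")


@dataclass
class EventTimeline:
    """Onset-ordered sequence of validated events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            ev.validate()
        onsets = [ev.onset_s for ev in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise SchemaError("event onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    def select(
        self,
        kind: Optional[str] = None,
        family: Optional[str] = None,
        block: Optional[str] = None,
    ) -> "EventTimeline":
        evs = [
            ev
            for ev in self.events
            if (kind is None or ev.kind == kind)
            and (family is None or ev.family == family)
            and (block is None or ev.block == block)
        ]
        return EventTimeline(evs)

    @property
    def injection(self) -> Optional[Event]:
        """The capsaicin injection event, if present."""
        for ev in self.events:
            if ev.kind == "injection":
                return ev
        return None

    def end_s(self) -> float:
        return max((ev.onset_s + ev.duration_s for ev in self.events), default=0.0)

    def to_records(self) -> list[dict]:
        return [
            {
                "kind": ev.kind,
                "family": ev.family,
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "grid_row": ev.grid_row,
                "grid_col": ev.grid_col,
                "trial_index": ev.trial_index,
                "block": ev.block,
            }
            for ev in self.events
        ]


ROI_COLUMNS = ("cell_id", "x_px", "y_px", "plane_index", "is_spbn", "depth_um")


@dataclass
class RoiTable:
    """Per-cell geometry: in-plane position, optical plane, projection flag.

    ``depth_um`` starts as NaN and is filled by the depth module (or the
    synthetic generator's ground truth when no structural volume is used).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ROI_COLUMNS:
            if col == "depth_um" and col not in df.columns:
                df[col] = np.nan
            elif col not in df.columns:
                raise SchemaError(f"ROI table missing column '{col}'")
        df["cell_id"] = df["cell_id"].astype(str)
        df["is_spbn"] = df["is_spbn"].astype(bool)
        df["plane_index"] = df["plane_index"].astype(int)
        if df["cell_id"].duplicated().any():
            raise SchemaError("duplicate cell ids in ROI table")
        self.df = df.reset_index(drop=True)

    def validate_against(self, traces: TraceSet, n_planes: int = 3) -> None:
        if set(self.df["cell_id"]) != set(traces.cell_ids):
            raise SchemaError("ROI table cell ids do not match the trace set")
        if ((self.df["plane_index"] < 0) | (self.df["plane_index"] >= n_planes)).any():
            raise SchemaError(f"plane_index must lie in 0..{n_planes - 1}")

    def with_depths(self, depths: pd.Series) -> "RoiTable":
        df = self.df.copy()
        df["depth_um"] = df["cell_id"].map(depths)
        return RoiTable(df)


@dataclass
class DffSet:
    """dF/F matrix with the rolling baseline and per-cell QC decisions.

    dF/F is unitless: 1.0 means a 100% fluorescence increase over baseline.
    """

    cell_ids: list[str]
    dff: np.ndarray
    baseline: np.ndarray
    qc: pd.DataFrame  # columns: cell_id, keep, reason, drift
    frame_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.dff.shape != self.baseline.shape:
            raise FormatError("dff and baseline shapes differ")
        if self.dff.shape[0] != len(self.cell_ids):
            raise FormatError("cell id count does not match dff rows")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def kept_ids(self) -> list[str]:
        return list(self.qc.loc[self.qc["keep"], "cell_id"])

    def trace(self, cell_id: str) -> np.ndarray:
        return self.dff[self.cell_ids.index(cell_id)]

    def kept(self) -> "DffSet":
        """Return a DffSet restricted to cells that passed drift QC."""
        keep = self.qc["keep"].to_numpy()
        idx = np.flatnonzero(keep)
        return DffSet(
            [self.cell_ids[i] for i in idx],
            self.dff[idx],
            self.baseline[idx],
            self.qc.loc[keep].reset_index(drop=True),
            self.frame_rate_hz,
        )


__all__ = [
    "STIMULUS_FAMILIES",
    "LIGANDS",
    "GRID_FAMILIES",
    "DYNAMIC_FAMILIES",
    "TraceSet",
    "Event",
    "EventTimeline",
    "RoiTable",
    "DffSet",
    "time_to_frame",
    "replace",
]
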