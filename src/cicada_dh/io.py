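"""Reading and writing the on-disk formats.

Traces travel as wide CSV (``cell_id,f0,f1,...``) for desk-scale work or as
an HDF5 container (``/F``, ``/cell_ids``, attr ``frame_rate_hz``) for full
recordings.  Events are a JSON array, ROI tables and all result tables are
CSV, and the end-of-run report is JSON with a checksummed file manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .data import Event, EventTimeline, RoiTable, TraceSet
from .errors import FormatError, ParseError, SchemaError

# -- traces ---------------------------------------------------------------


def read_traces(path: str | Path) -> TraceSet:
    """Read a TraceSet from CSV or HDF5, preserving row order.

    Raises
    ------
    FormatError
        If rows are ragged or the header is malformed.
    ParseError
        If a cell value is missing or non-numeric; the message names the
        offending row and frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as h:
            F = np.asarray(h["F"], dtype=float)
            ids = [c.decode() if isinstance(c, bytes) else str(c) for c in h["cell_ids"][()]]
            rate = float(h.attrs.get("frame_rate_hz", 1.0))
        return TraceSet(ids, F, rate)
    return _read_traces_csv(path)


def _read_traces_csv(path: Path) -> TraceSet:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if not header or header[0] != "cell_id":
            raise FormatError(f"{path}: first column must be 'cell_id'")
        n_frames = len(header) - 1
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for row_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(",")
            if len(parts) != n_frames + 1:
                raise FormatError(
                    f"{path}: ragged row {row_no} has {len(parts) - 1} frames, "
                    f"expected {n_frames}"
                )
            ids.append(parts[0])
            try:
                vals = np.array([float(v) if v != "" else np.nan for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value in row {row_no}: {exc}") from exc
            if np.any(np.isnan(vals)):
                frame = int(np.flatnonzero(np.isnan(vals))[0])
                raise ParseError(
                    f"{path}: missing value for cell '{parts[0]}' (row {row_no}) "
                    f"at frame {frame}"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no trace rows")
    rate = _read_sidecar_rate(path)
    return TraceSet(ids, np.vstack(rows), rate)


def _rate_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _read_sidecar_rate(path: Path) -> float:
    sidecar = _rate_sidecar(path)
    if sidecar.exists():
        return float(json.loads(sidecar.read_text()).get("frame_rate_hz", 1.0))
    return 1.0


def write_traces(traces: TraceSet, path: str | Path) -> Path:
    """Write a TraceSet; the container is chosen from the file suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as h:
            h.create_dataset("F", data=traces.F)
            h.create_dataset(
                "cell_ids", data=np.array(traces.cell_ids, dtype=h5py.string_dtype())
            )
            h.attrs["frame_rate_hz"] = traces.frame_rate_hz
        return path
    header = "cell_id," + ",".join(f"f{i}" for i in range(traces.n_frames))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for cid, row in zip(traces.cell_ids, traces.F):
            fh.write(cid + "," + ",".join(repr(float(v)) for v in row) + "\n")
    if traces.frame_rate_hz != 1.0:
        _rate_sidecar(path).write_text(json.dumps({"frame_rate_hz": traces.frame_rate_hz}))
    return path


# -- events ---------------------------------------------------------------

_EVENT_FIELDS = {
    "kind", "family", "onset_s", "duration_s", "grid_row", "grid_col",
    "trial_index", "block",
}


def read_events(path: str | Path) -> EventTimeline:
    """Read and validate a JSON event timeline; events are sorted by onset."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: events file must contain a JSON array")
    events = []
    for i, rec in enumerate(raw):
        unknown = set(rec) - _EVENT_FIELDS
        if unknown:
            raise SchemaError(f"{path}: event {i} has unknown fields {sorted(unknown)}")
        try:
            ev = Event(
                kind=rec["kind"],
                family=rec["family"],
                onset_s=float(rec["onset_s"]),
                duration_s=float(rec.get("duration_s", 1.0)),
                grid_row=rec.get("grid_row"),
                grid_col=rec.get("grid_col"),
                trial_index=int(rec.get("trial_index", 0)),
                block=rec.get("block", "pre"),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: event {i} missing field {exc}") from exc
        events.append(ev)
    events.sort(key=lambda e: e.onset_s)
    return EventTimeline(events)


def write_events(timeline: EventTimeline, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(timeline.to_records(), indent=1))
    return path


# -- ROI tables -----------------------------------------------------------


def read_roi_table(path: str | Path) -> RoiTable:
    return RoiTable(pd.read_csv(path))


def write_roi_table(rois: RoiTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rois.df.to_csv(path, index=False)
    return path


# -- report + manifest ----------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(
    tables: dict[str, pd.DataFrame],
    report: dict,
    out_dir: str | Path,
    config_echo: Optional[dict] = None,
) -> pd.DataFrame:
    """Write result tables plus ``report.json`` and return the file manifest.

    ``tables`` maps a base name (e.g. ``responses``) to a DataFrame written
    as ``<name>.csv``.  The report JSON always carries the software version
    and, when given, an echo of the configuration used, so a run can be
    reproduced from its own output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    payload = dict(report)
    payload["software_version"] = __version__
    if config_echo is not None:
        payload["config"] = config_echo
    report_path = out / "report.json"
    report_path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))
    written.append(report_path)
    manifest = pd.DataFrame(
        {"file": [p.name for p in written], "sha256": [_sha256(p) for p in written]}
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
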