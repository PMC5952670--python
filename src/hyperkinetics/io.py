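"""Plain-text I/O: per-cell trace tables, protocol schedules, results tables.

Trace tables are long (tidy) CSV with one row per frame:
``experiment_id, cell_id, time_s, f420, f490, cell_line, compartment,
treatment, ph``.  Times are stored in seconds (the acquisition unit) and
converted to minutes at the analysis boundary.  Protocol schedules are YAML
with keys ``duration_min``, ``sample_interval_s`` and an ``events`` list of
``{t_min, kind, conc_uM | ph}`` mappings.  All parsers validate and reject
malformed input rather than coercing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import Event, ProtocolSchedule, ScheduleError

__all__ = [
    "AcquisitionTrace",
    "TraceFormatError",
    "read_traces",
    "write_traces",
    "read_protocol",
    "write_protocol",
    "read_results",
    "write_results",
]

TRACE_COLUMNS = ["experiment_id", "cell_id", "time_s", "f420", "f490"]
META_COLUMNS = ["cell_line", "compartment", "treatment", "ph"]
_FLOAT_FMT = "%.12g"


class TraceFormatError(ValueError):
    """Raised for malformed trace/protocol/results files."""


@dataclass
class AcquisitionTrace:
    """Dual-channel fluorescence time series of a single cell ROI."""

    cell_id: str
    time_s: np.ndarray
    f420: np.ndarray
    f490: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f420 = np.asarray(self.f420, dtype=float)
        self.f490 = np.asarray(self.f490, dtype=float)
        n = len(self.time_s)
        if len(self.f420) != n or len(self.f490) != n:
            raise TraceFormatError(
                f"cell {self.cell_id}: channel lengths differ from time axis"
            )
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise TraceFormatError(f"cell {self.cell_id}: time_s not strictly increasing")
        if np.any(~np.isfinite(self.f420)) or np.any(~np.isfinite(self.f490)):
            raise TraceFormatError(f"cell {self.cell_id}: non-finite fluorescence")
        if np.any(self.f420 <= 0) or np.any(self.f490 <= 0):
            raise TraceFormatError(f"cell {self.cell_id}: non-positive fluorescence")

    @property
    def time_min(self) -> np.ndarray:
        return self.time_s / 60.0

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def read_traces(path) -> list[AcquisitionTrace]:
    """Read a long-format trace CSV into per-cell traces.

    Rows are grouped by ``(experiment_id, cell_id)`` and sorted by time;
    metadata columns are carried along on each trace.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"missing required column(s): {', '.join(missing)}")
    meta_cols = [c for c in df.columns if c not in ("time_s", "f420", "f490")]
    traces = []
    for (exp, cell), g in df.groupby(["experiment_id", "cell_id"], sort=True):
        g = g.sort_values("time_s")
        meta = {c: g[c].iloc[0] for c in meta_cols}
        traces.append(
            AcquisitionTrace(
                cell_id=str(cell),
                time_s=g["time_s"].to_numpy(),
                f420=g["f420"].to_numpy(),
                f490=g["f490"].to_numpy(),
                metadata=meta,
            )
        )
    return traces


def write_traces(traces, path) -> None:
    """Write traces as long-format CSV with deterministic column order and
    float formatting (two writes of the same data are byte-identical)."""
    path = Path(path)
    frames = []
    for tr in traces:
        meta = dict(tr.metadata)
        exp = meta.pop("experiment_id", meta.pop("experiment", "exp0"))
        df = pd.DataFrame(
            {
                "experiment_id": exp,
                "cell_id": tr.cell_id,
                "time_s": tr.time_s,
                "f420": tr.f420,
                "f490": tr.f490,
            }
        )
        for c in META_COLUMNS:
            df[c] = meta.get(c, "")
        frames.append(df)
    cols = TRACE_COLUMNS + META_COLUMNS
    if frames:
        out = pd.concat(frames, ignore_index=True)[cols]
    else:
        out = pd.DataFrame(columns=cols)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_protocol(path) -> ProtocolSchedule:
    """Read a YAML protocol schedule; validates event kinds and ordering."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TraceFormatError(f"{path}: protocol file must be a mapping")
    for key in ("duration_min", "events"):
        if key not in raw:
            raise TraceFormatError(f"{path}: missing required key {key!r}")
    events = []
    for i, ev in enumerate(raw["events"]):
        if not isinstance(ev, dict) or "t_min" not in ev or "kind" not in ev:
            raise TraceFormatError(f"{path}: event #{i} needs t_min and kind")
        try:
            events.append(
                Event(
                    t_min=float(ev["t_min"]),
                    kind=str(ev["kind"]),
                    conc_uM=None if ev.get("conc_uM") is None else float(ev["conc_uM"]),
                    ph=None if ev.get("ph") is None else float(ev["ph"]),
                )
            )
        except ScheduleError as exc:
            raise TraceFormatError(f"{path}: event #{i}: {exc}") from exc
    try:
        return ProtocolSchedule(
            events=tuple(events),
            duration_min=float(raw["duration_min"]),
            sample_interval_s=float(raw.get("sample_interval_s", 20.0)),
        )
    except ScheduleError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_protocol(schedule: ProtocolSchedule, path) -> None:
    events = []
    for e in schedule.events:
        d = {"t_min": float(e.t_min), "kind": e.kind}
        if e.conc_uM is not None:
            d["conc_uM"] = float(e.conc_uM)
        if e.ph is not None:
            d["ph"] = float(e.ph)
        events.append(d)
    doc = {
        "duration_min": float(schedule.duration_min),
        "sample_interval_s": float(schedule.sample_interval_s),
        "events": events,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


RESULTS_KEY = ["experiment_id", "cell_id"]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a per-cell results table (one row per analyzed cell)."""
    if all(k in table.columns for k in RESULTS_KEY):
        if table.duplicated(RESULTS_KEY).any():
            raise TraceFormatError("duplicated (experiment_id, cell_id) rows in results")
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if all(k in df.columns for k in RESULTS_KEY) and df.duplicated(RESULTS_KEY).any():
        raise TraceFormatError("duplicated (experiment_id, cell_id) rows in results")
    return df
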