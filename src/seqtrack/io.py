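"""Delimited-text readers and writers for session data.

File contracts (all UTF-8, comma-delimited, times in seconds):

* event log:  header ``time_s,event``; one file per session
* spike file: header ``unit_id,time_s``
* unit metadata: header ``unit_id,session_id,half_valley_width_ms``
* trace matrix: one row per unit, 175 rate columns, with a ``# segments:``
  header line recording the segment boundaries
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import EventLog
from .population import PopulationMatrix


def read_event_log(path: str | Path, session_id: str | None = None) -> EventLog:
    path = Path(path)
    df = pd.read_csv(path)
    return EventLog(session_id=session_id or path.stem, events=df[["time_s", "event"]])


def write_event_log(log: EventLog, path: str | Path) -> None:
    log.events.to_csv(path, index=False, float_format="%.4f")


def read_spikes(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        str(uid): np.sort(g["time_s"].to_numpy(dtype=float))
        for uid, g in df.groupby("unit_id", sort=True)
    }


def write_spikes(spikes: dict[str, np.ndarray], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"unit_id": uid, "time_s": times}) for uid, times in sorted(spikes.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def read_unit_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("unit_id")


def write_unit_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path)


def write_trace_matrix(m: PopulationMatrix, path: str | Path) -> None:
    seg = ";".join(f"{k}={v.start}:{v.stop}" for k, v in m.segments.items())
    with open(path, "w") as fh:
        fh.write(f"# segments: {seg}\n")
        pd.DataFrame(m.values, index=pd.Index(m.unit_ids, name="unit_id")).to_csv(fh)


def read_trace_matrix(path: str | Path) -> PopulationMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# segments:"):
            raise ValueError("missing '# segments:' header line")
        segments = {}
        for part in header.split(":", 1)[1].strip().split(";"):
            name, rng = part.split("=")
            lo, hi = rng.split(":")
            segments[name] = slice(int(lo), int(hi))
        df = pd.read_csv(fh, index_col="unit_id")
    return PopulationMatrix(
        values=df.to_numpy(dtype=float),
        unit_ids=[str(u) for u in df.index],
        meta=pd.DataFrame(index=df.index),
        segments=segments,
    )
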