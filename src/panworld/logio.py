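"""Event-log serialization: JSON Lines with a versioned header record.

The first line is a header carrying the schema version, the config (and its
fingerprint), and the master seed; every following line is one event with
flattened scalar fields (day, t, type, actor, target, x, y, payload).  A
flat-CSV exporter and a reader for a documented tabular dialect are provided
for working with externally archived session data.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .sim_engine import EVENT_TYPES, Event, SessionLog
from .world_config import WorldConfig, config_fingerprint

__all__ = ["SCHEMA_VERSION", "LogFormatError", "write_log", "read_log",
           "write_csv", "read_table_log", "log_to_frame"]

SCHEMA_VERSION = 1


class LogFormatError(ValueError):
    """Raised for corrupt, truncated, or wrong-version log files."""


def write_log(log: SessionLog, path: str | Path) -> None:
    """Write a session log as JSON Lines (header record + one event per line)."""
    header = {
        "schema_version": SCHEMA_VERSION,
        "fingerprint": log.fingerprint,
        "seed": log.seed,
        "config": log.config.model_dump(),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for ev in log.events:
            fh.write(json.dumps(
                {"day": ev.day, "t": ev.t, "type": ev.type, "actor": ev.actor,
                 "target": ev.target, "x": ev.x, "y": ev.y, "payload": ev.payload},
                sort_keys=True) + "\n")


def _parse_line(line: str, lineno: int) -> dict:
    try:
        return json.loads(line)
    except json.JSONDecodeError as exc:
        raise LogFormatError(f"corrupt log line {lineno}: {exc}") from exc


def read_log(path: str | Path) -> SessionLog:
    """Read and validate a JSON Lines session log.

    Checks the schema version, the config fingerprint, monotone timestamps,
    and known event types; reconstructs end-of-session points from the final
    day's points_snapshot events.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise LogFormatError("empty log file")
    header = _parse_line(lines[0], 1)
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise LogFormatError(
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION})")
    config = WorldConfig.model_validate(header["config"])
    if header.get("fingerprint") != config_fingerprint(config):
        raise LogFormatError("config fingerprint mismatch")
    events: list[Event] = []
    prev = (-1, -1.0)
    final_points: dict[int, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        rec = _parse_line(line, lineno)
        missing = {"day", "t", "type"} - rec.keys()
        if missing:
            raise LogFormatError(f"log line {lineno} missing fields {sorted(missing)}")
        if rec["type"] not in EVENT_TYPES:
            raise LogFormatError(f"log line {lineno}: unknown event type {rec['type']!r}")
        stamp = (rec["day"], rec["t"])
        if stamp < prev:
            raise LogFormatError(f"log line {lineno}: out-of-order timestamp {stamp}")
        prev = stamp
        ev = Event(day=rec["day"], t=rec["t"], type=rec["type"],
                   actor=rec.get("actor"), target=rec.get("target"),
                   x=rec.get("x"), y=rec.get("y"), payload=rec.get("payload", {}))
        events.append(ev)
        if ev.type == "points_snapshot":
            final_points[ev.actor] = ev.payload["points"]
    return SessionLog(config=config, fingerprint=header["fingerprint"],
                      seed=header["seed"], events=events,
                      final_points=final_points)


def log_to_frame(log: SessionLog) -> pd.DataFrame:
    """Flatten events to a DataFrame (payload as a JSON string column)."""
    return pd.DataFrame(
        {"day": ev.day, "t": ev.t, "type": ev.type, "actor": ev.actor,
         "target": ev.target, "x": ev.x, "y": ev.y,
         "payload": json.dumps(ev.payload, sort_keys=True)}
        for ev in log.events)


def write_csv(log: SessionLog, path: str | Path) -> None:
    """Flat CSV export for spreadsheet users (no header record; lossy on config)."""
    log_to_frame(log).to_csv(path, index=False)


def read_table_log(path: str | Path, config: WorldConfig, seed: int = 0) -> SessionLog:
    """Read the documented tabular dialect: a CSV with columns
    day,t,type,actor,target,x,y[,payload] — e.g. externally archived session
    data recoded to this shape.  The caller supplies the matching config."""
    frame = pd.read_csv(path)
    required = {"day", "t", "type"}
    if not required <= set(frame.columns):
        raise LogFormatError(f"tabular log must include columns {sorted(required)}")
    events = []
    for row in frame.itertuples(index=False):
        payload = getattr(row, "payload", None)
        payload = json.loads(payload) if isinstance(payload, str) and payload else {}

        def _opt(name):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

        actor = _opt("actor")
        target = _opt("target")
        events.append(Event(day=int(row.day), t=float(row.t), type=str(row.type),
                            actor=None if actor is None else int(actor),
                            target=None if target is None else int(target),
                            x=_opt("x"), y=_opt("y"), payload=payload))
    events.sort(key=lambda e: (e.day, e.t))
    final_points = {ev.actor: ev.payload.get("points")
                    for ev in events if ev.type == "points_snapshot"}
    return SessionLog(config=config, fingerprint=config_fingerprint(config),
                      seed=seed, events=events, final_points=final_points)
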