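"""CSV/YAML readers and writers, and video-to-photometry clock alignment.

One CSV dialect throughout: comma-separated, UTF-8, header row required,
'.' decimal.  Floats are written with Python's shortest round-trip repr so
write -> read is bit-identical in values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arenas import ArenaGeometry, arena_from_config
from .types import EventLog, FormatError, PhotometrySession, PositionTrack, ValidationError, ZScoredTrace

__all__ = [
    "read_session",
    "write_session",
    "read_events",
    "write_events",
    "read_track",
    "write_track",
    "read_ztrace",
    "write_ztrace",
    "load_arena",
    "save_arena_config",
    "align_events",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        # round_trip parsing: values written with shortest-repr floats read
        # back bit-identically
        return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_session(path, manifest: dict | None = None) -> PhotometrySession:
    """Read a photometry session from CSV.

    The file must have a ``time`` column and at least one fluorescence
    column.  ``manifest`` supplies session metadata and may name the
    fluorescence column (``signal_column``); otherwise the first non-time
    column is used.
    """
    manifest = dict(manifest or {})
    df = _read_csv(path)
    _require(df, ["time"], path)
    sig = manifest.pop("signal_column", None)
    if sig is None:
        candidates = [c for c in df.columns if c != "time"]
        if not candidates:
            raise FormatError(f"{path}: no fluorescence column beside 'time'")
        sig = candidates[0]
    if sig not in df.columns:
        raise FormatError(f"{path}: fluorescence column {sig!r} not found")
    meta = {
        "subject_id": manifest.pop("subject_id", Path(str(path)).stem),
        "region": manifest.pop("region", "ACC"),
        "fs": manifest.pop("fs", 30.0),
        "assay_label": manifest.pop("assay_label", ""),
        "week": manifest.pop("week", 0),
    }
    return PhotometrySession(t=df["time"].to_numpy(), F=df[sig].to_numpy(), **meta)


def write_session(session: PhotometrySession, path) -> None:
    pd.DataFrame({"time": session.t, "F": session.F}).to_csv(path, index=False)


def read_events(path, clock: str = "photometry") -> EventLog:
    df = _read_csv(path)
    _require(df, ["label", "start", "stop"], path)
    events = list(zip(df["label"].astype(str), df["start"].astype(float), df["stop"].astype(float)))
    return EventLog(events=events, clock=clock)


def write_events(log: EventLog, path) -> None:
    df = pd.DataFrame(log.events, columns=["label", "start", "stop"])
    df.to_csv(path, index=False)


def read_track(path) -> PositionTrack:
    df = _read_csv(path)
    _require(df, ["time", "x", "y"], path)
    return PositionTrack(t=df["time"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy())


def write_track(track: PositionTrack, path) -> None:
    pd.DataFrame({"time": track.t, "x": track.x, "y": track.y}).to_csv(path, index=False)


def read_ztrace(path, fs: float | None = None, source: str = "") -> ZScoredTrace:
    df = _read_csv(path)
    _require(df, ["time", "z"], path)
    t = df["time"].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer fs from < 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ZScoredTrace(t=t, z=df["z"].to_numpy(dtype=float), fs=fs, source=source)


def write_ztrace(trace: ZScoredTrace, path) -> None:
    pd.DataFrame({"time": trace.t, "z": trace.z}).to_csv(path, index=False)


def load_arena(source) -> ArenaGeometry:
    """Load an arena geometry from a YAML file path or a config mapping."""
    if isinstance(source, dict):
        return arena_from_config(source)
    with open(source, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{source}: arena config must be a mapping")
    return arena_from_config(cfg)


def save_arena_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def align_events(
    log: EventLog,
    session: PhotometrySession,
    offset: float = 0.0,
    drift: float = 1.0,
) -> tuple[EventLog, int]:
    """Map an event log onto the photometry sample clock.

    A linear clock map ``t_photometry = offset + drift * t_video`` (default
    identity) is applied, then each boundary is snapped to the nearest
    photometry sample time.  Events that fall entirely outside the session,
    or collapse to zero length after snapping, are dropped.

    Returns the aligned log (``clock='photometry'``) and the number of
    dropped events.  Aligning an already-aligned log with the identity map
    is a no-op.
    """
    if drift <= 0:
        raise ValidationError("drift must be positive")
    t = session.t
    kept: list[tuple[str, float, float]] = []
    dropped = 0
    for label, start, stop in log.events:
        a = offset + drift * start
        b = offset + drift * stop
        if b <= t[0] or a >= t[-1]:
            dropped += 1
            continue
        a_s = _snap(t, a)
        b_s = _snap(t, b)
        if not a_s < b_s:
            dropped += 1
            continue
        kept.append((label, a_s, b_s))
    return EventLog(events=kept, clock="photometry"), dropped


def _snap(t: np.ndarray, value: float) -> float:
    """Nearest sample time to ``value`` (ties broken toward the earlier sample)."""
    i = int(np.searchsorted(t, value))
    if i <= 0:
        return float(t[0])
    if i >= len(t):
        return float(t[-1])
    before, after = t[i - 1], t[i]
    return float(before if value - before <= after - value else after)
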