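"""Open-arm explore/retreat detection and signal-conditioned action probability.

An *explore* is a center-to-open crossing followed by at least
``min_commit`` continuous seconds in the open arm; a *retreat* is an
open-to-center crossing (after a committed open visit) followed by at
least ``min_commit`` seconds out of the open arm.  Sub-threshold
excursions generate no events.

The conditional curve estimates, for samples in a staging zone, the
probability that an event of the given type occurs within a horizon
(default 10 s), binned by the concurrent z-scored signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError, ZoneSeries, ZScoredTrace

__all__ = [
    "detect_transitions",
    "initiation_signal",
    "conditional_event_probability",
    "TransitionEvents",
    "ConditionalCurve",
]


@dataclass
class TransitionEvents:
    """Explore/retreat initiation times (s) on the session clock."""

    explores: np.ndarray
    retreats: np.ndarray
    min_commit: float

    def __post_init__(self) -> None:
        self.explores = np.asarray(self.explores, dtype=float)
        self.retreats = np.asarray(self.retreats, dtype=float)
        for arr, name in ((self.explores, "explores"), (self.retreats, "retreats")):
            if len(arr) > 1 and not (np.diff(arr) > 0).all():
                raise ValidationError(f"{name} must be strictly increasing")

    def times(self, event_type: str) -> np.ndarray:
        if event_type == "explore":
            return self.explores
        if event_type == "retreat":
            return self.retreats
        raise ValidationError("event_type must be 'explore' or 'retreat'")


def _runs(zone: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encoding: list of (label, start_idx, stop_idx) with stop exclusive."""
    runs = []
    start = 0
    for i in range(1, len(zone) + 1):
        if i == len(zone) or zone[i] != zone[start]:
            runs.append((zone[start], start, i))
            start = i
    return runs


def detect_transitions(zones: ZoneSeries, min_commit: float = 1.0) -> TransitionEvents:
    """Find committed open-arm entries (explores) and exits (retreats).

    Initiation is the first sample after the crossing.  An open-arm run
    starting at the session onset can end in a retreat without a preceding
    explore (the animal is placed in the open arm).
    """
    if min_commit < 0:
        raise ValidationError("min_commit must be >= 0")
    if len(zones) == 0:
        return TransitionEvents(np.array([]), np.array([]), min_commit)
    dt = zones.dt
    runs = _runs(zones.zone)
    explores: list[float] = []
    retreats: list[float] = []
    for k, (name, i0, i1) in enumerate(runs):
        if name != "open":
            continue
        dur = (i1 - i0) * dt
        committed = dur >= min_commit
        if committed and k > 0 and runs[k - 1][0] == "center":
            explores.append(float(zones.t[i0]))
        if (committed or k == 0) and k + 1 < len(runs) and runs[k + 1][0] == "center":
            # cumulative continuous time out of the open arm after the exit
            j = k + 1
            out_dur = 0.0
            while j < len(runs) and runs[j][0] != "open":
                out_dur += (runs[j][2] - runs[j][1]) * dt
                j += 1
            if out_dur >= min_commit:
                retreats.append(float(zones.t[runs[k + 1][1]]))
    return TransitionEvents(np.array(explores), np.array(retreats), min_commit)


def initiation_signal(
    z: ZScoredTrace,
    ev: TransitionEvents,
    window: tuple[float, float] = (0.0, 2.0),
) -> tuple[pd.DataFrame, int]:
    """Mean z over ``[t_init + w0, t_init + w1)`` per event.

    Events whose window runs past the session end are dropped and counted.
    Returns a tidy frame (event_type, t_init, mean_z) and the dropped count.
    """
    w0, w1 = window
    if not w0 < w1:
        raise ValidationError("window must satisfy w0 < w1")
    rows = []
    dropped = 0
    for event_type in ("explore", "retreat"):
        for t0 in ev.times(event_type):
            mask = (z.t >= t0 + w0) & (z.t < t0 + w1)
            if t0 + w1 > z.t[-1] + 1.0 / z.fs or not mask.any():
                dropped += 1
                continue
            rows.append({"event_type": event_type, "t_init": float(t0),
                         "mean_z": float(z.z[mask].mean())})
    return pd.DataFrame(rows, columns=["event_type", "t_init", "mean_z"]), dropped


@dataclass
class ConditionalCurve:
    """P(event within horizon | signal bin), with per-bin sample counts."""

    bin_edges: np.ndarray
    p: np.ndarray
    n: np.ndarray
    horizon: float
    event_type: str
    eligible_zone: str

    def __post_init__(self) -> None:
        bad = self.p[~np.isnan(self.p)]
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError("probabilities must lie in [0, 1]")


#: staging zone per event type: explores launch from the centre, retreats from the open arm
ELIGIBLE_ZONE = {"explore": "center", "retreat": "open"}


def conditional_event_probability(
    z: ZScoredTrace,
    zones: ZoneSeries,
    event_times: np.ndarray,
    event_type: str,
    horizon: float = 10.0,
    n_bins: int = 5,
    bin_edges: np.ndarray | None = None,
    subsample_hz: float = 1.0,
    eligible_zone: str | None = None,
) -> ConditionalCurve:
    """Probability of at least one event in ``(t, t + horizon]`` by signal bin.

    Eligible samples are those in the event's staging zone, subsampled at
    ``subsample_hz`` (default 1 Hz, limiting serial dependence) and
    excluding samples within ``horizon`` of the session end.  Bins default
    to within-session z quintiles of the eligible samples.  A success is
    one-or-more events of the type in the look-ahead window (events count
    once).
    """
    if len(z.z) != len(zones):
        raise ValidationError("signal and zone series must have equal length")
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    zone_label = eligible_zone or ELIGIBLE_ZONE.get(event_type)
    if zone_label is None:
        raise ValidationError(f"no staging zone known for event type {event_type!r}")
    step = max(1, int(round(z.fs / subsample_hz)))
    cand = np.arange(0, len(z.z), step)
    cand = cand[zones.zone[cand] == zone_label]
    cand = cand[z.t[cand] + horizon <= z.t[-1] + 1.0 / z.fs]
    if len(cand) == 0:
        return ConditionalCurve(np.array([]), np.array([]), np.array([], dtype=int),
                                horizon, event_type, zone_label)
    et = np.sort(np.asarray(event_times, dtype=float))
    tt = z.t[cand]
    n_after = np.searchsorted(et, tt + horizon, side="right") - np.searchsorted(et, tt, side="right")
    success = n_after > 0
    zvals = z.z[cand]
    if bin_edges is None:
        if n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        qs = np.quantile(zvals, np.linspace(0, 1, n_bins + 1))
        bin_edges = np.unique(qs)
        if len(bin_edges) < 2:  # constant signal: one degenerate bin
            bin_edges = np.array([bin_edges[0] - 0.5, bin_edges[0] + 0.5])
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
    k = len(bin_edges) - 1
    which = np.clip(np.digitize(zvals, bin_edges) - 1, 0, k - 1)
    n = np.bincount(which, minlength=k)
    hits = np.bincount(which, weights=success.astype(float), minlength=k)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return ConditionalCurve(bin_edges=bin_edges, p=p, n=n, horizon=horizon,
                            event_type=event_type, eligible_zone=zone_label)
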