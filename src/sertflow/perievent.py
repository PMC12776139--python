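"""Bout filtering, bout-locked trace extraction, and per-bout summary scores.

Consummatory bouts are merged (same-label events separated by less than a
gap) and then filtered by a minimum duration (1 s for the drinking/eating
assays).  Peri-event rows are time-locked to bout start, normalized to the
mean of a pre-bout baseline window, and summarised as the mean of the
normalized trace over a response window ("mean bout z-score").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EventLog, ValidationError, ZScoredTrace

__all__ = [
    "filter_bouts",
    "extract_peri_event",
    "session_mean_bout_score",
    "aversive_response",
    "PeriEventMatrix",
]

#: defaults (s): window, pre-bout baseline, and response scoring windows
DEFAULT_PRE = 5.0
DEFAULT_POST = 10.0
DEFAULT_BASELINE = (-5.0, 0.0)
DEFAULT_RESPONSE = (0.0, 5.0)


@dataclass
class PeriEventMatrix:
    """Bout-aligned, baseline-normalized traces for one label.

    ``traces`` is (n_bouts x n_samples); each row has mean 0 over the
    baseline window by construction.  ``bout_scores`` is the mean of each
    normalized row over the response window.
    """

    label: str
    window: tuple[float, float]  # (pre, post) seconds
    baseline: tuple[float, float]
    response: tuple[float, float]
    rel_time: np.ndarray
    traces: np.ndarray
    bout_scores: np.ndarray
    bout_starts: np.ndarray
    n_dropped: int = 0
    overlap_flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_bouts(self) -> int:
        return self.traces.shape[0]


def filter_bouts(log: EventLog, min_duration: float = 1.0, merge_gap: float = 0.0) -> EventLog:
    """Merge-then-filter bout intervals, per label.

    Same-label events whose gap (next start minus previous stop) is
    strictly less than ``merge_gap`` are merged first (overlapping events
    always merge); events shorter than ``min_duration`` are then removed.
    ``merge_gap=0, min_duration=0`` is the identity on disjoint input.
    """
    if min_duration < 0 or merge_gap < 0:
        raise ValidationError("min_duration and merge_gap must be >= 0")
    out: list[tuple[str, float, float]] = []
    for label in log.labels:
        merged: list[list[float]] = []
        for start, stop in log.for_label(label):
            if merged and start - merged[-1][1] < merge_gap:
                merged[-1][1] = max(merged[-1][1], stop)
            else:
                merged.append([start, stop])
        for start, stop in merged:
            if stop - start >= min_duration and stop - start > 0:
                out.append((label, start, stop))
    out.sort(key=lambda e: (e[1], e[0]))
    return EventLog(events=out, clock=log.clock)


def _window_indices(rel_time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValidationError(f"window {window} must satisfy lo < hi")
    return (rel_time >= lo) & (rel_time < hi)


def extract_peri_event(
    z: ZScoredTrace,
    log: EventLog,
    label: str,
    pre: float = DEFAULT_PRE,
    post: float = DEFAULT_POST,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    response: tuple[float, float] = DEFAULT_RESPONSE,
) -> PeriEventMatrix:
    """Bout-locked traces normalized to the pre-bout baseline.

    Each retained bout contributes the z-trace over
    ``[t_start - pre, t_start + post)`` minus its baseline-window mean.
    Bouts without full window coverage inside the session are dropped and
    counted (``n_dropped``).  An absent label yields an empty matrix, not
    an error.  Bouts starting inside the previous bout's response window
    are kept but flagged (possible baseline contamination).
    """
    if pre < 0 or post <= 0:
        raise ValidationError("need pre >= 0 and post > 0")
    fs = z.fs
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    rel_time = np.arange(-n_pre, n_post) / fs
    base_mask = _window_indices(rel_time, baseline)
    resp_mask = _window_indices(rel_time, response)
    if not base_mask.any() or not resp_mask.any():
        raise ValidationError("baseline/response windows contain no samples")

    bouts = log.for_label(label)
    rows, starts, flags = [], [], []
    n_dropped = 0
    prev_resp_end = -np.inf
    for start, _stop in bouts:
        idx = int(np.argmin(np.abs(z.t - start)))
        lo, hi = idx - n_pre, idx + n_post
        if lo < 0 or hi > len(z.z):
            n_dropped += 1
            continue
        row = z.z[lo:hi].astype(float)
        row = row - row[base_mask].mean()
        rows.append(row)
        starts.append(start)
        flags.append(start < prev_resp_end)
        prev_resp_end = start + response[1]
    traces = np.vstack(rows) if rows else np.empty((0, n_pre + n_post))
    scores = traces[:, resp_mask].mean(axis=1) if len(rows) else np.array([])
    return PeriEventMatrix(
        label=label, window=(pre, post), baseline=baseline, response=response,
        rel_time=rel_time, traces=traces, bout_scores=scores,
        bout_starts=np.asarray(starts, dtype=float), n_dropped=n_dropped,
        overlap_flags=np.asarray(flags, dtype=bool),
    )


def session_mean_bout_score(m: PeriEventMatrix) -> float:
    """Arithmetic mean of per-bout scores; NaN (flagged missing) when no bouts."""
    if m.n_bouts == 0:
        return float("nan")
    return float(m.bout_scores.mean())


def bout_score_table(
    matrices: dict[tuple, PeriEventMatrix],
    keys: tuple[str, ...] = ("subject", "week", "tastant"),
) -> pd.DataFrame:
    """Tidy (one row per key combination) table of session mean bout scores."""
    rows = []
    for key, m in matrices.items():
        row = dict(zip(keys, key))
        row["bout_score"] = session_mean_bout_score(m)
        row["n_bouts"] = m.n_bouts
        rows.append(row)
    return pd.DataFrame(rows)


def aversive_response(
    z: ZScoredTrace,
    log: EventLog,
    label: str,
    window: tuple[float, float] = (0.0, 60.0),
    baseline: tuple[float, float] = (-60.0, 0.0),
    anchor: str | None = None,
) -> float:
    """Mean baseline-normalized z over a post-event window, for a single event.

    The response window is anchored at the event start for ``splash`` and
    at the event stop (release) for ``scruff``; the baseline window is
    always relative to the event start (pre-onset).  Exactly one event
    with the label must be present.
    """
    events = log.for_label(label)
    if len(events) != 1:
        raise ValidationError(f"expected exactly one {label!r} event, found {len(events)}")
    start, stop = events[0]
    if anchor is None:
        anchor = "stop" if label == "scruff" else "start"
    t0 = stop if anchor == "stop" else start
    base = (z.t >= start + baseline[0]) & (z.t < start + baseline[1])
    resp = (z.t >= t0 + window[0]) & (z.t < t0 + window[1])
    if not resp.any():
        raise ValidationError("response window contains no samples")
    base_mean = float(z.z[base].mean()) if base.any() else 0.0
    return float(z.z[resp].mean() - base_mean)
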