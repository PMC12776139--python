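"""Drip-corrected alcohol/water intake for limited-access drinking sessions.

Intake is computed from bottle volumes (or masses converted via density):
``consumed_ml = max(pre - post - drip, 0)`` with the empty-cage drip
control subtracted, then normalized to body mass:
``g/kg = consumed_ml * etoh_fraction * etoh_density / (body_mass_kg)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = ["DrinkingRecord", "IntakeResult", "session_intake", "schedule_check", "stim_comparison"]

ETOH_DENSITY = 0.789  # g/ml at room temperature


@dataclass
class DrinkingRecord:
    """One bottle measurement for one session."""

    subject_id: str
    pre: float  # ml before the session
    post: float  # ml after the session
    drip: float = 0.0  # ml lost from the empty-cage control bottle
    body_mass: float = 25.0  # g
    bottle: str = "alcohol"
    side: str = "L"
    session: int = 0
    etoh_fraction: float = 0.20  # v/v
    session_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.bottle not in ("alcohol", "water"):
            raise ValidationError("bottle must be 'alcohol' or 'water'")
        if self.drip < 0:
            raise ValidationError("drip must be >= 0")
        if not 0 < self.etoh_fraction <= 1:
            raise ValidationError("etoh_fraction must be in (0, 1]")


@dataclass
class IntakeResult:
    consumed_ml: float
    g_per_kg: float | None  # None for water bottles (ml only)
    flags: list[str] = field(default_factory=list)


def session_intake(rec: DrinkingRecord, etoh_density: float = ETOH_DENSITY) -> IntakeResult:
    """Drip-corrected intake for one record.

    ``post > pre`` (an apparent refill) yields zero intake with a
    ``refill`` flag; drip larger than the measured loss clips intake to
    zero with a ``drip_clipped`` flag.
    """
    if rec.body_mass <= 0:
        raise ValidationError("body_mass must be positive")
    flags: list[str] = []
    delta = rec.pre - rec.post
    if delta < 0:
        flags.append("refill")
        delta = 0.0
    consumed = delta - rec.drip
    if consumed < 0:
        if "refill" not in flags:
            flags.append("drip_clipped")
        consumed = 0.0
    if rec.bottle == "water":
        return IntakeResult(consumed_ml=consumed, g_per_kg=None, flags=flags)
    g_per_kg = consumed * rec.etoh_fraction * etoh_density / (rec.body_mass / 1000.0)
    return IntakeResult(consumed_ml=consumed, g_per_kg=float(g_per_kg), flags=flags)


def intake_table(records: pd.DataFrame, etoh_density: float = ETOH_DENSITY) -> pd.DataFrame:
    """Vectorized :func:`session_intake` over a tidy drinking log."""
    out = records.copy()
    results = [
        session_intake(
            DrinkingRecord(
                subject_id=str(r.get("subject", r.get("subject_id", ""))),
                pre=float(r["pre"]), post=float(r["post"]), drip=float(r.get("drip", 0.0)),
                body_mass=float(r.get("body_mass", 25.0)), bottle=str(r.get("bottle", "alcohol")),
                side=str(r.get("side", "L")), session=int(r.get("session", 0)),
                etoh_fraction=float(r.get("etoh_fraction", 0.20)),
                session_hours=float(r.get("session_hours", 2.0)),
            ),
            etoh_density,
        )
        for _, r in records.iterrows()
    ]
    out["consumed_ml"] = [r.consumed_ml for r in results]
    out["g_per_kg"] = [r.g_per_kg if r.g_per_kg is not None else np.nan for r in results]
    out["flags"] = [";".join(r.flags) for r in results]
    return out


#: limited-access weekly schedule: 2 h Mon-Wed, 4 h Thu
WEEKLY_HOURS = (2.0, 2.0, 2.0, 4.0)


def schedule_check(records: pd.DataFrame) -> list[str]:
    """Verify the weekly session-hours pattern and bottle-side alternation.

    ``records`` needs columns ``subject``, ``session`` (0-based index),
    ``session_hours``, ``side``.  Returns a list of human-readable
    violations (empty for a conforming log).
    """
    violations: list[str] = []
    for subject, grp in records.sort_values("session").groupby("subject"):
        grp = grp.reset_index(drop=True)
        prev_side = None
        for _, row in grp.iterrows():
            expected = WEEKLY_HOURS[int(row["session"]) % len(WEEKLY_HOURS)]
            if float(row["session_hours"]) != expected:
                violations.append(
                    f"{subject} session {int(row['session'])}: {row['session_hours']} h, expected {expected} h"
                )
            if prev_side is not None and row["side"] == prev_side:
                violations.append(
                    f"{subject} session {int(row['session'])}: bottle side {row['side']} not alternated"
                )
            prev_side = row["side"]
    return violations


def stim_comparison(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Paired baseline-vs-stimulation intake table for the stats layer.

    ``table`` needs columns ``subject``, ``condition`` (``BL``/``Stim``),
    ``g_per_kg`` and optionally ``order``.  Subjects missing either
    condition are excluded and counted.
    """
    required = {"subject", "condition", "g_per_kg"}
    if not required <= set(table.columns):
        raise ValidationError(f"need columns {sorted(required)}")
    wide = table.pivot_table(index="subject", columns="condition", values="g_per_kg", aggfunc="mean")
    complete = wide.dropna(subset=["BL", "Stim"]) if {"BL", "Stim"} <= set(wide.columns) else wide.iloc[:0]
    excluded = len(wide) - len(complete)
    out = complete.reset_index()[["subject", "BL", "Stim"]].copy()
    out["diff"] = out["Stim"] - out["BL"]
    if "order" in table.columns:
        orders = table.groupby("subject")["order"].first()
        out["order"] = out["subject"].map(orders)
    return out, excluded
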