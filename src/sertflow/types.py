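"""Core data containers for photometry, behavior events, and position tracks.

The containers are deliberately thin: validated numpy arrays plus the
metadata the downstream analyses need (sampling rate, subject, recording
site, assay, week of alcohol history).  Time is always in seconds,
positions in centimetres in the arena frame, fluorescence in arbitrary
detector units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """A file or table does not have the expected layout."""


class ValidationError(ValueError):
    """Data violates a container invariant."""


REGIONS = ("ACC", "CeA")
CLOCKS = ("photometry", "video")


@dataclass
class PhotometrySession:
    """One fluorescence channel recorded from one fiber/region.

    Parameters
    ----------
    subject_id : str
        Animal identifier.
    region : str
        Recording site, one of ``ACC`` or ``CeA``.
    t : array of float
        Sample times in seconds, strictly increasing, no NaN.
    F : array of float
        Raw fluorescence (a.u.), same length as ``t``.
    fs : float
        Nominal sampling rate in Hz (30 for the sensor rig).  The median
        sampling interval must be within 10% of ``1/fs``.
    assay_label : str
        Free-text assay tag (``consummatory``, ``EPM``, ...).
    week : int
        Weeks of drinking history at recording time (>= 0).
    """

    subject_id: str
    region: str
    t: np.ndarray
    F: np.ndarray
    fs: float = 30.0
    assay_label: str = ""
    week: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.t.ndim != 1 or self.F.ndim != 1:
            raise ValidationError("t and F must be 1-D arrays")
        if len(self.t) != len(self.F):
            raise ValidationError("t and F must have equal length")
        if len(self.t) < 2:
            raise ValidationError("a session needs at least 2 samples")
        if np.isnan(self.t).any():
            raise ValidationError("t contains NaN")
        dt = np.diff(self.t)
        if not (dt > 0).all():
            raise ValidationError("t must be strictly increasing")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        med = float(np.median(dt))
        if abs(med - 1.0 / self.fs) > 0.1 / self.fs:
            raise ValidationError(
                f"median sampling interval {med:.5f}s is not within 10% of 1/fs={1.0 / self.fs:.5f}s"
            )
        if self.week < 0:
            raise ValidationError("week must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Session duration counted as n_samples sampling periods."""
        return self.n_samples / self.fs


@dataclass
class EventLog:
    """Labeled behavior intervals ``(label, start, stop)`` on one clock.

    Intervals are half-open ``[start, stop)`` seconds.  ``clock`` says
    whether times are on the photometry sample clock or the video clock;
    analyses require the photometry clock (see :func:`sertflow.io.align_events`).
    """

    events: list[tuple[str, float, float]] = field(default_factory=list)
    clock: str = "photometry"

    def __post_init__(self) -> None:
        if self.clock not in CLOCKS:
            raise ValidationError(f"clock must be one of {CLOCKS}, got {self.clock!r}")
        self.events = [(str(l), float(a), float(b)) for l, a, b in self.events]
        for label, start, stop in self.events:
            if not start < stop:
                raise ValidationError(f"event {label!r}: start {start} must be < stop {stop}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def labels(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: list[str] = []
        for label, _, _ in self.events:
            if label not in seen:
                seen.append(label)
        return seen

    def for_label(self, label: str) -> list[tuple[float, float]]:
        """Intervals with the given label, sorted by start."""
        ivs = [(a, b) for l, a, b in self.events if l == label]
        return sorted(ivs)


@dataclass
class PositionTrack:
    """Single-point (body centre) position samples in arena coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) >= 2 and not (np.diff(self.t) > 0).all():
            raise ValidationError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        if len(self.t) < 2:
            raise ValidationError("cannot infer sampling rate from < 2 samples")
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class ZScoredTrace:
    """Within-session z-scored fluorescence.

    Output of :func:`sertflow.signal.zscore_session` satisfies
    ``mean(z) == 0`` and ``SD(z) == 1`` (population SD) to 1e-9 over the
    full session.  The container itself does not re-check this so that
    derived traces (downsampled, simulated in z-units) can be represented.
    """

    t: np.ndarray
    z: np.ndarray
    fs: float
    source: str = ""
    detrend_params: dict | None = None
    detrend_fallback: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.t) != len(self.z):
            raise ValidationError("t and z must have equal length")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ZoneSeries:
    """Arena zone label per position sample."""

    t: np.ndarray
    zone: np.ndarray  # array of str labels
    arena_kind: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.zone = np.asarray(self.zone, dtype=object)
        if len(self.t) != len(self.zone):
            raise ValidationError("t and zone must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValidationError("cannot infer sampling period from < 2 samples")
        return float(np.median(np.diff(self.t)))
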