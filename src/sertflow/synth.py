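"""Synthetic photometry cohort generator with known ground truth.

Emulates the structure of the real recordings so every pipeline stage can
be verified against injected parameters:

* 30 Hz fluorescence with a double-exponential photobleaching baseline and
  a multiplicative event/zone signal: ``F(t) = B(t) * (1 + s(t)) + eps(t)``
  where ``s(t)`` is the fractional (dF/F-like) serotonin signal and
  ``eps`` is Gaussian detector noise.
* Event-locked transients shaped as an alpha function normalized to its
  peak, so the injected amplitude ``A`` is exactly the transient maximum.
  Default sign conventions follow the recorded motifs: consummatory bouts
  suppress the ACC signal (A < 0) and elevate the CeA signal (A > 0);
  aversive events (splash, scruff) elevate both.
* Zone-dependent tonic offsets (e.g. elevated signal in the EPM open arm).
* Position tracks inside the arena as a Gaussian random walk with optional
  mean reversion, kept in the arena and biased across zones by a
  Metropolis accept/reject step whose stationary occupancy is
  proportional to ``dwell_bias[zone] * area(zone)``.
* Explore/retreat action events drawn per sample from a logistic hazard
  ``P(event) = logistic(b0 + b1 * z)`` on the concurrent signal.
* A full cohort (sex x group x week) with injected group effects recorded
  verbatim in the ground-truth manifest.

All generators are pure functions of (config, seed): a fixed seed gives a
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .arenas import ArenaGeometry, epm_arena, oft_arena, zone_lookup_grid
from .types import EventLog, PhotometrySession, PositionTrack, ValidationError, ZoneSeries

__all__ = [
    "Bleach",
    "GroundTruth",
    "alpha_kernel",
    "event_signal",
    "noiseless_signal",
    "simulate_photometry",
    "simulate_track",
    "simulate_actions",
    "CohortDesign",
    "simulate_cohort",
]


@dataclass
class Bleach:
    """Double-exponential photobleaching baseline ``B(t) = b0*(a1*e^(-t/tau1) + a2*e^(-t/tau2))``.

    With ``a1 + a2 == 1`` the trace starts at ``b0``.  Long time constants
    relative to the transient width (>= 10x) keep the baseline locally flat
    so peri-event normalization is unbiased.
    """

    b0: float = 200.0
    a1: float = 0.6
    tau1: float = 600.0
    a2: float = 0.4
    tau2: float = 3000.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValidationError("bleach time constants must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.b0 * (self.a1 * np.exp(-t / self.tau1) + self.a2 * np.exp(-t / self.tau2))


def alpha_kernel(tau: np.ndarray, tau_r: float) -> np.ndarray:
    """Peak-normalized alpha transient ``k(tau) = (tau/tau_r) * e^(1 - tau/tau_r)`` for tau >= 0.

    The maximum is exactly 1, at ``tau == tau_r``, so an event of amplitude
    ``A`` contributes a transient whose peak is exactly ``A``.
    """
    if tau_r <= 0:
        raise ValidationError("tau_r must be positive")
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    m = tau >= 0
    out[m] = (tau[m] / tau_r) * np.exp(1.0 - tau[m] / tau_r)
    return out


@dataclass
class GroundTruth:
    """Generator parameters for one session; the recovery oracle for the pipeline.

    ``amplitudes`` maps event labels to transient peak amplitudes in
    fractional dF/F units (the "z-unit" scale of the noiseless signal);
    ``zone_offsets`` adds a tonic offset while the animal occupies a zone;
    ``hazards`` holds per-action logistic coefficients ``(b0, b1)``;
    ``noise_sd`` is detector noise in fluorescence a.u.
    """

    amplitudes: dict[str, float] = field(default_factory=dict)
    tau_r: float = 1.0
    bleach: Bleach = field(default_factory=Bleach)
    zone_offsets: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 2.0
    hazards: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"explore": (-6.0, -1.0), "retreat": (-6.5, 1.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_r <= 0:
            raise ValidationError("tau_r must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def event_signal(
    t: np.ndarray, events: EventLog | list, amplitudes: dict[str, float], tau_r: float
) -> np.ndarray:
    """Sum of peak-normalized transients, one per event, scaled per label."""
    t = np.asarray(t, dtype=float)
    s = np.zeros_like(t)
    evs = events.events if isinstance(events, EventLog) else list(events)
    for label, start, _stop in evs:
        A = amplitudes.get(label, 0.0)
        if A == 0.0:
            continue
        s += A * alpha_kernel(t - start, tau_r)
    return s


def noiseless_signal(
    gt: GroundTruth,
    t: np.ndarray,
    events: EventLog | list | None = None,
    zones: ZoneSeries | None = None,
) -> np.ndarray:
    """The fractional signal ``s(t)``: transients plus zone tonic offsets."""
    t = np.asarray(t, dtype=float)
    s = np.zeros_like(t)
    if events is not None:
        s += event_signal(t, events, gt.amplitudes, gt.tau_r)
    if zones is not None and gt.zone_offsets:
        if len(zones) != len(t):
            raise ValidationError("zone series must align with the time grid")
        offsets = np.array([gt.zone_offsets.get(z, 0.0) for z in zones.zone])
        s += offsets
    return s


def simulate_photometry(
    gt: GroundTruth,
    events: EventLog | list | None,
    duration: float,
    fs: float = 30.0,
    zones: ZoneSeries | None = None,
    subject_id: str = "sim",
    region: str = "ACC",
    assay_label: str = "synthetic",
    week: int = 0,
    seed: int | None = None,
) -> PhotometrySession:
    """Generate ``F(t) = B(t)*(1 + s(t)) + eps`` on a regular grid.

    Deterministic under a fixed seed (``gt.seed`` unless overridden).
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValidationError("duration too short for the sampling rate")
    t = np.arange(n) / fs
    if events is not None:
        evs = events.events if isinstance(events, EventLog) else list(events)
        for label, start, stop in evs:
            if start < 0 or start >= duration:
                raise ValidationError(f"event {label!r} at {start}s outside [0, {duration})")
    s = noiseless_signal(gt, t, events, zones)
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    F = gt.bleach(t) * (1.0 + s)
    if gt.noise_sd > 0:
        F = F + rng.normal(0.0, gt.noise_sd, n)
    return PhotometrySession(
        subject_id=subject_id, region=region, t=t, F=F, fs=fs,
        assay_label=assay_label, week=week,
    )


def simulate_track(
    arena: ArenaGeometry,
    duration: float,
    fs: float = 30.0,
    dwell_bias: dict[str, float] | None = None,
    seed: int = 0,
    step_sd: float = 8.0,
    mean_reversion: float = 0.0,
    start: tuple[float, float] | None = None,
) -> PositionTrack:
    """Biased random walk inside the arena.

    Per step the proposal is ``x' = x + theta*(centre - x)*dt + N(0, step_sd*sqrt(dt))``;
    proposals leaving the arena are rejected (the walker stays put), and
    zone changes are accepted with Metropolis probability
    ``min(1, w(zone') / w(zone))``.  The stationary occupancy of zone ``Z``
    is therefore proportional to ``dwell_bias[Z] * area(Z)`` (exactly
    uniform-within-zone for ``mean_reversion == 0``, the default).

    ``duration == 0`` returns an empty track.
    """
    if arena.floor.area <= 0:
        raise ValidationError("arena has zero area")
    weights = {z: 1.0 for z in arena.zones}
    if dwell_bias:
        weights.update({k: float(v) for k, v in dwell_bias.items()})
    if any(w <= 0 for w in weights.values()):
        raise ValidationError("dwell-bias weights must be positive")
    n = int(round(duration * fs))
    if n == 0:
        return PositionTrack(t=np.array([]), x=np.array([]), y=np.array([]))
    labels, grid, xmin, ymin, res = zone_lookup_grid(arena)
    wvec = np.array([weights[l] for l in labels])
    nx, ny = grid.shape
    dt = 1.0 / fs
    sd = step_sd * np.sqrt(dt)
    cx, cy = arena.floor.centroid.x, arena.floor.centroid.y
    rng = np.random.default_rng(seed)
    if start is None:
        # start at the first arena cell at/after the centroid, so the walk
        # begins inside the floor even for non-convex (plus-shaped) arenas
        ci = min(int((cx - xmin) / res), nx - 1)
        cj = min(int((cy - ymin) / res), ny - 1)
        if grid[ci, cj] < 0:
            inside = np.argwhere(grid >= 0)
            d2 = (inside[:, 0] - ci) ** 2 + (inside[:, 1] - cj) ** 2
            ci, cj = inside[int(np.argmin(d2))]
        x0 = xmin + (ci + 0.5) * res
        y0 = ymin + (cj + 0.5) * res
    else:
        x0, y0 = float(start[0]), float(start[1])

    def cell(x, y):
        if x < xmin or y < ymin:
            return -1
        i = int((x - xmin) / res)
        j = int((y - ymin) / res)
        if i >= nx or j >= ny:
            return -1
        return grid[i, j]

    z0 = cell(x0, y0)
    if z0 < 0:
        raise ValidationError("start position is outside the arena")
    xs = np.empty(n)
    ys = np.empty(n)
    steps = rng.normal(0.0, sd, size=(n, 2))
    accepts = rng.random(n)
    x, y, zi = x0, y0, z0
    for i in range(n):
        xs[i], ys[i] = x, y
        px = x + mean_reversion * (cx - x) * dt + steps[i, 0]
        py = y + mean_reversion * (cy - y) * dt + steps[i, 1]
        zj = cell(px, py)
        if zj < 0:
            continue
        if zj == zi or accepts[i] < wvec[zj] / wvec[zi]:
            x, y, zi = px, py, zj
    t = np.arange(n) / fs
    return PositionTrack(t=t, x=xs, y=ys)


def simulate_actions(
    zones: ZoneSeries,
    signal: np.ndarray,
    hazards: dict[str, tuple[float, float]],
    seed: int = 0,
    eligible_zone: dict[str, str] | None = None,
) -> EventLog:
    """Draw action events from per-sample logistic hazards on the signal.

    For each action label, samples in its eligible zone (default: explore
    from ``center``, retreat from ``open``) fire independently with
    probability ``logistic(b0 + b1 * z)``.  Each event occupies one sample
    period.  The sign of ``b1`` is configurable per action.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(zones):
        raise ValidationError("signal and zone series must have equal length")
    eligible_zone = eligible_zone or {"explore": "center", "retreat": "open"}
    dt = zones.dt
    events: list[tuple[str, float, float]] = []
    for k, (action, (b0, b1)) in enumerate(sorted(hazards.items())):
        rng = np.random.default_rng([seed, k])
        mask = zones.zone == eligible_zone.get(action, "")
        p = expit(b0 + b1 * signal)
        fire = (rng.random(len(signal)) < p) & mask
        for i in np.flatnonzero(fire):
            events.append((action, float(zones.t[i]), float(zones.t[i]) + dt))
    events.sort(key=lambda e: (e[1], e[0]))
    return EventLog(events=events, clock="photometry")


def expected_bout_scores(
    gt: GroundTruth,
    events: EventLog,
    label: str,
    duration: float,
    fs: float = 30.0,
    zones: ZoneSeries | None = None,
    **peri_kwargs,
) -> np.ndarray:
    """Ground-truth bout scores on the session z scale (noise-free oracle).

    Within-session z-scoring makes recovered amplitudes identifiable only
    up to the session SD, so the oracle applies the same normalization to
    the known signal: the ideal detrended trace is ``B(t) * s(t)``, which
    is z-scored and run through the peri-event normalization.  A perfect
    pipeline recovers exactly these scores; detrend-fit error is the only
    residual discrepancy on noiseless data.
    """
    from .perievent import extract_peri_event
    from .signal import zscore
    from .types import ZScoredTrace

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    s = noiseless_signal(gt, t, events, zones)
    residual_true = gt.bleach(t) * s
    ztrue = ZScoredTrace(t=t, z=zscore(residual_true), fs=fs, source="ground-truth")
    return extract_peri_event(ztrue, events, label, **peri_kwargs).bout_scores


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: default transient amplitudes per region: consummatory bouts suppress the
#: ACC signal and elevate the CeA signal; aversive events elevate both.
DEFAULT_AMPLITUDES = {
    "ACC": {"alcohol": -0.8, "sucrose": -0.8, "hfd": -0.6, "splash": 1.0, "scruff": 1.0},
    "CeA": {"alcohol": 0.8, "sucrose": 0.8, "hfd": 0.6, "splash": 0.2, "scruff": 1.0},
}

#: EPM tonic offsets scale with zone aversiveness (both regions).
DEFAULT_EPM_OFFSETS = {"open": 0.8, "center": 0.4, "closed": 0.0}
#: OFT offsets: elevated signal in the anxiogenic centre.
DEFAULT_OFT_OFFSETS = {"center": 0.5, "edge": 0.2, "corner": 0.0}


@dataclass
class Effect:
    """An injected group effect: an additive shift of one transient amplitude.

    ``sex is None`` applies to both sexes.  The shift is in the same
    fractional signal units as the base amplitude (e.g. +0.5 on an ACC
    alcohol amplitude of -0.8 blunts the suppression to -0.3).
    """

    group: str
    week: int
    label: str
    region: str
    shift: float
    sex: str | None = None


@dataclass
class CohortDesign:
    """Study design: cohort cells, schedule, session parameters, injected effects.

    Defaults mirror the recorded cohort: 10 male / 10 female binge-drinking
    (DID) mice and 10 male / 9 female water controls, consummatory
    recordings in the naive state and after 1 and 4 weeks of drinking, one
    OFT (week 0), one EPM and one splash/scruff session (week 4), and
    drinking logs for the DID group.  The default injected effects are the
    headline week-1 adaptations: ACC alcohol suppression blunted (+0.5,
    both sexes) and male CeA alcohol response augmented (+0.4).
    """

    n_per_cell: dict[str, int] = field(
        default_factory=lambda: {"male:water": 10, "male:DID": 10, "female:water": 9, "female:DID": 10}
    )
    weeks: tuple[int, ...] = (0, 1, 4)
    fs: float = 30.0
    consummatory_duration: float = 600.0
    epm_duration: float = 600.0
    oft_duration: float = 600.0
    splash_scruff_duration: float = 600.0
    assays: tuple[str, ...] = ("consummatory", "oft", "epm", "splash_scruff", "did")
    noise_sd: float = 2.0
    subject_scale_sd: float = 0.15
    effects: list[Effect] = field(
        default_factory=lambda: [
            Effect(group="DID", week=1, label="alcohol", region="ACC", shift=0.5),
            Effect(group="DID", week=1, label="alcohol", region="CeA", shift=0.4, sex="male"),
        ]
    )

    def cells(self) -> list[tuple[str, str, int]]:
        out = []
        for key, n in sorted(self.n_per_cell.items()):
            sex, group = key.split(":")
            out.append((sex, group, int(n)))
        return out


def _amplitudes_for(design: CohortDesign, region: str, sex: str, group: str, week: int,
                    subject_scale: float) -> dict[str, float]:
    amps = dict(DEFAULT_AMPLITUDES[region])
    for eff in design.effects:
        if eff.region != region or eff.group != group or eff.week != week:
            continue
        if eff.sex is not None and eff.sex != sex:
            continue
        if eff.label in amps:
            amps[eff.label] = amps[eff.label] + eff.shift
    return {k: v * subject_scale for k, v in amps.items()}


def _consummatory_events(rng: np.random.Generator, duration: float) -> EventLog:
    """2-3 bouts each of alcohol, sucrose, and high-fat diet, in that order."""
    events = []
    labels = ["alcohol", "sucrose", "hfd"]
    third = duration / 3.0
    head = min(20.0, 0.15 * third)
    tail = min(40.0, 0.35 * third)
    sep = min(25.0, 0.2 * third)
    max_dur = min(8.0, 0.05 * third)
    for k, label in enumerate(labels):
        n_bouts = int(rng.integers(2, 4))
        lo, hi = k * third + head, (k + 1) * third - tail
        # one bout per slot, jittered, so spacing >= sep and stops stay in range
        slot = (hi - lo) / n_bouts
        jitter = max(slot - sep, 0.1 * slot)
        starts = lo + slot * np.arange(n_bouts) + rng.uniform(0, jitter, n_bouts)
        for s in starts:
            events.append((label, float(s), float(s) + float(rng.uniform(1.5, max(max_dur, 2.0)))))
    return EventLog(events=events, clock="photometry")


def _subject_seed(master: int, idx: int, week: int, assay: str, region: str) -> list[int]:
    # zlib.crc32 is stable across processes (unlike built-in str hash)
    import zlib

    return [
        int(master) % (2**31),
        idx,
        week,
        zlib.crc32(assay.encode()) % (2**31),
        zlib.crc32(region.encode()) % (2**31),
    ]


@dataclass
class SubjectData:
    subject_id: str
    sex: str
    group: str
    scale: dict[str, float]  # per-region subject amplitude multiplier


@dataclass
class CohortData:
    """In-memory synthetic study plus its ground-truth manifest."""

    design: CohortDesign
    subjects: list[SubjectData]
    sessions: dict  # (subject_id, week, assay, region) -> PhotometrySession
    events: dict  # (subject_id, week, assay) -> EventLog
    tracks: dict  # (subject_id, assay) -> PositionTrack
    drinking: "object"  # pandas DataFrame of drinking records
    tracing: "object"  # pandas DataFrame of intensity replicates
    manifest: dict


def simulate_cohort(design: CohortDesign | None = None, seed: int = 0) -> CohortData:
    """Generate the full synthetic study for a design, keyed by one master seed."""
    import pandas as pd

    design = design or CohortDesign()
    master = int(seed) % (2**31)
    rng = np.random.default_rng([master, 999])
    subjects: list[SubjectData] = []
    idx = 0
    for sex, group, n in design.cells():
        for _ in range(n):
            scale = {
                r: float(max(0.2, 1.0 + rng.normal(0.0, design.subject_scale_sd)))
                for r in ("ACC", "CeA")
            }
            subjects.append(SubjectData(subject_id=f"m{idx:03d}", sex=sex, group=group, scale=scale))
            idx += 1

    sessions: dict = {}
    events: dict = {}
    tracks: dict = {}
    truth_amps: list[dict] = []

    epm = epm_arena()
    oft = oft_arena()
    from .spatial import assign_zones  # local import to avoid a cycle

    for i, sub in enumerate(subjects):
        if "consummatory" in design.assays:
            for week in design.weeks:
                ev_rng = np.random.default_rng(_subject_seed(master, i, week, "bouts", "NA"))
                log = _consummatory_events(ev_rng, design.consummatory_duration)
                events[(sub.subject_id, week, "consummatory")] = log
                for region in ("ACC", "CeA"):
                    amps = _amplitudes_for(design, region, sub.sex, sub.group, week, sub.scale[region])
                    gt = GroundTruth(amplitudes=amps, noise_sd=design.noise_sd)
                    ses = simulate_photometry(
                        gt, log, design.consummatory_duration, design.fs,
                        subject_id=sub.subject_id, region=region,
                        assay_label="consummatory", week=week,
                        seed=_subject_seed(master, i, week, "consummatory", region),
                    )
                    sessions[(sub.subject_id, week, "consummatory", region)] = ses
                    truth_amps.append(
                        {"subject": sub.subject_id, "sex": sub.sex, "group": sub.group,
                         "week": week, "region": region,
                         **{f"A_{k}": v for k, v in amps.items() if k in ("alcohol", "sucrose", "hfd")}}
                    )

        if "oft" in design.assays:
            week = design.weeks[0]
            track = simulate_track(
                oft, design.oft_duration, design.fs,
                dwell_bias={"corner": 3.0, "edge": 1.5, "center": 1.0},
                seed=int(np.random.default_rng(_subject_seed(master, i, week, "oft_track", "NA")).integers(2**31)),
            )
            tracks[(sub.subject_id, "oft")] = track
            zones = assign_zones(track, oft)
            for region in ("ACC", "CeA"):
                gt = GroundTruth(amplitudes={}, zone_offsets=DEFAULT_OFT_OFFSETS,
                                 noise_sd=design.noise_sd)
                sessions[(sub.subject_id, week, "oft", region)] = simulate_photometry(
                    gt, None, design.oft_duration, design.fs, zones=zones,
                    subject_id=sub.subject_id, region=region, assay_label="oft", week=week,
                    seed=_subject_seed(master, i, week, "oft", region),
                )

        if "epm" in design.assays:
            week = design.weeks[-1]
            track = simulate_track(
                epm, design.epm_duration, design.fs,
                dwell_bias={"closed": 3.0, "center": 1.0, "open": 0.7},
                seed=int(np.random.default_rng(_subject_seed(master, i, week, "epm_track", "NA")).integers(2**31)),
            )
            tracks[(sub.subject_id, "epm")] = track
            zones = assign_zones(track, epm)
            gt = GroundTruth(amplitudes={}, zone_offsets=DEFAULT_EPM_OFFSETS,
                             noise_sd=design.noise_sd)
            s = noiseless_signal(gt, track.t, None, zones)
            s_std = (s - s.mean()) / (s.std() or 1.0)
            act_seed = int(np.random.default_rng(_subject_seed(master, i, week, "actions", "NA")).integers(2**31))
            events[(sub.subject_id, week, "epm_actions")] = simulate_actions(
                zones, s_std, gt.hazards, seed=act_seed)
            for region in ("ACC", "CeA"):
                sessions[(sub.subject_id, week, "epm", region)] = simulate_photometry(
                    gt, None, design.epm_duration, design.fs, zones=zones,
                    subject_id=sub.subject_id, region=region, assay_label="epm", week=week,
                    seed=_subject_seed(master, i, week, "epm", region),
                )

        if "splash_scruff" in design.assays:
            week = design.weeks[-1]
            dur = design.splash_scruff_duration
            log = EventLog(events=[("splash", 0.3 * dur, 0.3 * dur + 1.0),
                                   ("scruff", 0.7 * dur - 60.0, 0.7 * dur)],
                           clock="photometry")
            events[(sub.subject_id, week, "splash_scruff")] = log
            for region in ("ACC", "CeA"):
                amps = _amplitudes_for(design, region, sub.sex, sub.group, week, sub.scale[region])
                amps = {k: v for k, v in amps.items() if k in ("splash", "scruff")}
                gt = GroundTruth(amplitudes=amps, tau_r=10.0, noise_sd=design.noise_sd)
                sessions[(sub.subject_id, week, "splash_scruff", region)] = simulate_photometry(
                    gt, log, dur, design.fs,
                    subject_id=sub.subject_id, region=region,
                    assay_label="splash_scruff", week=week,
                    seed=_subject_seed(master, i, week, "splash_scruff", region),
                )

    drinking = None
    if "did" in design.assays:
        rows = []
        for i, sub in enumerate(subjects):
            if sub.group != "DID":
                continue
            drng = np.random.default_rng(_subject_seed(master, i, 0, "did", "NA"))
            body = float(drng.normal(27.0, 1.5) if sub.sex == "male" else drng.normal(22.0, 1.2))
            sex_factor = 1.25 if sub.sex == "female" else 1.0
            s_idx = 0
            for week in range(1, 5):
                for day in range(4):
                    hours = 4.0 if day == 3 else 2.0
                    consumed = max(0.0, float(drng.normal(0.55, 0.12)) * hours * sex_factor)
                    drip = float(drng.uniform(0.05, 0.2))
                    rows.append({
                        "subject": sub.subject_id, "sex": sub.sex, "group": sub.group,
                        "week": week, "day": day, "session": s_idx,
                        "bottle": "alcohol", "side": "L" if s_idx % 2 == 0 else "R",
                        "pre": 10.0, "post": 10.0 - consumed - drip, "drip": drip,
                        "body_mass": body, "etoh_fraction": 0.20, "session_hours": hours,
                    })
                    s_idx += 1
        import pandas as pd  # noqa: F811
        drinking = pd.DataFrame(rows)

    tracing = _simulate_tracing(master)

    manifest = {
        "seed": master,
        "design": {
            "n_per_cell": dict(design.n_per_cell),
            "weeks": list(design.weeks),
            "fs": design.fs,
            "assays": list(design.assays),
            "noise_sd": design.noise_sd,
            "subject_scale_sd": design.subject_scale_sd,
        },
        "effects": [asdict(e) for e in design.effects],
        "base_amplitudes": {r: dict(a) for r, a in DEFAULT_AMPLITUDES.items()},
        "epm_zone_offsets": dict(DEFAULT_EPM_OFFSETS),
        "oft_zone_offsets": dict(DEFAULT_OFT_OFFSETS),
        "subject_amplitudes": truth_amps,
    }
    return CohortData(design=design, subjects=subjects, sessions=sessions, events=events,
                      tracks=tracks, drinking=drinking, tracing=tracing, manifest=manifest)


#: per-region mean labeling intensity (a.u.) by serotonergic source nucleus;
#: loosely follows the observed projection split (median raphe dominates the
#: ACC, dorsal raphe dominates the CeA, several targets mixed)
TRACING_PROFILE = {
    "ACC": (90.0, 30.0), "RSC": (80.0, 35.0), "dHIP": (75.0, 40.0), "MPOA": (70.0, 30.0),
    "NAsh": (65.0, 35.0), "MHb": (60.0, 25.0),
    "CeA": (25.0, 85.0), "BLA": (30.0, 80.0), "OFC": (35.0, 75.0), "IC": (30.0, 70.0),
    "PIR": (35.0, 72.0), "CPu": (25.0, 65.0), "NAc": (30.0, 68.0), "SNR": (20.0, 60.0),
    "MDT": (55.0, 55.0), "PV": (50.0, 52.0), "dBNST": (48.0, 50.0), "vBNST": (52.0, 48.0),
    "ovBNST": (45.0, 47.0), "LH": (50.0, 50.0), "LHb": (42.0, 44.0), "vHIP": (55.0, 50.0),
    "CoA": (46.0, 49.0), "VTA": (40.0, 42.0), "MRN_local": (95.0, 20.0),
}


def _simulate_tracing(master: int, n_subjects: int = 3):
    """Replicate-level ROI intensity table for the two source nuclei."""
    import pandas as pd

    rng = np.random.default_rng([master, 777])
    rows = []
    for region, (mrn_mu, drn_mu) in TRACING_PROFILE.items():
        for source, mu in (("MRN", mrn_mu), ("DRN", drn_mu)):
            for s in range(n_subjects):
                subj_val = mu * float(np.exp(rng.normal(0.0, 0.15)))
                for rep in range(int(rng.integers(2, 5))):
                    rows.append({
                        "source": source, "subject": f"{source}{s}", "region": region,
                        "replicate": rep,
                        "mean_intensity": subj_val * float(np.exp(rng.normal(0.0, 0.1))),
                    })
    return pd.DataFrame(rows)
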