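"""Zone occupancy, zone-conditioned signal, spatial maps, and preference scores.

Occupancy is counted in whole sample periods (n_samples / fs), so every
aggregation here — zone table, time-binned occupancy, spatial maps —
conserves total session time exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .arenas import ArenaGeometry
from .types import PositionTrack, ValidationError, ZoneSeries, ZScoredTrace

__all__ = [
    "assign_zones",
    "zone_signal_average",
    "signal_map",
    "occupancy_map",
    "distance_profile",
    "zone_time_correlation",
    "binned_occupancy",
    "preference_score",
    "SpatialMap",
]

#: samples farther than this (cm) from the arena floor are an error
OUTSIDE_TOLERANCE = 0.5


def assign_zones(track: PositionTrack, arena: ArenaGeometry) -> ZoneSeries:
    """Label every track sample with its arena zone.

    Zones are tested in the arena's priority order (most anxiogenic first),
    so samples exactly on a shared boundary get the more anxiogenic label.
    Samples outside every zone but within ``OUTSIDE_TOLERANCE`` of the
    floor are assigned to the nearest zone; farther out is an error.
    """
    n = len(track)
    labels = np.full(n, None, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for name in arena.priority:
        if not unassigned.any():
            break
        idx = np.flatnonzero(unassigned)
        hit = shapely.intersects_xy(arena.zones[name], track.x[idx], track.y[idx])
        labels[idx[hit]] = name
        unassigned[idx[hit]] = False
    if unassigned.any():
        stray = np.flatnonzero(unassigned)
        pts = shapely.points(track.x[stray], track.y[stray])
        dists = {name: shapely.distance(arena.zones[name], pts) for name in arena.priority}
        dmat = np.column_stack([dists[name] for name in arena.priority])
        nearest = dmat.min(axis=1)
        if (nearest > OUTSIDE_TOLERANCE).any():
            worst = float(nearest.max())
            raise ValidationError(
                f"{int((nearest > OUTSIDE_TOLERANCE).sum())} samples lie > "
                f"{OUTSIDE_TOLERANCE} cm outside the arena (max {worst:.2f} cm)"
            )
        # nearest zone; ties resolved by priority order (argmin takes first)
        for k, i in enumerate(stray):
            labels[i] = arena.priority[int(np.argmin(dmat[k]))]
    return ZoneSeries(t=track.t, zone=labels, arena_kind=arena.kind)


def _dt(zones: ZoneSeries) -> float:
    return zones.dt


def zone_signal_average(z: ZScoredTrace, zones: ZoneSeries, arena: ArenaGeometry | None = None) -> pd.DataFrame:
    """Mean z and occupancy seconds per zone.

    Zones never visited appear with NaN mean and 0 s when an arena is
    supplied (so the row set is the full zone set); occupancy sums to the
    session duration exactly.
    """
    if len(z.z) != len(zones):
        raise ValidationError("signal and zone series must have equal length")
    dt = _dt(zones)
    zone_names = list(arena.zones) if arena is not None else sorted(set(zones.zone))
    rows = []
    for name in zone_names:
        mask = zones.zone == name
        rows.append({
            "zone": name,
            "mean_z": float(z.z[mask].mean()) if mask.any() else float("nan"),
            "time_s": float(mask.sum() * dt),
        })
    return pd.DataFrame(rows)


@dataclass
class SpatialMap:
    """Binned arena map: per-bin mean signal (or dwell seconds) plus counts.

    Bins never visited hold NaN in ``value`` (missing, not zero).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    value: np.ndarray  # (nx, ny)
    count: np.ndarray
    kind: str  # "signal" or "occupancy"
    bin_cm: float


def _grid_edges(arena: ArenaGeometry, bin_cm: float) -> tuple[np.ndarray, np.ndarray]:
    if bin_cm <= 0:
        raise ValidationError("bin_cm must be positive")
    xmin, ymin, xmax, ymax = arena.bounds
    if bin_cm > (xmax - xmin) or bin_cm > (ymax - ymin):
        raise ValidationError("bin_cm exceeds the arena size")
    nx = int(np.ceil((xmax - xmin) / bin_cm))
    ny = int(np.ceil((ymax - ymin) / bin_cm))
    return xmin + np.arange(nx + 1) * bin_cm, ymin + np.arange(ny + 1) * bin_cm


def occupancy_map(track: PositionTrack, arena: ArenaGeometry, bin_cm: float = 2.5) -> SpatialMap:
    """Dwell seconds per spatial bin; the map total equals the session duration."""
    xe, ye = _grid_edges(arena, bin_cm)
    count, _, _ = np.histogram2d(track.x, track.y, bins=[xe, ye])
    dt = 1.0 / track.fs
    value = count * dt
    value = np.where(count > 0, value, np.nan)
    return SpatialMap(x_edges=xe, y_edges=ye, value=value, count=count, kind="occupancy", bin_cm=bin_cm)


def signal_map(z: ZScoredTrace, track: PositionTrack, arena: ArenaGeometry, bin_cm: float = 2.5) -> SpatialMap:
    """Mean z per spatial bin (NaN where the animal never went)."""
    if len(z.z) != len(track):
        raise ValidationError("signal and track must have equal length")
    xe, ye = _grid_edges(arena, bin_cm)
    count, _, _ = np.histogram2d(track.x, track.y, bins=[xe, ye])
    total, _, _ = np.histogram2d(track.x, track.y, bins=[xe, ye], weights=z.z)
    with np.errstate(invalid="ignore"):
        value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SpatialMap(x_edges=xe, y_edges=ye, value=value, count=count, kind="signal", bin_cm=bin_cm)


def distance_profile(
    z: ZScoredTrace,
    track: PositionTrack,
    arena: ArenaGeometry,
    arm: str,
    n_bins: int = 10,
    zones: ZoneSeries | None = None,
) -> pd.DataFrame:
    """Mean z binned by distance from the maze centre along an EPM arm.

    Distance is measured from the centre-square centroid along the arm's
    long axis (body-centre point only) and split into ``n_bins`` equal
    segments spanning centre-square edge to arm tip.  An arm never visited
    yields an all-NaN profile.
    """
    if arena.kind != "EPM":
        raise ValidationError("distance_profile requires an EPM arena")
    if arm not in ("open", "closed"):
        raise ValidationError("arm must be 'open' or 'closed'")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if zones is None:
        zones = assign_zones(track, arena)
    if not (len(z.z) == len(track) == len(zones)):
        raise ValidationError("signal, track, and zones must have equal length")
    size = arena.meta["size"]
    hw = arena.meta["arm_width"] / 2.0
    c = size / 2.0
    mask = zones.zone == arm
    # arms are axis-aligned: the along-axis offset is the larger coordinate excursion
    d = np.maximum(np.abs(track.x - c), np.abs(track.y - c))
    edges = np.linspace(hw, size / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    if mask.any():
        which = np.clip(np.digitize(d[mask], edges) - 1, 0, n_bins - 1)
        vals = z.z[mask]
        for b in range(n_bins):
            sel = which == b
            counts[b] = int(sel.sum())
            if sel.any():
                means[b] = float(vals[sel].mean())
    return pd.DataFrame({"arm": arm, "bin": np.arange(n_bins), "distance_cm": centers,
                         "mean_z": means, "n_samples": counts})


def zone_time_correlation(table: pd.DataFrame, scope: str = "all_zones"):
    """Pearson correlation of (mean z, occupancy time) across subject-zone points.

    ``table`` needs columns ``mean_z``, ``time_s`` and (for
    ``scope='closed_only'``) ``zone``.  Requires >= 3 finite points.
    Returns the stats-layer :class:`~sertflow.stats.TestResult`.
    """
    from .stats import pearson

    df = table
    if scope == "closed_only":
        df = df[df["zone"] == "closed"]
    elif scope != "all_zones":
        raise ValidationError("scope must be 'all_zones' or 'closed_only'")
    df = df.dropna(subset=["mean_z", "time_s"])
    if len(df) < 3:
        raise ValidationError("need >= 3 (subject, zone) points")
    return pearson(df["mean_z"].to_numpy(), df["time_s"].to_numpy())


def binned_occupancy(zones: ZoneSeries, bin_s: float = 180.0) -> pd.DataFrame:
    """Dwell seconds per zone per consecutive time bin (row sums = bin length)."""
    if bin_s <= 0:
        raise ValidationError("bin must be positive")
    dt = _dt(zones)
    rel = zones.t - zones.t[0]
    which = np.floor(rel / bin_s + 1e-12).astype(int)
    names = sorted(set(zones.zone))
    n_bins = int(which.max()) + 1 if len(which) else 0
    data = {name: np.zeros(n_bins) for name in names}
    for b in range(n_bins):
        sel = which == b
        for name in names:
            data[name][b] = float(((zones.zone == name) & sel).sum() * dt)
    out = pd.DataFrame(data)
    out.insert(0, "bin_start_s", np.arange(n_bins) * bin_s)
    return out


def preference_score(zones: ZoneSeries, side: str) -> float:
    """Fraction of total session time spent on the given side (e.g. stimulation side)."""
    if len(zones) == 0:
        raise ValidationError("zero total time")
    return float((zones.zone == side).sum() / len(zones))
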