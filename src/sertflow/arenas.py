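"""Built-in arena geometries: open field, elevated plus maze, place-preference box.

Each arena is a set of named shapely zone polygons that partition the
floor, plus a priority order used to break ties for samples that land
exactly on a zone boundary.  The priority puts the more anxiogenic zone
first (OFT: center > edge > corner; EPM: open > center > closed) so that
boundary samples are scored conservatively for avoidance metrics.

Zone dimensions the source assays leave open are explicit keyword
arguments here (OFT quartile partition, EPM arm width) and are echoed in
``ArenaGeometry.meta`` so every output can report the geometry it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .types import ValidationError

ARENA_KINDS = ("OFT", "EPM", "RTPP")


@dataclass
class ArenaGeometry:
    """Named zone polygons partitioning an arena floor."""

    kind: str
    zones: dict[str, BaseGeometry]
    priority: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARENA_KINDS:
            raise ValidationError(f"kind must be one of {ARENA_KINDS}, got {self.kind!r}")
        if set(self.priority) != set(self.zones):
            raise ValidationError("priority must list exactly the zone labels")

    @property
    def floor(self) -> BaseGeometry:
        """Union of all zones (the whole arena floor)."""
        return unary_union(list(self.zones.values()))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.floor.bounds

    def zone_areas(self) -> dict[str, float]:
        return {name: geom.area for name, geom in self.zones.items()}

    def check_partition(self, tol: float = 1e-6) -> None:
        """Raise unless zones tile the arena (union area == sum of areas)."""
        total = sum(self.zone_areas().values())
        if abs(total - self.floor.area) > tol:
            raise ValidationError(
                f"zones do not partition the arena: sum {total} vs union {self.floor.area}"
            )


def oft_arena(side: float = 50.0, corner: float = 12.5) -> ArenaGeometry:
    """Square open field with corner / edge / center zones.

    ``corner`` is the side of the four corner squares; the center square
    has side ``side - 2*corner`` (the quartile partition for the default
    50 cm arena: 12.5 cm corners, 25 cm center, edge = remainder).
    """
    if not 0 < 2 * corner < side:
        raise ValidationError("need 0 < 2*corner < side")
    full = box(0, 0, side, side)
    center = box(corner, corner, side - corner, side - corner)
    corners = unary_union(
        [
            box(0, 0, corner, corner),
            box(side - corner, 0, side, corner),
            box(0, side - corner, corner, side),
            box(side - corner, side - corner, side, side),
        ]
    )
    edge = full.difference(center).difference(corners)
    return ArenaGeometry(
        kind="OFT",
        zones={"center": center, "edge": edge, "corner": corners},
        priority=["center", "edge", "corner"],
        meta={"side": side, "corner": corner},
    )


def epm_arena(size: float = 76.0, arm_width: float = 7.0) -> ArenaGeometry:
    """Plus-shaped elevated maze with open / center / closed zones.

    The platform spans ``size`` cm tip to tip; the center square is
    ``arm_width`` x ``arm_width`` at the arm intersection.  Open arms run
    along x, closed arms along y.
    """
    if not 0 < arm_width < size:
        raise ValidationError("need 0 < arm_width < size")
    c = size / 2.0
    hw = arm_width / 2.0
    center = box(c - hw, c - hw, c + hw, c + hw)
    open_arms = unary_union(
        [box(0, c - hw, c - hw, c + hw), box(c + hw, c - hw, size, c + hw)]
    )
    closed_arms = unary_union(
        [box(c - hw, 0, c + hw, c - hw), box(c - hw, c + hw, c + hw, size)]
    )
    return ArenaGeometry(
        kind="EPM",
        zones={"open": open_arms, "center": center, "closed": closed_arms},
        priority=["open", "center", "closed"],
        meta={"size": size, "arm_width": arm_width},
    )


def rtpp_arena(length: float = 52.0, width: float = 26.0) -> ArenaGeometry:
    """Two-compartment rectangular place-preference box, sides A and B."""
    if length <= 0 or width <= 0:
        raise ValidationError("length and width must be positive")
    return ArenaGeometry(
        kind="RTPP",
        zones={"A": box(0, 0, length / 2, width), "B": box(length / 2, 0, length, width)},
        priority=["A", "B"],
        meta={"length": length, "width": width},
    )


_FACTORIES = {"OFT": oft_arena, "EPM": epm_arena, "RTPP": rtpp_arena}


def arena_from_config(config: dict) -> ArenaGeometry:
    """Build an arena from a plain config mapping (e.g. parsed YAML).

    ``{"kind": "EPM", "size": 76, "arm_width": 7}`` -> :func:`epm_arena`.
    """
    from .types import FormatError

    cfg = dict(config)
    kind = cfg.pop("kind", None)
    if kind not in _FACTORIES:
        raise FormatError(f"unknown arena kind {kind!r}; expected one of {ARENA_KINDS}")
    return _FACTORIES[kind](**cfg)


def zone_lookup_grid(arena: ArenaGeometry, resolution: float = 0.25):
    """Rasterize zones to a lookup grid for fast per-sample queries.

    Returns ``(labels, grid, xmin, ymin, resolution)`` where ``grid`` holds
    the index into ``labels`` of the zone covering each cell centre, or -1
    outside the arena.  Used by the track simulator; exact (vector) zone
    assignment lives in :mod:`sertflow.spatial`.
    """
    import shapely

    xmin, ymin, xmax, ymax = arena.bounds
    nx = int(np.ceil((xmax - xmin) / resolution))
    ny = int(np.ceil((ymax - ymin) / resolution))
    xs = xmin + (np.arange(nx) + 0.5) * resolution
    ys = ymin + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.full((nx, ny), -1, dtype=np.int8)
    labels = list(arena.priority)
    for i, name in enumerate(labels):
        geom = arena.zones[name]
        mask = shapely.intersects_xy(geom, gx.ravel(), gy.ravel()).reshape(nx, ny)
        grid[(grid == -1) & mask] = i
    return labels, grid, xmin, ymin, resolution
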