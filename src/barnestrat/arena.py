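"""Geometry of the Barnes maze arena and the open-field box.

Coordinate conventions, used throughout the package: the origin sits at the
arena centre, lengths are in centimetres, the y axis points up and angles are
measured counter-clockwise from the +x axis.  Hole ``k`` of ``n_holes`` sits on
the hole ring at angle ``2*pi*k/n_holes``; the escape (target) hole is a hole
index, not a coordinate.

The default dimensions follow common commercial mouse Barnes mazes (92 cm
platform, holes on a 40 cm ring); every value is overridable through
:func:`make_arena` or a YAML/JSON config file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArenaConfigError",
    "ArenaSpec",
    "OpenFieldSpec",
    "Zone",
    "make_arena",
    "load_arena",
    "load_open_field",
    "hole_positions",
    "circular_hole_distance",
    "locate_point",
]


class ArenaConfigError(ValueError):
    """A configuration violates an arena or open-field invariant."""


@dataclass(frozen=True)
class ArenaSpec:
    """Holed circular arena: radii in cm, holes equally spaced on the ring."""

    arena_radius: float = 46.0
    hole_ring_radius: float = 40.0
    n_holes: int = 20
    hole_radius: float = 2.5
    visit_radius: float = 7.0
    target_hole: int = 0

    def __post_init__(self) -> None:
        if self.n_holes < 2:
            raise ArenaConfigError("n_holes must be >= 2")
        if not (0 < self.hole_radius <= self.visit_radius):
            raise ArenaConfigError("need 0 < hole_radius <= visit_radius")
        if not (self.visit_radius < self.hole_ring_radius < self.arena_radius):
            raise ArenaConfigError(
                "need visit_radius < hole_ring_radius < arena_radius"
            )
        if not (0 <= self.target_hole < self.n_holes):
            raise ArenaConfigError("target_hole must lie in [0, n_holes)")

    def hole_angle(self, k: int) -> float:
        """Angle of hole ``k`` in radians, counter-clockwise from +x."""
        return 2.0 * math.pi * k / self.n_holes

    @property
    def target_angle(self) -> float:
        return self.hole_angle(self.target_hole)

    @property
    def target_position(self) -> np.ndarray:
        return hole_positions(self)[self.target_hole]


@dataclass(frozen=True)
class OpenFieldSpec:
    """Square open-field box; the centre region is a centred square whose side
    is ``center_fraction`` of the box side."""

    side_length: float = 50.0
    center_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ArenaConfigError("side_length must be positive")
        if not (0.0 < self.center_fraction < 1.0):
            raise ArenaConfigError("center_fraction must lie in (0, 1)")

    def in_center_region(self, x, y) -> np.ndarray:
        """Boolean mask: points inside the centred square (box centred at 0)."""
        half = 0.5 * self.center_fraction * self.side_length
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (np.abs(x) <= half) & (np.abs(y) <= half)


@dataclass(frozen=True)
class Zone:
    """A named region of the arena.

    ``kind`` is one of ``hole``, ``quadrant``, ``center_region``,
    ``open_floor``; ``id`` is the hole index or quadrant index (0-3).
    Quadrant 0 is the 90-degree sector centred on the target hole.
    """

    kind: str
    id: int

    _KINDS = ("hole", "quadrant", "center_region", "open_floor")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ArenaConfigError(f"unknown zone kind {self.kind!r}")


_ARENA_FIELDS = {f for f in ArenaSpec.__dataclass_fields__}


def make_arena(config: dict | None = None, **overrides) -> ArenaSpec:
    """Build a validated :class:`ArenaSpec` from a keyed parameter set.

    Omitted keys take the documented defaults; unknown keys are rejected so a
    typo cannot silently leave a default in place.
    """
    merged = dict(config or {})
    merged.update(overrides)
    unknown = set(merged) - _ARENA_FIELDS
    if unknown:
        raise ArenaConfigError(f"unknown arena parameter(s): {sorted(unknown)}")
    return ArenaSpec(**merged)


def load_arena(path: str | Path) -> ArenaSpec:
    """Read an arena config (YAML or JSON; keys = ArenaSpec field names)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return make_arena(data or {})


def load_open_field(path: str | Path) -> OpenFieldSpec:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return OpenFieldSpec(**(data or {}))


def hole_positions(arena: ArenaSpec) -> np.ndarray:
    """(n_holes, 2) array of hole centres; hole k at angle 2*pi*k/n_holes."""
    ang = 2.0 * np.pi * np.arange(arena.n_holes) / arena.n_holes
    return arena.hole_ring_radius * np.column_stack([np.cos(ang), np.sin(ang)])


def circular_hole_distance(i: int, j: int, n_holes: int) -> int:
    """Number of holes separating i and j the short way around the ring."""
    if not (0 <= i < n_holes and 0 <= j < n_holes):
        raise ValueError(f"hole index out of range for n_holes={n_holes}")
    d = abs(i - j)
    return min(d, n_holes - d)


def locate_point(arena: ArenaSpec, p) -> Zone:
    """Map a planar point to its Zone.

    A point within ``visit_radius`` of a hole centre belongs to that hole
    (nearest hole wins where visit zones overlap); otherwise it belongs to the
    90-degree quadrant containing it, quadrant 0 being centred on the target
    hole.  Points outside the arena are assigned by angle.
    """
    p = np.asarray(p, dtype=float)
    holes = hole_positions(arena)
    d = np.hypot(holes[:, 0] - p[0], holes[:, 1] - p[1])
    k = int(np.argmin(d))
    if d[k] <= arena.visit_radius:
        return Zone("hole", k)
    rel = math.atan2(p[1], p[0]) - arena.target_angle
    q = int(math.floor((rel + math.pi / 4) / (math.pi / 2))) % 4
    return Zone("quadrant", q)


def quadrant_of_angle(arena: ArenaSpec, theta) -> np.ndarray:
    """Vectorised quadrant index for angles (radians); 0 = target quadrant.

    Unlike :func:`locate_point` this ignores hole zones, so dwell time inside
    the target hole zone still counts toward the target quadrant.
    """
    rel = np.asarray(theta, dtype=float) - arena.target_angle
    return np.floor((rel + np.pi / 4) / (np.pi / 2)).astype(int) % 4
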