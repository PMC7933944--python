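"""Per-trial trajectory features for Barnes-maze and open-field trials.

The feature set is what the strategy classifier and the cumulative strategy
score consume: escape latency, path length and efficiency, grid-occupancy
coverage of the arena, distance from the trajectory centroid to the escape
hole, and the ordered hole-visit sequence with its primary-error count.

Features for a training trial are computed on the trajectory truncated at the
escape (first entry into the target hole's visit zone); trials that never
reach the target use the full trajectory and are flagged via
``reached_target``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaSpec, OpenFieldSpec, hole_positions
from .trajectory_io import Cohort, Trajectory, TrialRecord, resample_uniform
from .trajectory_io import smooth as smooth_traj

__all__ = [
    "TrialFeatures",
    "OpenFieldMetrics",
    "hole_visit_sequence",
    "escape_latency",
    "path_length",
    "path_efficiency",
    "total_coverage",
    "centroid_to_target",
    "primary_errors",
    "open_field_metrics",
    "compute_trial_features",
    "cohort_features",
    "features_frame",
    "sequence_to_str",
    "str_to_sequence",
]


@dataclass(frozen=True)
class TrialFeatures:
    """Scalar and sequence features of one Barnes-maze trial."""

    escape_latency: float          # s; trial duration if target never reached
    reached_target: bool
    path_length: float             # cm, up to escape
    mean_speed: float              # cm/s, up to escape
    path_efficiency: float         # straight start->target / path length
    total_coverage: float          # fraction of arena grid cells visited
    centroid_to_target: float      # cm
    centroid_to_nearest_nontarget_hole: float  # cm; supports focal-search detection
    hole_sequence: tuple = ()      # ((hole index, first-contact time s), ...)
    primary_errors: int = 0


@dataclass(frozen=True)
class OpenFieldMetrics:
    distance: float       # cm
    mean_speed: float     # cm/s
    time_in_center: float # s


def hole_visit_sequence(
    traj: Trajectory, arena: ArenaSpec, refractory: float = 1.0
) -> list[tuple[int, float]]:
    """Ordered hole visits as (hole index, first-contact time).

    A sample belongs to a hole when it lies within ``visit_radius`` of that
    hole's centre (nearest hole wins where zones overlap).  A visit opens on
    entry and closes on exit; re-entry into the same hole within ``refractory``
    seconds of the previous exit — with no other hole visited in between —
    collapses into the earlier visit.
    """
    holes = hole_positions(arena)
    diff = traj.positions[:, None, :] - holes[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    nearest = np.argmin(dist, axis=1)
    inside = dist[np.arange(traj.n), nearest] <= arena.visit_radius
    active = np.where(inside, nearest, -1)

    # run-length encode, keeping entry/exit times of each hole run
    runs: list[tuple[int, float, float]] = []
    start = 0
    for i in range(1, traj.n + 1):
        if i == traj.n or active[i] != active[start]:
            if active[start] >= 0:
                runs.append((int(active[start]), float(traj.t[start]), float(traj.t[i - 1])))
            start = i

    visits: list[list[float | int]] = []
    for hole, t_in, t_out in runs:
        if visits and visits[-1][0] == hole and t_in - visits[-1][2] <= refractory:
            visits[-1][2] = t_out
        else:
            visits.append([hole, t_in, t_out])
    return [(int(h), float(t_in)) for h, t_in, _ in visits]


def escape_latency(
    traj: Trajectory, arena: ArenaSpec, refractory: float = 1.0
) -> float | None:
    """Time from trial start to first target-hole visit; None if never reached."""
    for hole, t_in in hole_visit_sequence(traj, arena, refractory):
        if hole == arena.target_hole:
            return t_in - float(traj.t[0])
    return None


def path_length(traj: Trajectory) -> float:
    """Sum of Euclidean segment lengths, cm."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def path_efficiency(
    traj: Trajectory, arena: ArenaSpec, refractory: float = 1.0
) -> float:
    """Straight-line distance from the first sample to the target hole centre,
    divided by the path length travelled up to escape (full path if the target
    is never reached).  Can exceed 1 slightly when the trajectory stops at the
    visit-zone boundary rather than the hole centre.
    """
    lat = escape_latency(traj, arena, refractory)
    seg = traj if lat is None else traj.truncated(lat)
    plen = path_length(seg)
    if plen <= 0:
        raise ValueError("path_efficiency undefined for zero path length")
    tx, ty = arena.target_position
    straight = math.hypot(traj.x[0] - tx, traj.y[0] - ty)
    return straight / plen


@functools.lru_cache(maxsize=32)
def _disk_cells(arena_radius: float, cell_size: float) -> frozenset[tuple[int, int]]:
    """Grid cells (index pairs) whose square intersects the open arena disk."""
    kmax = int(math.ceil(arena_radius / cell_size))
    cells = set()
    for ix in range(-kmax - 1, kmax + 1):
        for iy in range(-kmax - 1, kmax + 1):
            # closest point of the square [ix,ix+1)x[iy,iy+1)*cell to origin
            cx = min(max(0.0, ix * cell_size), (ix + 1) * cell_size)
            cy = min(max(0.0, iy * cell_size), (iy + 1) * cell_size)
            if math.hypot(cx, cy) < arena_radius:
                cells.add((ix, iy))
    return frozenset(cells)


def total_coverage(traj: Trajectory, arena: ArenaSpec, cell_size: float = 4.0) -> float:
    """Fraction of arena grid cells (side ``cell_size``) containing >= 1 sample.

    The trajectory should be uniformly resampled first so the fraction has a
    defined sampling basis.  Monotone non-decreasing in trajectory prefixes.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    valid = _disk_cells(arena.arena_radius, cell_size)
    ix = np.floor(traj.x / cell_size).astype(int)
    iy = np.floor(traj.y / cell_size).astype(int)
    occupied = set(zip(ix.tolist(), iy.tolist())) & valid
    return len(occupied) / len(valid)


def centroid_to_target(traj: Trajectory, arena: ArenaSpec) -> float:
    """Distance from the unweighted mean sample position to the target centre."""
    tx, ty = arena.target_position
    return float(math.hypot(traj.x.mean() - tx, traj.y.mean() - ty))


def primary_errors(seq: list[tuple[int, float]] | list[int], target: int) -> int:
    """Visits to non-target holes before the first target visit (all visits if
    the target is never visited)."""
    count = 0
    for item in seq:
        hole = item[0] if isinstance(item, (tuple, list)) else item
        if hole == target:
            return count
        count += 1
    return count


def open_field_metrics(traj: Trajectory, box: OpenFieldSpec) -> OpenFieldMetrics:
    """Distance, mean speed and centre-region time for an open-field trial.

    Centre time is the sum of inter-sample intervals whose starting sample
    lies in the centre square, so a uniformly resampled trajectory gives
    dt-weighted dwell time.
    """
    if traj.duration <= 0:
        raise ValueError("open_field_metrics requires a positive-duration trajectory")
    dist = path_length(traj)
    in_center = box.in_center_region(traj.x, traj.y)
    dts = np.diff(traj.t)
    time_in_center = float(dts[in_center[:-1]].sum())
    return OpenFieldMetrics(
        distance=dist,
        mean_speed=dist / traj.duration,
        time_in_center=time_in_center,
    )


def compute_trial_features(
    traj: Trajectory,
    arena: ArenaSpec,
    dt: float = 0.1,
    smooth_window: int = 5,
    cell_size: float = 4.0,
    refractory: float = 1.0,
) -> TrialFeatures:
    """Full feature pipeline: smooth, resample, detect visits, measure.

    Degenerate trajectories (single sample, zero path) yield zeroed features
    with ``path_efficiency`` 0 rather than an error, so cohort pipelines never
    abort on a bad trial.
    """
    prepared = resample_uniform(smooth_traj(traj, smooth_window), dt)
    seq = hole_visit_sequence(prepared, arena, refractory)
    lat = next(
        (t_in - float(prepared.t[0]) for h, t_in in seq if h == arena.target_hole), None
    )
    reached = lat is not None
    segment = prepared.truncated(lat) if reached else prepared
    plen = path_length(segment)
    duration = segment.duration
    tx, ty = arena.target_position
    straight = math.hypot(prepared.x[0] - tx, prepared.y[0] - ty)
    cx, cy = segment.x.mean(), segment.y.mean()
    holes = hole_positions(arena)
    nontarget = np.delete(np.arange(arena.n_holes), arena.target_hole)
    d_nontarget = np.hypot(holes[nontarget, 0] - cx, holes[nontarget, 1] - cy)
    return TrialFeatures(
        escape_latency=lat if reached else prepared.duration,
        reached_target=reached,
        path_length=plen,
        mean_speed=plen / duration if duration > 0 else 0.0,
        path_efficiency=straight / plen if plen > 0 else 0.0,
        total_coverage=total_coverage(segment, arena, cell_size),
        centroid_to_target=float(math.hypot(cx - tx, cy - ty)),
        centroid_to_nearest_nontarget_hole=float(d_nontarget.min()),
        hole_sequence=tuple((h, t) for h, t in seq),
        primary_errors=primary_errors(seq, arena.target_hole),
    )


def sequence_to_str(seq) -> str:
    """Serialize a hole-visit sequence for CSV output, e.g. '3@12.40;4@15.00'."""
    return ";".join(f"{h}@{t:.2f}" for h, t in seq)


def str_to_sequence(s: str) -> tuple:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return ()
    return tuple(
        (int(part.split("@")[0]), float(part.split("@")[1])) for part in s.split(";")
    )


def cohort_features(
    cohort: Cohort, phases: tuple[str, ...] = ("training", "probe"), **kwargs
) -> list[tuple[TrialRecord, TrialFeatures]]:
    """Compute features for every trial of the given phases."""
    return [
        (tr, compute_trial_features(tr.trajectory, cohort.arena, **kwargs))
        for tr in cohort.trials
        if tr.phase in phases
    ]


def features_frame(pairs: list[tuple[TrialRecord, TrialFeatures]]) -> pd.DataFrame:
    """Tabulate (trial, features) pairs, one row per trial."""
    rows = []
    for tr, ft in pairs:
        rows.append(
            {
                "animal_id": tr.animal_id,
                "group": tr.group,
                "day": tr.day,
                "trial_index": tr.trial_index,
                "phase": tr.phase,
                "escape_latency": ft.escape_latency,
                "reached_target": ft.reached_target,
                "path_length": ft.path_length,
                "mean_speed": ft.mean_speed,
                "path_efficiency": ft.path_efficiency,
                "total_coverage": ft.total_coverage,
                "centroid_to_target": ft.centroid_to_target,
                "centroid_to_nearest_nontarget_hole": ft.centroid_to_nearest_nontarget_hole,
                "primary_errors": ft.primary_errors,
                "hole_sequence": sequence_to_str(ft.hole_sequence),
            }
        )
    return pd.DataFrame(rows)
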