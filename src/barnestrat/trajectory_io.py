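"""Reading, calibrating, resampling and smoothing tracking data.

Tracking tables are generic CSV exports with one row per video frame and
columns for time, x and y.  A *dialect* maps the exporter's column names onto
those roles and optionally applies a pixel-to-cm scale and an origin offset, so
any tracker export can be read without a bespoke parser.  All trajectories are
stored in calibrated units: seconds and centimetres, arena centre at (0, 0).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .arena import ArenaSpec

__all__ = [
    "Trajectory",
    "TrialRecord",
    "Cohort",
    "TrackingFormatError",
    "PHASES",
    "read_tracking",
    "write_tracking",
    "write_features_table",
    "read_manifest",
    "load_cohort",
    "resample_uniform",
    "smooth",
]

PHASES = ("habituation", "training", "probe", "open_field")

#: default dialect; ``scale`` is cm per input unit, ``origin`` is subtracted
#: after scaling, ``rezero_time`` shifts time so the first sample is t=0.
DEFAULT_DIALECT = {
    "time": "time",
    "x": "x",
    "y": "y",
    "scale": 1.0,
    "origin": (0.0, 0.0),
    "rezero_time": False,
    "max_gap": 1.0,
}


class TrackingFormatError(ValueError):
    """A tracking table does not satisfy the expected layout."""


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered planar samples for one trial, in seconds and cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 1:
            raise ValueError("t, x, y must be equal-length 1-D arrays with >= 1 sample")
        if not (np.isfinite(t).all() and np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("trajectory contains non-finite values")
        if t.size > 1 and not (np.diff(t) > 0).all():
            bad = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(f"time must be strictly increasing (violated at row {bad + 1})")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def truncated(self, t_max: float) -> "Trajectory":
        """Samples with t - t0 <= t_max (at least the first sample)."""
        keep = self.t - self.t[0] <= t_max
        keep[0] = True
        return Trajectory(self.t[keep], self.x[keep], self.y[keep], self.note)


@dataclass(frozen=True)
class TrialRecord:
    """One tracked trial with its experimental metadata."""

    animal_id: str
    group: str
    day: int
    trial_index: int
    phase: str
    trajectory: Trajectory

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based and must be >= 1")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")


@dataclass
class Cohort:
    """All trials of an experiment plus the arena they were run on."""

    trials: list[TrialRecord]
    arena: ArenaSpec

    def __post_init__(self) -> None:
        keys = [(tr.animal_id, tr.phase, tr.trial_index) for tr in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (animal_id, phase, trial_index) in cohort")

    def training_trials(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.phase == "training"]

    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.animal_id, None)
        return list(seen)


def read_tracking(source, dialect: dict | None = None) -> Trajectory:
    """Read one trial's tracking table into a calibrated :class:`Trajectory`.

    ``source`` is a path or text stream; ``dialect`` overrides
    :data:`DEFAULT_DIALECT`.  Rows with non-finite coordinates are dropped
    (count reported via a warning); gaps longer than ``max_gap`` seconds raise
    a QC warning rather than silently interpolating positions.
    """
    d = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(source)
    for role in ("time", "x", "y"):
        if d[role] not in df.columns:
            raise TrackingFormatError(f"missing required column {d[role]!r} for {role}")
    t = df[d["time"]].to_numpy(dtype=float)
    x = df[d["x"]].to_numpy(dtype=float) * d["scale"] - d["origin"][0]
    y = df[d["y"]].to_numpy(dtype=float) * d["scale"] - d["origin"][1]
    ok = np.isfinite(t) & np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} rows with non-finite values", stacklevel=2)
        t, x, y = t[ok], x[ok], y[ok]
    if t.size < 1:
        raise TrackingFormatError("no valid tracking rows in input")
    if t.size > 1:
        dt = np.diff(t)
        if (dt <= 0).any():
            bad = int(np.argmax(dt <= 0))
            raise TrackingFormatError(f"non-monotone time at row {bad + 1}")
        gaps = int((dt > d["max_gap"]).sum())
        if gaps:
            warnings.warn(
                f"{gaps} inter-sample gap(s) exceed max_gap={d['max_gap']} s; "
                "positions across these gaps are not trustworthy",
                stacklevel=2,
            )
    if d["rezero_time"]:
        t = t - t[0]
    return Trajectory(t, x, y, note=f"read_tracking(scale={d['scale']})")


def write_tracking(traj: Trajectory, sink) -> None:
    """Write a trajectory as a CSV readable by :func:`read_tracking`."""
    pd.DataFrame({"time": traj.t, "x": traj.x, "y": traj.y}).to_csv(sink, index=False)


def write_features_table(rows: list[dict], sink) -> None:
    """Write per-trial feature records as CSV, one row per trial.

    Column order follows the first record; an empty list yields a header-less
    empty table (pandas writes just a newline), kept round-trippable.
    """
    if rows:
        df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    else:
        df = pd.DataFrame()
    df.to_csv(sink, index=False)


MANIFEST_COLUMNS = ("animal_id", "group", "day", "trial_index", "phase", "file")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TrackingFormatError(f"manifest missing column(s): {sorted(missing)}")
    return df


def load_cohort(
    manifest_path,
    arena: ArenaSpec,
    dialect: dict | None = None,
    base_dir: str | Path | None = None,
) -> Cohort:
    """Read every trial listed in a manifest CSV into a :class:`Cohort`."""
    mf = read_manifest(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(str(manifest_path)).parent
    trials = []
    for row in mf.itertuples(index=False):
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        trials.append(
            TrialRecord(
                animal_id=str(row.animal_id),
                group=str(row.group),
                day=int(row.day),
                trial_index=int(row.trial_index),
                phase=str(row.phase),
                trajectory=read_tracking(fpath, dialect),
            )
        )
    return Cohort(trials, arena)


def resample_uniform(traj: Trajectory, dt: float) -> Trajectory:
    """Linear interpolation onto a uniform grid t0, t0+dt, ... <= t_end.

    Idempotent on already-uniform input at the same dt; a small tolerance in
    the grid length guards against float round-off at the last sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(np.floor(traj.duration / dt + 1e-9))
    grid = traj.t[0] + dt * np.arange(n_steps + 1)
    return Trajectory(
        grid,
        np.interp(grid, traj.t, traj.x),
        np.interp(grid, traj.t, traj.y),
        traj.note,
    )


def smooth(traj: Trajectory, window: int = 5) -> Trajectory:
    """Centred moving-median filter per coordinate; timestamps unchanged.

    window=1 is the identity.  Median (not mean) so single-frame tracking
    glitches are removed without rounding corners.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    if window == 1 or traj.n == 1:
        return traj
    return Trajectory(
        traj.t,
        median_filter(traj.x, size=window, mode="nearest"),
        median_filter(traj.y, size=window, mode="nearest"),
        traj.note,
    )
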