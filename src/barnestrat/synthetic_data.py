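"""Seeded trajectory and cohort simulator for Barnes-maze analyses.

The movement model is a constant-time-step correlated walk: each step the
heading is drawn around an aim direction with von Mises noise and the speed
around a mean with Gaussian noise.  Per-strategy generative rules compose
walks between the arena centre, holes on the ring and the escape hole:

* direct — re-aimed walk from the centre straight to the target hole.
* short_chaining — approach a hole within 3 holes of the target, then
  hole-to-hole ring steps to the target, dwelling at each hole.
* long_chaining — approach a hole 5-10 holes from the target, then a
  monotone hole-by-hole ring walk to the target.
* serial — approach a random non-target hole, then a systematic
  hole-by-hole sweep along the *longer* arc until the target is reached; a
  scan that is not target-directed, unlike chaining.  At the antipode both
  arcs tie and the direction is random.
* random — correlated random walk with weak heading persistence, reflected
  at the arena wall, ending on a chance target encounter or at max_duration.
* focal_incorrect — approach the hole antipodal to the target and dwell in a
  small-radius walk around it for the whole trial.

Everything is a pure function of (parameters, seed); cohort simulation
derives one stable sub-seed per (seed, group, mouse, trial) so adding a group
never perturbs existing groups' trajectories.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec, circular_hole_distance, hole_positions
from .trajectory_io import Cohort, Trajectory, TrialRecord, write_tracking

__all__ = [
    "StrategySimParams",
    "GroupProfile",
    "SimManifest",
    "simulate_trajectory",
    "simulate_cohort",
    "builtin_group_profiles",
    "expected_profile_score",
    "export_cohort",
    "SIMULATED_STRATEGIES",
]

SIMULATED_STRATEGIES = (
    "direct",
    "short_chaining",
    "long_chaining",
    "serial",
    "random",
    "focal_incorrect",
)


@dataclass(frozen=True)
class StrategySimParams:
    """Movement-model parameters (cm, s).  ``heading_kappa`` is the von Mises
    concentration of per-step heading noise (larger = straighter);
    ``noiseless`` removes all heading and speed noise for exact constructions."""

    speed_mean: float = 12.0
    speed_sd: float = 2.0
    heading_kappa: float = 8.0
    dwell_at_hole: float = 1.0
    step_dt: float = 0.1
    max_duration: float = 180.0
    noiseless: bool = False

    def __post_init__(self) -> None:
        for name in ("speed_mean", "speed_sd", "heading_kappa", "dwell_at_hole", "step_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.step_dt < self.max_duration):
            raise ValueError("need 0 < step_dt < max_duration")


@dataclass(frozen=True)
class GroupProfile:
    """Trial-indexed strategy mixture for one experimental group."""

    name: str
    mixture: tuple[dict[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mixture", tuple(dict(m) for m in self.mixture))
        for i, mix in enumerate(self.mixture):
            for s, prob in mix.items():
                if s not in SIMULATED_STRATEGIES:
                    raise ValueError(f"unknown strategy {s!r} in mixture for trial {i + 1}")
                if prob < 0:
                    raise ValueError("mixture probabilities must be non-negative")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixture for trial {i + 1} does not sum to 1")


@dataclass(frozen=True)
class SimManifest:
    """Specification of a simulated multi-group cohort."""

    seed: int
    n_mice: int
    profiles: tuple[GroupProfile, ...]
    arena: ArenaSpec = ArenaSpec()
    n_trials: int = 9
    sim_params: StrategySimParams = StrategySimParams()

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_mice < 1 or not self.profiles:
            raise ValueError("need n_trials >= 1, n_mice >= 1 and at least one group")
        for prof in self.profiles:
            if len(prof.mixture) != self.n_trials:
                raise ValueError(
                    f"profile {prof.name!r} has {len(prof.mixture)} mixtures, "
                    f"expected n_trials={self.n_trials}"
                )


class _Walker:
    """Stateful stepper shared by the strategy generators."""

    def __init__(self, arena: ArenaSpec, p: StrategySimParams, rng) -> None:
        self.arena = arena
        self.p = p
        self.rng = rng
        self.max_steps = int(round(p.max_duration / p.step_dt))
        self.ts = [0.0]
        self.xs = [0.0]
        self.ys = [0.0]

    @property
    def pos(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]

    @property
    def exhausted(self) -> bool:
        return len(self.ts) - 1 >= self.max_steps

    def _step(self, heading: float) -> None:
        p = self.p
        if p.noiseless:
            speed = p.speed_mean
        else:
            speed = max(self.rng.normal(p.speed_mean, p.speed_sd), 1.0)
        self.ts.append(self.ts[-1] + p.step_dt)
        self.xs.append(self.xs[-1] + speed * p.step_dt * math.cos(heading))
        self.ys.append(self.ys[-1] + speed * p.step_dt * math.sin(heading))

    def walk_to(self, goal, stop_radius: float, kappa: float | None = None,
                speed_scale: float = 1.0) -> bool:
        """Re-aimed noisy walk toward ``goal``; True if reached in time."""
        p = self.p
        kappa = p.heading_kappa if kappa is None else kappa
        while not self.exhausted:
            x, y = self.pos
            dx, dy = goal[0] - x, goal[1] - y
            if math.hypot(dx, dy) <= stop_radius:
                return True
            aim = math.atan2(dy, dx)
            heading = aim if p.noiseless else aim + self.rng.vonmises(0.0, kappa)
            if speed_scale != 1.0:
                speed = (p.speed_mean if p.noiseless
                         else max(self.rng.normal(p.speed_mean, p.speed_sd), 1.0))
                self.ts.append(self.ts[-1] + p.step_dt)
                self.xs.append(x + speed_scale * speed * p.step_dt * math.cos(heading))
                self.ys.append(y + speed_scale * speed * p.step_dt * math.sin(heading))
            else:
                self._step(heading)
        return False

    def dwell(self, duration: float) -> None:
        n = min(int(round(duration / self.p.step_dt)),
                self.max_steps - (len(self.ts) - 1))
        x, y = self.pos
        for _ in range(n):
            self.ts.append(self.ts[-1] + self.p.step_dt)
            self.xs.append(x)
            self.ys.append(y)

    def trajectory(self, note: str) -> Trajectory:
        return Trajectory(np.array(self.ts), np.array(self.xs), np.array(self.ys), note)


def _signed_offset(frm: int, to: int, n: int) -> int:
    """Signed hole-index difference to->frm along the shorter arc, in (-n/2, n/2]."""
    return (to - frm + n // 2) % n - n // 2


def _chain(w: _Walker, holes: np.ndarray, start: int, target: int, n: int,
           direction: int, settle: float) -> None:
    """Hole-by-hole ring walk from ``start`` to ``target`` stepping ``direction``."""
    k = start
    while k != target and not w.exhausted:
        w.dwell(w.p.dwell_at_hole)
        k = (k + direction) % n
        w.walk_to(holes[k], w.arena.hole_radius)
    w.dwell(settle)


def _simulate(strategy: str, arena: ArenaSpec, p: StrategySimParams, rng) -> Trajectory:
    holes = hole_positions(arena)
    target = arena.target_hole
    n = arena.n_holes
    w = _Walker(arena, p, rng)
    settle = min(0.5, p.dwell_at_hole)  # brief pause at the escape hole

    if strategy == "direct":
        w.walk_to(holes[target], arena.hole_radius)
        w.dwell(settle)

    elif strategy == "short_chaining":
        offset = int(rng.choice([-3, -2, -1, 1, 2, 3]))
        start = (target + offset) % n
        w.walk_to(holes[start], arena.hole_radius)
        direction = 1 if _signed_offset(start, target, n) > 0 else -1
        _chain(w, holes, start, target, n, direction, settle)

    elif strategy == "long_chaining":
        offset = int(rng.integers(5, 11)) * (1 if rng.random() < 0.5 else -1)
        start = (target + offset) % n
        w.walk_to(holes[start], arena.hole_radius)
        direction = 1 if _signed_offset(start, target, n) > 0 else -1
        _chain(w, holes, start, target, n, direction, settle)

    elif strategy == "serial":
        start = int(rng.choice([k for k in range(n) if k != target]))
        w.walk_to(holes[start], arena.hole_radius)
        off = _signed_offset(start, target, n)
        if abs(off) * 2 == n:  # antipodal: both arcs tie
            direction = 1 if rng.random() < 0.5 else -1
        else:  # sweep the longer arc: the scan is not target-directed
            direction = -1 if off > 0 else 1
        _chain(w, holes, start, target, n, direction, settle)

    elif strategy == "random":
        heading = rng.uniform(0.0, 2.0 * math.pi)
        kappa = p.heading_kappa / 4.0
        tx, ty = holes[target]
        margin = arena.arena_radius - 1.0
        stop = 0.8 * arena.visit_radius  # deep enough that the target is nearest
        while not w.exhausted:
            x, y = w.pos
            if math.hypot(x - tx, y - ty) <= stop:
                w.dwell(settle)
                break
            if not p.noiseless:
                heading += rng.vonmises(0.0, kappa)
            w._step(heading)
            nx, ny = w.pos
            r = math.hypot(nx, ny)
            if r > margin:  # reflect velocity across the wall tangent
                ux, uy = nx / r, ny / r
                vx, vy = math.cos(heading), math.sin(heading)
                dot = vx * ux + vy * uy
                heading = math.atan2(vy - 2 * dot * uy, vx - 2 * dot * ux)
                scale = margin / r
                w.xs[-1], w.ys[-1] = nx * scale, ny * scale

    elif strategy == "focal_incorrect":
        wrong = (target + n // 2) % n
        w.walk_to(holes[wrong], arena.hole_radius)
        cx, cy = holes[wrong]
        while not w.exhausted:
            r = rng.uniform(0.0, 3.0)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            goal = (cx + r * math.cos(phi), cy + r * math.sin(phi))
            w.walk_to(goal, 0.5, speed_scale=0.4)
            w.dwell(0.3)

    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return w.trajectory(note=f"simulated:{strategy}")


def simulate_trajectory(
    strategy: str,
    arena: ArenaSpec | None = None,
    params: StrategySimParams | None = None,
    seed: int = 0,
) -> Trajectory:
    """Simulate one trial executing ``strategy``; deterministic in ``seed``."""
    arena = arena or ArenaSpec()
    params = params or StrategySimParams()
    return _simulate(strategy, arena, params, np.random.default_rng(seed))


def _subseed(seed: int, *parts) -> int:
    key = "|".join(str(p) for p in (seed,) + parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def simulate_cohort(manifest: SimManifest) -> tuple[Cohort, pd.DataFrame]:
    """Simulate every (group, mouse, trial) of a manifest.

    Returns the cohort plus the truth table of generating strategies for
    recovery testing.  Trials are mapped onto the standard protocol of three
    training trials per day starting on day 2.
    """
    trials: list[TrialRecord] = []
    truth_rows: list[dict] = []
    for prof in manifest.profiles:
        for m in range(manifest.n_mice):
            animal = f"{prof.name}_m{m + 1:02d}"
            for j in range(1, manifest.n_trials + 1):
                rng = np.random.default_rng(_subseed(manifest.seed, prof.name, m, j))
                mix = prof.mixture[j - 1]
                names = sorted(mix)
                strat = str(rng.choice(names, p=[mix[s] for s in names]))
                traj = _simulate(strat, manifest.arena, manifest.sim_params, rng)
                trials.append(
                    TrialRecord(
                        animal_id=animal,
                        group=prof.name,
                        day=2 + (j - 1) // 3,
                        trial_index=j,
                        phase="training",
                        trajectory=traj,
                    )
                )
                truth_rows.append(
                    {"animal_id": animal, "group": prof.name, "trial_index": j,
                     "strategy": strat}
                )
    return Cohort(trials, manifest.arena), pd.DataFrame(truth_rows)


#: mixture anchors of the built-in profiles (documented constants)
CONTROL_START = {"random": 0.6, "serial": 0.3, "long_chaining": 0.1}
CONTROL_END = {"direct": 0.5, "short_chaining": 0.3, "long_chaining": 0.1, "serial": 0.1}
IMPAIRED_MIX = {"random": 0.5, "serial": 0.35, "focal_incorrect": 0.1, "long_chaining": 0.05}


def builtin_group_profiles(n_trials: int = 9) -> tuple[GroupProfile, GroupProfile]:
    """Control-like and impaired-like strategy mixtures over training trials.

    The control-like group interpolates linearly from a random/serial-heavy
    mixture on trial 1 to a direct/short-chaining-heavy mixture on the last
    trial (a learning cohort); the impaired-like group keeps the same
    unstructured mixture on every trial.
    """
    if n_trials < 3:
        raise ValueError("builtin profiles need n_trials >= 3")
    keys = sorted(set(CONTROL_START) | set(CONTROL_END))
    mixes = []
    for i in range(n_trials):
        wgt = i / (n_trials - 1)
        mix = {
            k: (1 - wgt) * CONTROL_START.get(k, 0.0) + wgt * CONTROL_END.get(k, 0.0)
            for k in keys
        }
        total = sum(mix.values())
        mixes.append({k: v / total for k, v in mix.items() if v > 0})
    control = GroupProfile("control_like", tuple(mixes))
    impaired = GroupProfile("impaired_like", tuple(dict(IMPAIRED_MIX) for _ in range(n_trials)))
    return control, impaired


def expected_profile_score(profile: GroupProfile, weights=None) -> float:
    """Analytic expected per-mouse score under a profile (mixture x weights)."""
    from .scoring_stats import ScoreParams

    p = weights or ScoreParams()
    return float(
        np.mean([sum(prob * p.weight(s) for s, prob in mix.items())
                 for mix in profile.mixture])
    )


def export_cohort(cohort: Cohort, truth: pd.DataFrame, out_dir) -> Path:
    """Write per-trial tracking CSVs + manifest.csv + truth_labels.csv in the
    dialect :func:`barnestrat.trajectory_io.load_cohort` reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in cohort.trials:
        fname = f"{tr.animal_id}_{tr.phase}_{tr.trial_index:02d}.csv"
        write_tracking(tr.trajectory, out / fname)
        rows.append(
            {"animal_id": tr.animal_id, "group": tr.group, "day": tr.day,
             "trial_index": tr.trial_index, "phase": tr.phase, "file": fname}
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    truth.to_csv(out / "truth_labels.csv", index=False)
    return out
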