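"""Rule-based classification of Barnes-maze search strategies.

Each training trial is assigned one strategy from a fixed vocabulary by a
deterministic decision cascade over the trial's features; the first matching
rule wins, and the cascade is ordered from the most target-directed
("cognitive") strategy downward.  The hippocampus-dependent set is
{direct, short_chaining, long_chaining}.

The cascade is fully parameterised (:class:`ClassifierParams`); the defaults
were calibrated against this package's own trajectory simulator and make no
claim of equivalence with any proprietary tracking software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaSpec, circular_hole_distance
from .features import TrialFeatures, cohort_features
from .trajectory_io import Cohort

__all__ = [
    "STRATEGIES",
    "HIPPOCAMPUS_DEPENDENT",
    "StrategyLabel",
    "ClassifierParams",
    "make_label",
    "is_hippocampus_dependent",
    "classify_trial",
    "classify_cohort",
    "StrategyFrequencies",
    "strategy_frequencies",
]

STRATEGIES = (
    "direct",
    "short_chaining",
    "long_chaining",
    "serial",
    "random",
    "focal_incorrect",
    "unclassified",
)

HIPPOCAMPUS_DEPENDENT = frozenset({"direct", "short_chaining", "long_chaining"})


@dataclass(frozen=True)
class StrategyLabel:
    name: str
    hippocampus_dependent: bool

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.hippocampus_dependent != (self.name in HIPPOCAMPUS_DEPENDENT):
            raise ValueError("hippocampus_dependent flag inconsistent with name")


def make_label(name: str) -> StrategyLabel:
    return StrategyLabel(name, name in HIPPOCAMPUS_DEPENDENT)


def is_hippocampus_dependent(name: str) -> bool:
    """True for the three strategies held to need hippocampal function."""
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}")
    return name in HIPPOCAMPUS_DEPENDENT


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the decision cascade (hole distances in holes).

    ``direct_max_first_hole_dist`` is 0: a direct trial pokes the target
    first.  Allowing the adjacent hole would swallow the shortest chaining
    trials, whose visit zones overlap the target's on a standard 20-hole ring.
    """

    direct_max_first_hole_dist: int = 0
    direct_min_efficiency: float = 0.7
    direct_max_errors: int = 1
    short_chain_max_first_hole_dist: int = 3
    chain_step_max: int = 1
    chain_min_efficiency: float = 0.45
    long_chain_min_run: int = 4
    random_min_mean_step: float = 2.0
    focal_max_coverage: float = 0.1

    def __post_init__(self) -> None:
        if self.short_chain_max_first_hole_dist < self.direct_max_first_hole_dist:
            raise ValueError(
                "short_chain_max_first_hole_dist must be >= direct_max_first_hole_dist"
            )
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{f} must be >= 0")


def classify_trial(
    feat: TrialFeatures, arena: ArenaSpec, params: ClassifierParams | None = None
) -> StrategyLabel:
    """Assign one strategy label to a trial; first matching rule wins.

    Cascade, most cognitive first:

    1. direct — target poked first (within ``direct_max_first_hole_dist``),
       few primary errors, efficient path.
    2. short_chaining — >= 2 visits, starts within
       ``short_chain_max_first_hole_dist`` of the target, hole-to-hole steps of
       at most ``chain_step_max``, never strays beyond that band, no hole
       revisited, efficiency >= ``chain_min_efficiency``, ends at the target.
       The efficiency floor and revisit-free condition separate executed
       chaining from a meander that incidentally ends next to the target.
    3. long_chaining — the whole visit sequence is one monotone approach
       chain: steps <= ``chain_step_max``, circular distance to the target
       strictly decreasing, >= ``long_chain_min_run`` visits, starting beyond
       the short-chaining band, ending at the target.  Requiring the chain to
       span the whole sequence separates target-directed chaining from a
       wrap-around scan that merely *ends* near the target.
    4. serial — >= 3 visits, every step <= ``chain_step_max``, no hole
       revisited: a systematic hole-by-hole sweep without the target-approach
       structure.
    5. random — disorganised search: scattered visits (mean |step| >
       ``random_min_mean_step`` or any step beyond ``chain_step_max``),
       repeated returns to already-searched holes, or a sparse low-efficiency
       find.
    6. focal_incorrect — < 2 visits, little coverage, centroid parked at a
       wrong hole far from the target.
    7. unclassified.
    """
    p = params or ClassifierParams()
    n = arena.n_holes
    target = arena.target_hole
    seq = [h for h, _ in feat.hole_sequence]
    dists = [circular_hole_distance(h, target, n) for h in seq]
    steps = [circular_hole_distance(a, b, n) for a, b in zip(seq, seq[1:])]
    reached = feat.reached_target

    if (
        reached
        and seq
        and dists[0] <= p.direct_max_first_hole_dist
        and feat.primary_errors <= p.direct_max_errors
        and feat.path_efficiency >= p.direct_min_efficiency
    ):
        return make_label("direct")

    revisit_free = len(set(seq)) == len(seq)

    if (
        reached
        and len(seq) >= 2
        and seq[-1] == target
        and dists[0] <= p.short_chain_max_first_hole_dist
        and max(dists) <= p.short_chain_max_first_hole_dist
        and all(s <= p.chain_step_max for s in steps)
        and revisit_free
        and feat.path_efficiency >= p.chain_min_efficiency
    ):
        return make_label("short_chaining")

    if (
        reached
        and len(seq) >= p.long_chain_min_run
        and seq[-1] == target
        and dists[0] > p.short_chain_max_first_hole_dist
        and all(s <= p.chain_step_max for s in steps)
        and all(a > b for a, b in zip(dists, dists[1:]))
    ):
        return make_label("long_chaining")

    if len(seq) >= 3 and revisit_free and all(s <= p.chain_step_max for s in steps):
        return make_label("serial")

    scattered = len(seq) >= 2 and (
        float(np.mean(steps)) > p.random_min_mean_step
        or max(steps) > p.chain_step_max
        or not revisit_free
    )
    sparse_find = (
        reached
        and len(seq) <= 2
        and feat.path_efficiency < p.direct_min_efficiency
    )
    if scattered or sparse_find:
        return make_label("random")

    if (
        len(seq) < 2
        and feat.total_coverage < p.focal_max_coverage
        and feat.centroid_to_target > arena.hole_ring_radius / 2
        and feat.centroid_to_nearest_nontarget_hole <= arena.visit_radius
    ):
        return make_label("focal_incorrect")

    return make_label("unclassified")


def classify_cohort(
    cohort: Cohort,
    params: ClassifierParams | None = None,
    phases: tuple[str, ...] = ("training",),
    **feature_kwargs,
) -> pd.DataFrame:
    """Feature + classification pipeline over a cohort's trials.

    Returns one row per trial: animal_id, group, day, trial_index, phase,
    strategy, hippocampus_dependent.
    """
    rows = []
    for tr, ft in cohort_features(cohort, phases=phases, **feature_kwargs):
        label = classify_trial(ft, cohort.arena, params)
        rows.append(
            {
                "animal_id": tr.animal_id,
                "group": tr.group,
                "day": tr.day,
                "trial_index": tr.trial_index,
                "phase": tr.phase,
                "strategy": label.name,
                "hippocampus_dependent": label.hippocampus_dependent,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrategyFrequencies:
    """Per-trial counts of hippocampus-dependent strategies across a cohort.

    ``Sdf[i]``, ``Sscf[i]``, ``Slcf[i]`` count the animals classified direct,
    short-chaining and long-chaining on trial i+1; ``matrix`` is the full
    animal x trial label grid.
    """

    n_trials: int
    mc: int
    Sdf: np.ndarray
    Sscf: np.ndarray
    Slcf: np.ndarray
    matrix: pd.DataFrame


def strategy_frequencies(
    labels, n_trials: int | None = None, mc: int | None = None
) -> StrategyFrequencies:
    """Tally per-trial strategy counts from trial labels.

    ``labels`` is either a DataFrame with columns animal_id, trial_index,
    strategy (e.g. from :func:`classify_cohort`) or a mapping
    ``(animal, trial_index) -> StrategyLabel | name``.  Missing animal/trial
    cells are counted as unclassified and reported via a warning.
    """
    if isinstance(labels, pd.DataFrame):
        items = {
            (str(r.animal_id), int(r.trial_index)): str(r.strategy)
            for r in labels.itertuples(index=False)
        }
    else:
        items = {
            (str(a), int(t)): (lab.name if isinstance(lab, StrategyLabel) else str(lab))
            for (a, t), lab in labels.items()
        }
    animals = sorted({a for a, _ in items})
    trials = sorted({t for _, t in items})
    if n_trials is None:
        n_trials = max(trials) if trials else 0
    if mc is None:
        mc = len(animals)
    if mc != len(animals):
        raise ValueError(f"mc={mc} inconsistent with {len(animals)} animals present")
    if n_trials < 1 or mc < 1:
        raise ValueError("need at least one trial and one animal")

    trial_range = list(range(1, n_trials + 1))
    grid = pd.DataFrame(index=animals, columns=trial_range, dtype=object)
    missing = 0
    for a in animals:
        for t in trial_range:
            name = items.get((a, t))
            if name is None:
                name = "unclassified"
                missing += 1
            elif name not in STRATEGIES:
                raise ValueError(f"unknown strategy {name!r}")
            grid.loc[a, t] = name
    if missing:
        warnings.warn(f"{missing} missing trial label(s) counted as unclassified")

    def count(name: str) -> np.ndarray:
        return np.array([(grid[t] == name).sum() for t in trial_range], dtype=int)

    return StrategyFrequencies(
        n_trials=n_trials,
        mc=mc,
        Sdf=count("direct"),
        Sscf=count("short_chaining"),
        Slcf=count("long_chaining"),
        matrix=grid,
    )
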