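"""Cumulative strategy scoring, probe-trial metrics and group statistics.

The cumulative hippocampus-dependent strategy score averages, over training
trials, the cohort-normalised weighted frequency of the three
hippocampus-dependent strategies:

    score = (1/n) * sum_i [ Sdf_i*Sdc/mc + Sscf_i*Sscc/mc + Slcf_i*Slcc/mc ]

with weights Sdc=10 (direct), Sscc=9.5 (short chaining), Slcc=7 (long
chaining); all other strategies weigh 0.  A per-mouse score is the same
formula at mc=1, and the cohort score equals the mean of per-mouse scores
exactly — both forms are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arena import ArenaSpec, quadrant_of_angle
from .features import hole_visit_sequence
from .strategy import StrategyFrequencies, StrategyLabel
from .trajectory_io import Trajectory, resample_uniform

__all__ = [
    "ScoreParams",
    "CohortScore",
    "ProbeMetrics",
    "cumulative_strategy_score",
    "cohort_score",
    "per_mouse_score",
    "per_animal_scores",
    "probe_metrics",
    "welch_ttest",
    "learning_curve_anova",
]


@dataclass(frozen=True)
class ScoreParams:
    """Strategy weights of the cumulative score."""

    Sdc: float = 10.0   # direct
    Sscc: float = 9.5   # short chaining
    Slcc: float = 7.0   # long chaining

    def __post_init__(self) -> None:
        if not (self.Sdc >= self.Sscc >= self.Slcc >= 0):
            warnings.warn(
                "strategy weights are not in the expected order Sdc >= Sscc >= Slcc >= 0"
            )

    def weight(self, strategy: str) -> float:
        return {
            "direct": self.Sdc,
            "short_chaining": self.Sscc,
            "long_chaining": self.Slcc,
        }.get(strategy, 0.0)


@dataclass(frozen=True)
class CohortScore:
    """Per-trial hippocampus-dependent strategy counts and the mean score."""

    n: int
    mc: int
    Sdf: np.ndarray
    Sscf: np.ndarray
    Slcf: np.ndarray
    mean_score: float


@dataclass(frozen=True)
class ProbeMetrics:
    target_visits: int
    time_in_target_quadrant: float  # s
    mean_distance_to_target: float  # cm
    duration: float = 120.0


def cumulative_strategy_score(
    freqs: StrategyFrequencies | CohortScore, params: ScoreParams | None = None
) -> float:
    """Evaluate the cumulative strategy score from per-trial counts."""
    p = params or ScoreParams()
    n = freqs.n if isinstance(freqs, CohortScore) else freqs.n_trials
    mc = freqs.mc
    if n < 1 or mc < 1:
        raise ValueError("need n >= 1 trials and mc >= 1 mice")
    Sdf = np.asarray(freqs.Sdf, dtype=float)
    Sscf = np.asarray(freqs.Sscf, dtype=float)
    Slcf = np.asarray(freqs.Slcf, dtype=float)
    if not (len(Sdf) == len(Sscf) == len(Slcf) == n):
        raise ValueError("count vectors must all have length n")
    for name, arr in (("Sdf", Sdf), ("Sscf", Sscf), ("Slcf", Slcf)):
        if (arr < 0).any() or (arr > mc).any():
            raise ValueError(f"{name} counts must lie in [0, mc]")
    if (Sdf + Sscf + Slcf > mc).any():
        raise ValueError("per-trial strategy counts exceed the number of mice")
    per_trial = (Sdf * p.Sdc + Sscf * p.Sscc + Slcf * p.Slcc) / mc
    return float(per_trial.sum() / n)


def cohort_score(
    freqs: StrategyFrequencies, params: ScoreParams | None = None
) -> CohortScore:
    return CohortScore(
        n=freqs.n_trials,
        mc=freqs.mc,
        Sdf=freqs.Sdf.copy(),
        Sscf=freqs.Sscf.copy(),
        Slcf=freqs.Slcf.copy(),
        mean_score=cumulative_strategy_score(freqs, params),
    )


def per_mouse_score(labels, params: ScoreParams | None = None) -> float:
    """Mean strategy weight over one animal's trials (the mc=1 score)."""
    p = params or ScoreParams()
    names = [lab.name if isinstance(lab, StrategyLabel) else str(lab) for lab in labels]
    if not names:
        raise ValueError("per_mouse_score requires at least one trial label")
    return float(np.mean([p.weight(nm) for nm in names]))


def per_animal_scores(
    labels_df: pd.DataFrame, params: ScoreParams | None = None
) -> pd.DataFrame:
    """Per-animal scores from a label table (animal_id, group, strategy)."""
    rows = [
        {
            "animal_id": animal,
            "group": sub["group"].iloc[0],
            "score": per_mouse_score(sub["strategy"].tolist(), params),
        }
        for animal, sub in labels_df.groupby("animal_id", sort=True)
    ]
    return pd.DataFrame(rows)


def probe_metrics(
    traj: Trajectory,
    arena: ArenaSpec,
    duration: float = 120.0,
    dt: float = 0.1,
    refractory: float = 1.0,
) -> ProbeMetrics:
    """Probe-trial spatial-memory metrics over the first ``duration`` seconds.

    Target visits use the same collapsed-visit rule as training trials; the
    target quadrant is the 90-degree sector centred on the (closed) escape
    hole, and hole-zone dwell inside that sector counts toward it.
    """
    if traj.n < 2 or traj.duration <= 0:
        raise ValueError("probe_metrics requires a trajectory with positive duration")
    clipped = resample_uniform(traj.truncated(duration), dt)
    visits = hole_visit_sequence(clipped, arena, refractory)
    target_visits = sum(1 for h, _ in visits if h == arena.target_hole)
    theta = np.arctan2(clipped.y, clipped.x)
    in_quadrant = quadrant_of_angle(arena, theta) == 0
    dts = np.diff(clipped.t)
    tx, ty = arena.target_position
    dist = np.hypot(clipped.x - tx, clipped.y - ty)
    return ProbeMetrics(
        target_visits=target_visits,
        time_in_target_quadrant=float(dts[in_quadrant[:-1]].sum()),
        mean_distance_to_target=float(dist.mean()),
        duration=float(duration),
    )


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-tailed unpaired Welch t-test; returns (t, p).

    Identical constant samples return (0, 1) by convention; two constant
    samples with different means have no defined t and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both samples have zero variance and different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def learning_curve_anova(
    df: pd.DataFrame,
    dv: str = "latency",
    within: str = "trial",
    between: str = "group",
    subject: str = "animal",
) -> pd.DataFrame:
    """Two-way mixed ANOVA: between factor group, within factor trial.

    Standard sums-of-squares decomposition for the balanced (equal trials per
    subject) mixed design: the group effect is tested against subjects-within-
    groups, trial and interaction against the subject-by-trial residual.
    Subjects with missing trials are excluded listwise with a warning.
    Degenerate effects with zero sum of squares report F=0, p=1.

    Returns a DataFrame indexed by effect (group, trial, interaction) with
    columns SS, df1, df2, F, p.
    """
    data = df[[subject, between, within, dv]].dropna()
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    complete = counts[counts == n_levels].index
    if len(complete) < len(counts):
        warnings.warn(
            f"excluded {len(counts) - len(complete)} subject(s) with missing trials"
        )
        data = data[data[subject].isin(complete)]
    groups = data[between].unique()
    trials = data[within].unique()
    a, b = len(groups), len(trials)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 groups and >= 2 trials")

    y = data[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = data.groupby(subject)[dv].mean()
    subj_group = data.groupby(subject)[between].first()
    n_subj = len(subj_means)
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    group_means = data.groupby(between)[dv].mean()
    group_sizes = subj_group.value_counts()
    ss_group = float(
        sum(b * group_sizes[g] * (group_means[g] - grand) ** 2 for g in groups)
    )
    ss_subj_within = ss_between_subj - ss_group

    trial_counts = data.groupby(within)[dv].count()
    trial_means = data.groupby(within)[dv].mean()
    ss_trial = float(sum(trial_counts[t] * (trial_means[t] - grand) ** 2 for t in trials))

    cell = data.groupby([between, within])[dv].agg(["mean", "count"])
    ss_cells = float((cell["count"] * (cell["mean"] - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_trial
    ss_error = ss_total - ss_between_subj - ss_trial - ss_inter

    effects = {
        "group": (ss_group, a - 1, ss_subj_within, n_subj - a),
        "trial": (ss_trial, b - 1, ss_error, (n_subj - a) * (b - 1)),
        "interaction": (ss_inter, (a - 1) * (b - 1), ss_error, (n_subj - a) * (b - 1)),
    }
    rows = {}
    for name, (ss, df1, ss_err, df2) in effects.items():
        if ss <= 1e-12:
            F, p = 0.0, 1.0
        else:
            ms, ms_err = ss / df1, ss_err / df2
            if ms_err == 0:
                F, p = float("inf"), 0.0
            else:
                F = ms / ms_err
                p = float(stats.f.sf(F, df1, df2))
        rows[name] = {"SS": ss, "df1": df1, "df2": df2, "F": F, "p": p}
    return pd.DataFrame.from_dict(rows, orient="index")
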