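import math

import numpy as np
import pandas as pd
import pytest

from barnestrat.arena import ArenaSpec, hole_positions
from barnestrat.scoring_stats import (
    CohortScore,
    ScoreParams,
    cohort_score,
    cumulative_strategy_score,
    learning_curve_anova,
    per_animal_scores,
    per_mouse_score,
    probe_metrics,
    welch_ttest,
)
from barnestrat.strategy import STRATEGIES, strategy_frequencies
from barnestrat.trajectory_io import Trajectory

from conftest import make_traj

HIPPO_WEIGHTS = {"direct": 10.0, "short_chaining": 9.5, "long_chaining": 7.0}


def freqs_from_matrix(matrix):
    """matrix: list (animals) of list (trials) of strategy names."""
    labels = {
        (f"m{a}", t + 1): name
        for a, row in enumerate(matrix)
        for t, name in enumerate(row)
    }
    return strategy_frequencies(labels, n_trials=len(matrix[0]), mc=len(matrix))


class TestCumulativeScore:
    def test_single_mouse_all_direct_scores_ten(self):
        fq = freqs_from_matrix([["direct"] * 9])
        assert cumulative_strategy_score(fq) == pytest.approx(10.0)

    def test_no_hippocampal_strategies_scores_zero(self):
        fq = freqs_from_matrix([["random", "serial", "focal_incorrect"]])
        assert cumulative_strategy_score(fq) == 0.0

    def test_hand_arithmetic_two_mice_two_trials(self):
        # trial 1: both direct; trial 2: one short chaining
        # (1/2) * [2*10/2 + 1*9.5/2] = 7.375
        fq = freqs_from_matrix(
            [["direct", "short_chaining"], ["direct", "random"]]
        )
        assert cumulative_strategy_score(fq) == pytest.approx(7.375)

    def test_count_exceeding_mc_is_error(self):
        bad = CohortScore(n=1, mc=1, Sdf=np.array([2]), Sscf=np.array([0]),
                          Slcf=np.array([0]), mean_score=0.0)
        with pytest.raises(ValueError):
            cumulative_strategy_score(bad)

    def test_zero_mice_is_error(self):
        bad = CohortScore(n=1, mc=0, Sdf=np.array([0]), Sscf=np.array([0]),
                          Slcf=np.array([0]), mean_score=0.0)
        with pytest.raises(ValueError):
            cumulative_strategy_score(bad)

    def test_doubling_mice_and_counts_leaves_score_unchanged(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 10))
            mc = int(rng.integers(1, 6))
            counts = [rng.multinomial(mc, [0.2, 0.2, 0.2, 0.4])[:3] for _ in range(n)]
            fq1 = CohortScore(n=n, mc=mc,
                              Sdf=np.array([c[0] for c in counts]),
                              Sscf=np.array([c[1] for c in counts]),
                              Slcf=np.array([c[2] for c in counts]), mean_score=0.0)
            fq2 = CohortScore(n=n, mc=2 * mc,
                              Sdf=2 * fq1.Sdf, Sscf=2 * fq1.Sscf, Slcf=2 * fq1.Slcf,
                              mean_score=0.0)
            assert cumulative_strategy_score(fq2) == pytest.approx(
                cumulative_strategy_score(fq1), abs=1e-12
            )

    def test_unordered_weights_warn_but_do_not_fail(self):
        with pytest.warns(UserWarning, match="order"):
            ScoreParams(Sdc=1.0, Sscc=9.5, Slcc=7.0)


class TestPerMouseScore:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["direct", "long_chaining"], 8.5),
            (["serial", "serial", "serial"], 0.0),
            (["short_chaining"], 9.5),
            (["direct", "random", "unclassified"], 10.0 / 3),
        ],
    )
    def test_examples(self, labels, expected):
        assert per_mouse_score(labels) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            per_mouse_score([])

    def test_mean_of_per_mouse_equals_cohort_formula(self):
        """Exact identity between per-animal averaging and the pooled formula."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            mc = int(rng.integers(1, 8))
            n = int(rng.integers(1, 12))
            matrix = [
                [STRATEGIES[rng.integers(0, len(STRATEGIES))] for _ in range(n)]
                for _ in range(mc)
            ]
            cohort = cumulative_strategy_score(freqs_from_matrix(matrix))
            per_mouse = np.mean([per_mouse_score(row) for row in matrix])
            assert abs(cohort - per_mouse) < 1e-12

    def test_score_bounds_and_maximum_iff_all_direct(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            mc, n = int(rng.integers(1, 5)), int(rng.integers(1, 8))
            matrix = [
                [STRATEGIES[rng.integers(0, len(STRATEGIES))] for _ in range(n)]
                for _ in range(mc)
            ]
            s = cumulative_strategy_score(freqs_from_matrix(matrix))
            assert 0.0 <= s <= 10.0
            if all(name == "direct" for row in matrix for name in row):
                assert s == pytest.approx(10.0)
            else:
                assert s < 10.0

    def test_upgrading_one_trial_never_decreases_score(self):
        order = ["unclassified", "long_chaining", "short_chaining", "direct"]
        rng = np.random.default_rng(2)
        for _ in range(100):
            mc, n = int(rng.integers(1, 4)), int(rng.integers(1, 6))
            matrix = [
                [order[rng.integers(0, 3)] for _ in range(n)] for _ in range(mc)
            ]
            s0 = cumulative_strategy_score(freqs_from_matrix(matrix))
            i, j = int(rng.integers(0, mc)), int(rng.integers(0, n))
            matrix[i][j] = order[order.index(matrix[i][j]) + 1]
            s1 = cumulative_strategy_score(freqs_from_matrix(matrix))
            assert s1 >= s0 - 1e-12

    def test_per_animal_scores_frame(self):
        labels = pd.DataFrame(
            {
                "animal_id": ["a", "a", "b", "b"],
                "group": ["g1", "g1", "g2", "g2"],
                "trial_index": [1, 2, 1, 2],
                "strategy": ["direct", "serial", "long_chaining", "long_chaining"],
            }
        )
        out = per_animal_scores(labels)
        assert out.set_index("animal_id")["score"].to_dict() == {"a": 5.0, "b": 7.0}


class TestProbeMetrics:
    def test_never_near_target_or_quadrant(self, arena):
        traj = make_traj([(-20, 0), (-20, 1)], dt=60.0)
        m = probe_metrics(traj, arena)
        assert m.target_visits == 0
        assert m.time_in_target_quadrant == 0.0

    def test_two_separated_crossings_count_twice(self, arena):
        tgt = tuple(hole_positions(arena)[0])
        far = (-20.0, 0.0)
        traj = make_traj([tgt, far, far, far, tgt, tgt], dt=5.0)
        assert probe_metrics(traj, arena).target_visits == 2

    def test_stationary_at_target_center(self, arena):
        traj = make_traj([(40, 0), (40, 0)], dt=120.0)
        m = probe_metrics(traj, arena, duration=120.0)
        assert m.time_in_target_quadrant == pytest.approx(120.0)
        assert m.mean_distance_to_target == pytest.approx(0.0)

    def test_clips_to_duration(self, arena):
        # 240 s half in quadrant 2, second half at target; only first 120 s count
        pts = [(-20, 0)] * 3 + [(40, 0)]
        traj = make_traj(pts, dt=80.0)
        m = probe_metrics(traj, arena, duration=120.0)
        assert m.time_in_target_quadrant == 0.0
        assert m.target_visits == 0

    def test_single_sample_is_error(self, arena):
        with pytest.raises(ValueError):
            probe_metrics(Trajectory([0.0], [0.0], [0.0]), arena)


class TestWelchTTest:
    def test_identical_samples(self):
        t, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_sample_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        t, p = welch_ttest(a, b)
        se = math.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se)
        assert p < 0.01

    def test_sign_antisymmetric_under_swap(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0]
        t_ab, p_ab = welch_ttest(a, b)
        t_ba, p_ba = welch_ttest(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_degenerate_constant_inputs(self):
        assert welch_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            welch_ttest([2.0, 2.0], [3.0, 3.0])

    def test_sample_too_small_is_error(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])


def long_frame(values, groups, n_trials):
    """values: dict animal -> list of per-trial scores."""
    rows = []
    for animal, vals in values.items():
        for t, v in enumerate(vals, start=1):
            rows.append(
                {"animal": animal, "group": groups[animal], "trial": t, "latency": v}
            )
    return pd.DataFrame(rows)


class TestLearningCurveAnova:
    def test_all_equal_values_give_zero_f(self):
        df = long_frame(
            {"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5], "d": [5, 5, 5]},
            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
            3,
        )
        out = learning_curve_anova(df)
        assert (out["F"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_pure_group_effect(self):
        base = {"a": [3.0, 3.1, 2.9], "b": [3.1, 3.0, 3.0]}
        shifted = {"c": [13.0, 13.1, 12.9], "d": [13.1, 13.0, 13.0]}
        df = long_frame(
            {**base, **shifted},
            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
            3,
        )
        out = learning_curve_anova(df)
        assert out.loc["group", "F"] > 100
        assert out.loc["group", "p"] < 0.01
        assert out.loc["trial", "F"] < 5

    def test_fewer_than_two_groups_is_error(self):
        df = long_frame({"a": [1, 2], "b": [2, 3]}, {"a": "g1", "b": "g1"}, 2)
        with pytest.raises(ValueError):
            learning_curve_anova(df)

    def test_incomplete_subject_excluded_with_warning(self):
        df = long_frame(
            {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5], "d": [4, 5, 6]},
            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
            3,
        )
        df = df[~((df.animal == "d") & (df.trial == 3))]
        with pytest.warns(UserWarning, match="excluded 1"):
            learning_curve_anova(df)

    def test_matches_pingouin_on_random_balanced_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        values = {f"m{i}": rng.normal(10, 2, size=5).tolist() for i in range(8)}
        groups = {f"m{i}": ("g1" if i < 4 else "g2") for i in range(8)}
        df = long_frame(values, groups, 5)
        mine = learning_curve_anova(df)
        ref = pingouin.mixed_anova(
            data=df, dv="latency", within="trial", between="group", subject="animal"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert mine.loc["trial", "F"] == pytest.approx(ref.loc["trial", "F"])
        assert mine.loc["interaction", "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert mine.loc["trial", "p"] == pytest.approx(ref.loc["trial", "p_unc"])

    def test_null_permutations_rarely_significant(self):
        rng = np.random.default_rng(21)
        base = rng.normal(10, 2, size=(8, 4))
        n_sig = 0
        n_perm = 100
        for _ in range(n_perm):
            order = rng.permutation(8)
            values = {f"m{i}": base[i].tolist() for i in range(8)}
            groups = {f"m{i}": ("g1" if int(np.where(order == i)[0][0]) < 4 else "g2")
                      for i in range(8)}
            out = learning_curve_anova(long_frame(values, groups, 4))
            n_sig += out.loc["group", "p"] < 0.05
        assert n_sig <= 15  # ~5% expected under the null
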