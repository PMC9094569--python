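"""Log analytics on hand-constructed episode logs."""

import numpy as np
import pytest

from snnpong.analysis import (compare_before_after, correct_move_heatmap,
                              cumulative_performance, extract_trajectories,
                              motor_coverage_fraction, participation_matrix,
                              trajectory_performance_table)
from snnpong.game import GameConfig
from snnpong.loop import EpisodeLog, hit_miss_ratio


def make_log(steps, spikes=(), pop_slices=None, dt=20.0, config=None):
    """Build an EpisodeLog from per-step dicts.

    Each step dict may carry ball state (x, y, dx, dy), racket_y, action,
    event and critic; omitted keys default to quiet values.
    """
    log = EpisodeLog(game_config=config or GameConfig().scaled(4),
                     game_step_ms=dt,
                     pop_slices=pop_slices or {"EMUP": (0, 3),
                                               "EMDOWN": (3, 6)})
    n = len(steps)
    defaults = dict(x=0, y=0, dx=1, dy=0, racket_y=0, action=0,
                    event="none", critic=np.nan, up=0, down=0)
    cols = {k: [] for k in defaults}
    for s in steps:
        for k, v in defaults.items():
            cols[k].append(s.get(k, v))
    log.ball_x = np.array(cols["x"])
    log.ball_y = np.array(cols["y"])
    log.ball_dx = np.array(cols["dx"])
    log.ball_dy = np.array(cols["dy"])
    log.racket_y = np.array(cols["racket_y"])
    log.action = np.array(cols["action"])
    log.event = np.array(cols["event"])
    log.critic = np.array(cols["critic"], dtype=float)
    log.count_up = np.array(cols["up"])
    log.count_down = np.array(cols["down"])
    if spikes:
        t, i = zip(*spikes)
        log.spikes_t = np.array(t, dtype=float)
        log.spikes_i = np.array(i, dtype=np.int64)
    else:
        log.spikes_t = np.empty(0)
        log.spikes_i = np.empty(0, dtype=np.int64)
    log.hits = int(np.sum(log.event == "hit"))
    log.misses = int(np.sum(log.event == "miss"))
    return log


def approach(x0, n, outcome, y=10, dy=0):
    """n steps of the ball moving toward the racket, ending in hit/miss."""
    steps = [dict(x=x0 + 2 * i, y=y + dy * i, dx=2, dy=dy) for i in range(n)]
    steps[-1]["event"] = outcome
    return steps


class TestCumulativePerformance:
    def test_final_ratio(self):
        steps = []
        for _ in range(9):
            steps += approach(0, 2, "hit")
        for _ in range(10):
            steps += approach(0, 2, "miss")
        df = cumulative_performance(make_log(steps))
        assert df["ratio"].iloc[-1] == pytest.approx(0.9)
        assert df["hits"].iloc[-1] == 9 and df["misses"].iloc[-1] == 10

    def test_empty_log(self):
        assert cumulative_performance(make_log([])).empty

    def test_piecewise_constant_between_events(self):
        steps = approach(0, 5, "hit") + approach(0, 5, "miss")
        df = cumulative_performance(make_log(steps))
        # counts change only at event steps
        assert (np.diff(df["hits"]) != 0).sum() == 1
        assert (np.diff(df["misses"]) != 0).sum() == 1

    def test_zero_misses_is_inf(self):
        df = cumulative_performance(make_log(approach(0, 3, "hit")))
        assert np.isinf(df["ratio"].iloc[-1])


class TestTrajectories:
    def test_three_known_paths(self):
        log = make_log(approach(0, 3, "hit") + approach(0, 3, "miss", y=20)
                       + approach(4, 2, "hit", y=30))
        groups = extract_trajectories([log], min_repeats=1)
        assert len(groups) == 3

    def test_min_repeats_excludes_rare(self):
        steps = []
        for _ in range(4):
            steps += approach(0, 3, "hit")  # repeated 4 times
        log = make_log(steps)
        assert extract_trajectories([log], min_repeats=5) == []
        assert len(extract_trajectories([log], min_repeats=4)) == 1

    def test_identical_episodes_double_counts(self):
        log = make_log(approach(0, 3, "hit") + approach(0, 3, "miss", y=20))
        groups = extract_trajectories([log, log], min_repeats=2)
        assert all(g.n_repeats == 2 for g in groups)
        assert len(groups) == 2

    def test_cumulative_ratio_sequence(self):
        steps = (approach(0, 2, "hit") + approach(0, 2, "hit")
                 + approach(0, 2, "miss") + approach(0, 2, "hit"))
        log = make_log(steps)
        g = extract_trajectories([log], min_repeats=4)[0]
        ratios = g.cumulative_ratios()
        assert np.isinf(ratios[0]) and np.isinf(ratios[1])
        assert ratios[2] == 2.0 and ratios[3] == 3.0

    def test_performance_table(self):
        steps = (approach(0, 2, "hit") + approach(0, 2, "miss")
                 + approach(0, 2, "hit") + approach(0, 2, "miss"))
        df = trajectory_performance_table(
            extract_trajectories([make_log(steps)], min_repeats=4))
        row = df.iloc[0]
        assert row["final_ratio"] == 1.0
        assert np.isinf(row["peak_ratio"])  # spotless before the first miss
        assert row["peak_repeat"] == 1
        assert row["rel_peak_repeat"] == pytest.approx(0.25)


class TestCorrectMoveHeatmap:
    def test_oracle_follower_all_ones(self):
        steps = [dict(x=4, y=10, critic=0.1), dict(x=8, y=10, critic=0.1)]
        hm = correct_move_heatmap([make_log(steps)])
        assert hm[11, 5] == 1.0 and hm[11, 9] == 1.0

    def test_anti_follower_all_zero(self):
        steps = [dict(x=4, y=10, critic=-0.01)]
        hm = correct_move_heatmap([make_log(steps)])
        assert hm[11, 5] == 0.0

    def test_unvisited_nan(self):
        hm = correct_move_heatmap([make_log([dict(x=4, y=10, critic=0.1)])])
        assert np.isnan(hm[0, 0])
        assert np.isnan(hm).sum() == hm.size - 1

    def test_half_correct(self):
        steps = [dict(x=4, y=10, critic=0.1), dict(x=4, y=10, critic=-0.01)]
        hm = correct_move_heatmap([make_log(steps)])
        assert hm[11, 5] == 0.5


class TestParticipation:
    def _log_with_counts(self, counts_per_encounter):
        """Two encounters of one trajectory; EMUP spike counts prescribed."""
        steps = approach(0, 2, "hit") + approach(0, 2, "hit")
        spikes = []
        for e, counts in enumerate(counts_per_encounter):
            t0 = e * 2 * 20.0  # encounter e covers steps [2e, 2e+2)
            for neuron, c in enumerate(counts):
                spikes += [(t0 + 1.0 + 0.1 * k, neuron) for k in range(c)]
        return make_log(steps, spikes=spikes)

    def test_matches_exhaustive_enumeration(self):
        # 3 EMUP neurons; top-70% of 3 = ceil(2.1) = 3 -> all marked
        log = self._log_with_counts([(5, 2, 0), (1, 4, 0)])
        mat, mean = participation_matrix([log], "EMUP", top_fraction=0.7,
                                         min_repeats=2)
        assert mat.shape == (1, 3)
        assert mat.iloc[0].tolist() == [1.0, 1.0, 1.0]

    def test_top_third_selects_max_only(self):
        log = self._log_with_counts([(5, 2, 0), (1, 4, 0)])
        mat, mean = participation_matrix([log], "EMUP", top_fraction=1 / 3,
                                         min_repeats=2)
        # encounter 1: neuron 0 max; encounter 2: neuron 1 max
        assert mat.iloc[0].tolist() == [0.5, 0.5, 0.0]
        assert mean.tolist() == [0.5, 0.5, 0.0]

    def test_monotone_in_top_fraction(self):
        log = self._log_with_counts([(5, 2, 1), (1, 4, 2)])
        prev = None
        for f in (1 / 3, 2 / 3, 1.0):
            mat, _ = participation_matrix([log], "EMUP", top_fraction=f,
                                          min_repeats=2)
            if prev is not None:
                assert (mat.values >= prev - 1e-12).all()
            prev = mat.values

    def test_full_fraction_all_ones(self):
        log = self._log_with_counts([(5, 2, 0), (1, 4, 0)])
        mat, _ = participation_matrix([log], "EMUP", top_fraction=1.0,
                                      min_repeats=2)
        assert (mat.values == 1.0).all()


class TestCoverage:
    def test_all_silent(self):
        log = make_log(approach(0, 4, "hit"))
        assert motor_coverage_fraction([log]) == 0.0

    def test_half_covered(self):
        log = make_log(approach(0, 4, "hit"),
                       spikes=[(5.0, 0), (25.0, 4)])  # windows 0 and 1 of 4
        assert motor_coverage_fraction([log]) == 0.5

    def test_union_monotone(self):
        log = make_log(approach(0, 4, "hit"),
                       spikes=[(5.0, 0), (45.0, 4)])
        both = motor_coverage_fraction([log], ("EMUP", "EMDOWN"))
        up = motor_coverage_fraction([log], ("EMUP",))
        assert both >= up


class TestTTest:
    def test_identical_groups(self):
        t, p, degenerate = compare_before_after([1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0 and degenerate

    def test_separated_groups(self):
        a = [0.0, 1e-6, 0.0]
        b = [1.0, 1.0 - 1e-6, 1.0]
        t, p, degenerate = compare_before_after(a, b)
        assert p < 0.001 and not degenerate

    def test_textbook_values(self):
        """Cross-checked against the closed-form pooled-variance t."""
        a = [2.1, 2.5, 2.3, 2.7]
        b = [3.1, 3.5, 3.3]
        t, p, _ = compare_before_after(a, b)
        na, nb = 4, 3
        ma, mb = np.mean(a), np.mean(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
            / (na + nb - 2)
        t_ref = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_ref, rel=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_before_after([1.0], [1.0, 2.0])


def test_hit_miss_ratio_sentinels():
    assert hit_miss_ratio(3, 0) == np.inf
    assert np.isnan(hit_miss_ratio(0, 0))
    assert hit_miss_ratio(9, 10) == pytest.approx(0.9)
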