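"""Performance and population-activity analyses over episode logs.

All analytics are pure functions of :class:`~snnpong.loop.EpisodeLog`
objects: hit/miss performance curves, ball-trajectory extraction and
per-trajectory learning curves, correct-move probability maps, and motor
neuron participation statistics.  The hit/miss ratio of a spotless record
(zero misses) is reported as ``inf`` — tables always carry raw hit and miss
counts alongside so no information is lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .loop import EpisodeLog, hit_miss_ratio

__all__ = [
    "cumulative_performance", "Trajectory", "TrajectoryGroup",
    "extract_trajectories", "trajectory_performance_table",
    "correct_move_heatmap", "participation_matrix",
    "motor_coverage_fraction", "population_rate_per_trajectory",
    "compare_before_after",
]


def cumulative_performance(log: EpisodeLog) -> pd.DataFrame:
    """Running hit and miss counts and their ratio, one row per game-step."""
    if log.n_steps == 0:
        return pd.DataFrame(columns=["time_ms", "hits", "misses", "ratio"])
    hits = np.cumsum(log.event == "hit")
    misses = np.cumsum(log.event == "miss")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(misses > 0, hits / np.maximum(misses, 1),
                         np.where(hits > 0, np.inf, np.nan))
    t = (np.arange(log.n_steps) + 1) * log.game_step_ms
    return pd.DataFrame({"time_ms": t, "hits": hits, "misses": misses,
                         "ratio": ratio})


@dataclass(frozen=True)
class Trajectory:
    """One encounter of the ball travelling toward the racket."""

    episode: int
    start: int       # first step index with the ball moving toward the racket
    end: int         # step index whose event resolved the encounter
    states: Tuple[Tuple[int, int, int, int], ...]
    outcome: str     # "hit" | "miss"


@dataclass
class TrajectoryGroup:
    """All encounters of one unique ball trajectory (exact state sequence)."""

    traj_id: int
    states: Tuple[Tuple[int, int, int, int], ...]
    encounters: List[Trajectory] = dc_field(default_factory=list)

    @property
    def outcomes(self) -> List[str]:
        return [e.outcome for e in self.encounters]

    @property
    def n_repeats(self) -> int:
        return len(self.encounters)

    def cumulative_ratios(self) -> np.ndarray:
        h = m = 0
        out = []
        for o in self.outcomes:
            h += o == "hit"
            m += o == "miss"
            out.append(hit_miss_ratio(h, m))
        return np.array(out)


def _encounters(log: EpisodeLog, episode: int) -> Iterable[Trajectory]:
    """Split one episode into ball-approach segments ending in hit or miss."""
    start = None
    states: List[Tuple[int, int, int, int]] = []
    for i in range(log.n_steps):
        moving_in = log.ball_dx[i] > 0
        if moving_in and start is None:
            start = i
            states = []
        if start is not None:
            states.append((int(log.ball_x[i]), int(log.ball_y[i]),
                           int(log.ball_dx[i]), int(log.ball_dy[i])))
            ev = log.event[i]
            if ev in ("hit", "miss"):
                yield Trajectory(episode, start, i, tuple(states), str(ev))
                start = None
            elif log.ball_dx[i] <= 0:  # pragma: no cover - defensive
                start = None


def extract_trajectories(logs: Sequence[EpisodeLog],
                         min_repeats: int = 5) -> List[TrajectoryGroup]:
    """Group encounters by exact state-sequence identity.

    Unique trajectories are numbered in order of first occurrence; only
    those repeated at least ``min_repeats`` times are returned.
    """
    groups: Dict[Tuple, TrajectoryGroup] = {}
    next_id = 0
    for ep, log in enumerate(logs):
        for enc in _encounters(log, ep):
            grp = groups.get(enc.states)
            if grp is None:
                grp = TrajectoryGroup(next_id, enc.states)
                groups[enc.states] = grp
                next_id += 1
            grp.encounters.append(enc)
    return [g for g in groups.values() if g.n_repeats >= min_repeats]


def trajectory_performance_table(groups: Sequence[TrajectoryGroup]) -> pd.DataFrame:
    """Per-trajectory peak and median performance over ordered repeats.

    ``rel_peak_repeat`` is the (1-based) repeat index of the best cumulative
    ratio divided by the number of repeats — values near 1 mean the model
    kept improving until the end, values near 0 mean it only forgot.
    """
    rows = []
    for g in groups:
        ratios = g.cumulative_ratios()
        finite_max = np.nanmax(np.where(np.isinf(ratios), -np.inf, ratios))
        peak_idx = int(np.argmax(np.where(np.isnan(ratios), -np.inf, ratios)))
        rows.append({
            "traj_id": g.traj_id,
            "n_repeats": g.n_repeats,
            "hits": sum(o == "hit" for o in g.outcomes),
            "misses": sum(o == "miss" for o in g.outcomes),
            "final_ratio": ratios[-1],
            "peak_ratio": ratios[peak_idx],
            "peak_ratio_finite": finite_max,
            "median_ratio": float(np.median(ratios)),
            "peak_repeat": peak_idx + 1,
            "rel_peak_repeat": (peak_idx + 1) / g.n_repeats,
        })
    return pd.DataFrame(rows)


def correct_move_heatmap(logs: Sequence[EpisodeLog]) -> np.ndarray:
    """P(action was favorable | ball at pixel), NaN where never visited.

    A step counts as favorable when its logged intermediate critic was a
    reward, i.e. the action moved the racket toward the projected intercept
    or held it on target.  Steps with the ball moving away from the racket
    (no projection) contribute nothing, so the region right of the racket
    column stays NaN.
    """
    g = logs[0].game_config
    visits = np.zeros((g.court_height, g.court_width))
    correct = np.zeros_like(visits)
    half = g.ball_size // 2
    for log in logs:
        mask = ~np.isnan(log.critic)
        xs = np.minimum(log.ball_x[mask] + half, g.court_width - 1)
        ys = np.minimum(log.ball_y[mask] + half, g.court_height - 1)
        good = log.critic[mask] > 0
        np.add.at(visits, (ys, xs), 1)
        np.add.at(correct, (ys, xs), good.astype(float))
    with np.errstate(invalid="ignore"):
        return np.where(visits > 0, correct / np.maximum(visits, 1), np.nan)


def _window_of(enc: Trajectory, dt: float) -> Tuple[float, float]:
    return enc.start * dt, (enc.end + 1) * dt


def _pop_spike_counts(log: EpisodeLog, pop: str, t0: float, t1: float) -> np.ndarray:
    a, b = log.pop_slices[pop]
    sel = (log.spikes_t >= t0) & (log.spikes_t < t1) & \
          (log.spikes_i >= a) & (log.spikes_i < b)
    return np.bincount(log.spikes_i[sel] - a, minlength=b - a)


def participation_matrix(logs: Sequence[EpisodeLog], population: str = "EMUP",
                         top_fraction: float = 0.7, min_repeats: int = 5
                         ) -> Tuple[pd.DataFrame, pd.Series]:
    """P(neuron among the top-X% most active | trajectory), plus neuron means.

    For every encounter of a unique ball trajectory, neurons are ranked by
    spike count within the encounter window and the ``ceil(f * N)`` most
    active are marked; ties at the cutoff are all included.  Entry (i, j) is
    the fraction of encounters of trajectory i in which neuron j was marked.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    groups = extract_trajectories(logs, min_repeats=min_repeats)
    a, b = logs[0].pop_slices[population]
    n = b - a
    m = math.ceil(top_fraction * n)
    rows = {}
    for g in groups:
        marks = np.zeros(n)
        for enc in g.encounters:
            log = logs[enc.episode]
            t0, t1 = _window_of(enc, log.game_step_ms)
            counts = _pop_spike_counts(log, population, t0, t1)
            cutoff = np.sort(counts)[::-1][m - 1]
            marks += counts >= cutoff
        rows[g.traj_id] = marks / g.n_repeats
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.index.name = "traj_id"
    mat.columns.name = "neuron"
    return mat, mat.mean(axis=0)


def motor_coverage_fraction(logs: Sequence[EpisodeLog],
                            populations: Sequence[str] = ("EMUP", "EMDOWN")
                            ) -> float:
    """Fraction of action windows with at least one spike in the populations."""
    covered = total = 0
    for log in logs:
        dt = log.game_step_ms
        win = np.zeros(log.n_steps, dtype=bool)
        for pop in populations:
            a, b = log.pop_slices[pop]
            sel = (log.spikes_i >= a) & (log.spikes_i < b)
            idx = (log.spikes_t[sel] // dt).astype(int)
            idx = idx[idx < log.n_steps]
            win[idx] = True
        covered += int(win.sum())
        total += log.n_steps
    return covered / total if total else 0.0


def population_rate_per_trajectory(logs: Sequence[EpisodeLog], population: str,
                                   min_repeats: int = 1) -> pd.DataFrame:
    """Mean population firing rate (Hz) during each trajectory encounter."""
    groups = extract_trajectories(logs, min_repeats=min_repeats)
    a, b = logs[0].pop_slices[population]
    size = b - a
    rows = []
    for g in groups:
        for k, enc in enumerate(g.encounters):
            log = logs[enc.episode]
            t0, t1 = _window_of(enc, log.game_step_ms)
            n_spikes = _pop_spike_counts(log, population, t0, t1).sum()
            rows.append({"traj_id": g.traj_id, "repeat": k,
                         "episode": enc.episode, "outcome": enc.outcome,
                         "rate_hz": 1000.0 * n_spikes / (size * (t1 - t0))})
    return pd.DataFrame(rows)


def compare_before_after(perf_before: Sequence[float],
                         perf_after: Sequence[float]
                         ) -> Tuple[float, float, bool]:
    """Two-sample t-test on per-repeat cumulative hit/miss ratios.

    Returns ``(t, p, degenerate)``; ``degenerate`` flags zero variance in
    both groups, where the test statistic is defined by the limit (t = 0,
    p = 1 for equal means; infinite separation otherwise).
    """
    a = np.asarray(perf_before, dtype=float)
    b = np.asarray(perf_after, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p), False
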