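"""Court dynamics: serves, bounces, collisions and the intercept oracle."""

from fractions import Fraction

import numpy as np
import pytest

from snnpong.game import (Action, GameConfig, GameEnv, GameState,
                          intermediate_critic, project_ball_intercept,
                          render_frame, reset, step)
from snnpong.game import _intercept_folded


def brute_force_intercept(state: GameState, cfg: GameConfig):
    """Exact no-racket ray trace in rational arithmetic (test oracle).

    Advances the ball one horizontal pixel at a time with triangle-wave
    reflection of the vertical position, until the ball's right edge reaches
    the racket column.
    """
    if state.ball_dx <= 0:
        return None
    L = cfg.court_height - cfg.ball_size
    y = Fraction(state.ball_y)
    v = Fraction(state.ball_dy, state.ball_dx)
    p = cfg.racket_x - state.ball_x - cfg.ball_size + 1
    for _ in range(max(p, 0)):
        y += v
        if y < 0:
            y, v = -y, -v
        elif y > L:
            y, v = 2 * L - y, -v
    return y + Fraction(cfg.ball_size - 1, 2)


class TestReset:
    def test_forced_positions_echoed(self, config):
        s = reset(config, 1, init_ball=(0, 80), init_racket=72)
        assert (s.ball_x, s.ball_y, s.racket_y) == (0, 80, 72)

    def test_same_seed_same_state(self, config):
        assert reset(config, 7) == reset(config, 7)

    def test_out_of_court_rejected(self, config):
        with pytest.raises(ValueError):
            reset(config, 1, init_ball=(0, 200))
        with pytest.raises(ValueError):
            reset(config, 1, init_racket=190)

    def test_serve_rows_uniform(self, config):
        """Serve rows are uniform over the stated choices (3-sigma binomial)."""
        rng = np.random.default_rng(5)
        n = 100_000
        counts = {y: 0 for y in config.serve_y_choices}
        for _ in range(n):
            counts[reset(config, rng).ball_y] += 1
        p = 1 / len(config.serve_y_choices)
        sigma = np.sqrt(n * p * (1 - p))
        for y, c in counts.items():
            assert abs(c - n * p) < 3 * sigma, f"row {y} count {c}"

    def test_serve_velocity_from_choices(self, config):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = reset(config, rng)
            assert (s.ball_dx, abs(s.ball_dy)) in config.serve_velocity_choices
            assert s.ball_x == 0


class TestStep:
    def test_top_wall_flips_dy_only(self, config, rng):
        s = GameState(50, 1, 2, -2, 72)
        nxt, out = step(s, Action.STAY, config, rng)
        assert (nxt.ball_dy, nxt.ball_dx) == (2, 2)
        assert nxt.ball_y == 1  # reflected: 1 - 2 -> -1 -> 1
        assert out.event == "none"

    def test_stay_keeps_racket(self, config, rng):
        s = GameState(50, 80, 1, 1, 72)
        nxt, _ = step(s, Action.STAY, config, rng)
        assert nxt.racket_y == 72

    def test_up_down_move_by_step(self, config, rng):
        s = GameState(50, 80, 1, 1, 72)
        assert step(s, Action.UP, config, rng)[0].racket_y == 72 - config.racket_step
        assert step(s, Action.DOWN, config, rng)[0].racket_y == 72 + config.racket_step

    def test_racket_clamped_to_court(self, config, rng):
        s = GameState(50, 80, 1, 1, 0)
        assert step(s, Action.UP, config, rng)[0].racket_y == 0

    def test_center_hit_flips_dx_keeps_speed(self, config):
        # ball just left of the racket, aligned with its center
        s = GameState(config.racket_x - 5, 76, 2, 0, 72)
        for seed in range(10):
            nxt, out = step(s, Action.STAY, config, np.random.default_rng(seed))
            assert out.event == "hit"
            assert out.score_delta == 1
            assert nxt.ball_dx == -2  # sign flipped, magnitude kept
            assert abs(nxt.ball_dy) in (1, 2, 3)  # vertical direction redrawn

    def test_edge_hit_doubles_speed(self, config):
        # contact at the racket's lower quarter
        s = GameState(config.racket_x - 5, 72 + 13, 2, 0, 72)
        for seed in range(10):
            nxt, out = step(s, Action.STAY, config, np.random.default_rng(seed))
            assert out.event == "hit"
            assert nxt.ball_dx == -4  # doubled incoming horizontal speed
            assert abs(nxt.ball_dy) in (2, 4, 6)  # doubled redrawn vertical

    def test_speed_cap(self, config):
        s = GameState(config.racket_x - 7, 72 + 13, 6, 0, 72)
        nxt, out = step(s, Action.STAY, config, np.random.default_rng(0))
        assert out.event == "hit"
        assert abs(nxt.ball_dx) <= config.speed_cap
        assert abs(nxt.ball_dy) <= config.speed_cap

    def test_miss_reserves_immediately(self, config):
        s = GameState(config.racket_x - 2, 10, 6, 0, 120)  # racket far away
        nxt, out = step(s, Action.STAY, config, np.random.default_rng(0))
        assert out.event == "miss"
        assert out.score_delta == -1
        assert nxt.ball_x == 0 and nxt.ball_y in config.serve_y_choices

    def test_left_wall_redraws_dy(self, config):
        s = GameState(1, 80, -2, 1, 72)
        nxt, _ = step(s, Action.STAY, config, np.random.default_rng(0))
        assert nxt.ball_dx == 2 and nxt.ball_x == 1
        assert abs(nxt.ball_dy) in (1, 2, 3)

    def test_score_accounting_and_ball_containment(self, small_config):
        """Score equals hits - misses; ball never sits past the racket plane."""
        env = GameEnv(small_config, seed=11)
        env.reset()
        rng = np.random.default_rng(2)
        hits = misses = 0
        for _ in range(3000):
            a = [Action.UP, Action.DOWN, Action.STAY][rng.integers(3)]
            s, out = env.step(a)
            hits += out.event == "hit"
            misses += out.event == "miss"
            assert 0 <= s.ball_y <= small_config.court_height - small_config.ball_size
            assert 0 <= s.ball_x <= small_config.court_width - small_config.ball_size
        assert hits + misses > 0
        assert s.score == hits - misses

    def test_replay_determinism(self, config):
        def play(seed):
            env = GameEnv(config, seed=seed)
            env.reset()
            states = []
            rng = np.random.default_rng(0)
            for _ in range(500):
                a = [Action.UP, Action.DOWN, Action.STAY][rng.integers(3)]
                states.append(env.step(a)[0])
            return states

        assert play(42) == play(42)


class TestIntercept:
    def test_horizontal_path(self, config):
        s = GameState(100, 80, 2, 0, 72)
        assert project_ball_intercept(s, config) == 80 + 1.5

    def test_moving_away_absent(self, config):
        s = GameState(100, 80, -2, 1, 72)
        assert project_ball_intercept(s, config) is None

    @pytest.mark.parametrize("scale", [1, 4])
    def test_matches_brute_force(self, scale):
        """Closed-form fold agrees exactly with a rational ray trace."""
        cfg = GameConfig().scaled(scale)
        rng = np.random.default_rng(99)
        n = 2000
        for _ in range(n):
            s = GameState(
                ball_x=int(rng.integers(0, cfg.racket_x - cfg.ball_size)),
                ball_y=int(rng.integers(0, cfg.court_height - cfg.ball_size + 1)),
                ball_dx=int(rng.integers(1, 7)),
                ball_dy=int(rng.integers(-6, 7)),
                racket_y=0)
            m, dx = _intercept_folded(s, cfg)
            assert Fraction(m, dx) + Fraction(cfg.ball_size - 1, 2) == \
                brute_force_intercept(s, cfg)


class TestIntermediateCritic:
    def test_toward_target_rewarded(self, config):
        # intercept at row ~41.5, racket center at 80: UP approaches
        s = GameState(100, 40, 2, 0, 72)
        assert intermediate_critic(s, Action.UP, config) == 0.1
        assert intermediate_critic(s, Action.DOWN, config) == -0.01

    def test_stay_at_target_rewarded(self, config):
        # racket center 79.5 equals the projected intercept row
        s = GameState(100, 78, 2, 0, 72)
        assert project_ball_intercept(s, config) == 79.5
        assert intermediate_critic(s, Action.STAY, config) == 0.1
        assert intermediate_critic(s, Action.UP, config) == -0.01
        assert intermediate_critic(s, Action.DOWN, config) == -0.01

    def test_no_projection_when_moving_away(self, config):
        s = GameState(100, 78, -2, 1, 72)
        assert intermediate_critic(s, Action.UP, config) is None


class TestRender:
    def test_pixel_count_and_placement(self, config):
        s = GameState(0, 40, 1, 1, 72)
        img = render_frame(s, config)
        assert img.shape == (config.court_height, config.court_width)
        assert img.sum() == 16 + 64  # ball 4x4 plus racket 4x16, no overlap
        assert img[40:44, 0:4].all()
        assert img[72:88, 140:144].all()

    def test_render_deterministic(self, config):
        s = GameState(10, 20, 1, 1, 30)
        assert np.array_equal(render_frame(s, config), render_frame(s, config))
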