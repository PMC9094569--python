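"""Racket-ball game environment.

A single-player Pong-like court: a ball bounces around a rectangular court
and a racket on the right side, driven by external motor commands
(UP / DOWN / STAY), tries to hit it.  Coordinates follow the image-frame
convention: origin at the top-left, x grows rightward, y grows downward,
0-based integer pixels.  "UP" therefore *decreases* y.

The module is functional at its core (``reset`` / ``step`` are pure given an
RNG) with a thin gym-style :class:`GameEnv` wrapper on top.  It also provides
the projected-intercept oracle used by the intermediate reward paradigm: a
small reward (+0.1) is delivered whenever an action moves the racket toward
the row where the ball will cross the racket column, and a smaller punishment
(-0.01) when it moves away.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Action",
    "GameConfig",
    "GameState",
    "StepOutcome",
    "GameEnv",
    "reset",
    "step",
    "project_ball_intercept",
    "intermediate_critic",
    "render_frame",
]


class Action(Enum):
    """Motor commands the racket understands."""

    UP = -1
    STAY = 0
    DOWN = 1


_DEFAULT_SERVE_Y = (40, 60, 80, 100, 120)
_DEFAULT_SERVE_V = (
    (1, 1), (1, 2), (1, 3),
    (2, 1), (2, 2), (2, 3),
    (3, 1), (3, 2), (3, 3),
)


@dataclass(frozen=True)
class GameConfig:
    """Court geometry, serve rules and scoring.

    Defaults give the full-size 160x160 court with a 4x4 ball and a 4x16
    racket pinned at column 140.  ``scaled(k)`` derives a smaller court for
    desk-scale experiments.
    """

    court_width: int = 160
    court_height: int = 160
    ball_size: int = 4
    racket_width: int = 4
    racket_height: int = 16
    racket_x: int = 140
    racket_step: int = 4
    serve_y_choices: Tuple[int, ...] = _DEFAULT_SERVE_Y
    serve_velocity_choices: Tuple[Tuple[int, int], ...] = _DEFAULT_SERVE_V
    speed_cap: int = 6
    hit_reward: float = 1.0
    miss_penalty: float = -1.0
    intermediate_reward: float = 0.1
    intermediate_penalty: float = -0.01

    def __post_init__(self) -> None:
        if self.racket_x + self.racket_width > self.court_width:
            raise ValueError("racket must fit inside the court horizontally")
        if self.racket_height > self.court_height:
            raise ValueError("racket taller than the court")
        for y in self.serve_y_choices:
            if not 0 <= y <= self.court_height - self.ball_size:
                raise ValueError(f"serve row {y} outside the court")
        for dx, dy in self.serve_velocity_choices:
            if dx <= 0 or dy <= 0:
                raise ValueError("serve velocity components must be positive")

    def scaled(self, k: int) -> "GameConfig":
        """Court reduced by ``k`` with objects kept resolvable.

        Court dimensions shrink by ``k``; ball and racket shrink by ``k/2``
        so that after the retina's 2x downsampling every object still covers
        at least one input pixel.
        """
        if k <= 1:
            return self
        return GameConfig(
            court_width=self.court_width // k,
            court_height=self.court_height // k,
            ball_size=max(1, self.ball_size * 2 // k),
            racket_width=max(1, self.racket_width * 2 // k),
            racket_height=max(2, self.racket_height * 2 // k),
            racket_x=self.racket_x // k,
            racket_step=self.racket_step,
            serve_y_choices=tuple(y // k for y in self.serve_y_choices),
            serve_velocity_choices=self.serve_velocity_choices,
            speed_cap=self.speed_cap,
        )

    @property
    def racket_center_offset_2x(self) -> int:
        """Racket center offset from its top row, in half-pixel units."""
        return self.racket_height - 1


@dataclass(frozen=True)
class GameState:
    """Snapshot of the court between game-steps."""

    ball_x: int
    ball_y: int
    ball_dx: int
    ball_dy: int
    racket_y: int
    score: float = 0.0
    step_index: int = 0
    last_event: str = "serve"


@dataclass(frozen=True)
class StepOutcome:
    """What a single game-step produced."""

    event: str  # "none" | "hit" | "miss"
    score_delta: float
    intermediate_critic: Optional[float] = None


def _serve(config: GameConfig, rng: np.random.Generator,
           y: Optional[int] = None) -> Tuple[int, int, int, int]:
    """Draw a serve: ball at the left edge, velocity from the serve set.

    The listed serve velocities are positive displacement magnitudes; the
    vertical sign is drawn uniformly so serves go up or down equally often.
    """
    if y is None:
        y = int(config.serve_y_choices[rng.integers(len(config.serve_y_choices))])
    dx, dy = config.serve_velocity_choices[rng.integers(len(config.serve_velocity_choices))]
    sign = 1 if rng.integers(2) == 1 else -1
    return 0, int(y), int(dx), int(dy) * sign


def reset(config: GameConfig, rng, init_ball: Optional[Tuple[int, int]] = None,
          init_racket: Optional[int] = None) -> GameState:
    """Start a new episode; forced initial positions must lie inside the court."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if init_ball is not None:
        bx, by = init_ball
        if not (0 <= bx <= config.court_width - config.ball_size
                and 0 <= by <= config.court_height - config.ball_size):
            raise ValueError(f"initial ball position {init_ball} outside the court")
        _, _, dx, dy = _serve(config, rng)
        ball = (int(bx), int(by), dx, dy)
    else:
        ball = _serve(config, rng)
    if init_racket is None:
        init_racket = (config.court_height - config.racket_height) // 2
    if not 0 <= init_racket <= config.court_height - config.racket_height:
        raise ValueError(f"initial racket row {init_racket} outside the court")
    return GameState(*ball, racket_y=int(init_racket))


def _redraw_dy(rng: np.random.Generator) -> int:
    """New vertical velocity after a bounce: magnitude in {1,2,3}, sign uniform."""
    mag = int(rng.integers(1, 4))
    return mag if rng.integers(2) == 1 else -mag


def _move_racket(racket_y: int, action: Action, config: GameConfig) -> int:
    ry = racket_y + action.value * config.racket_step
    return int(np.clip(ry, 0, config.court_height - config.racket_height))


def step(state: GameState, action: Action, config: GameConfig,
         rng: np.random.Generator) -> Tuple[GameState, StepOutcome]:
    """Advance the game one step.

    The racket moves first (clamped to the court), then the ball advances by
    (dx, dy) using a swept, sub-pixel collision check so that fast balls
    cannot tunnel through the racket.  Top/bottom wall contacts flip the
    vertical direction only; the left wall and the racket redraw the vertical
    velocity; racket-edge contacts additionally double the speed (capped).
    """
    cfg = config
    critic = intermediate_critic(state, action, cfg)
    ry = _move_racket(state.racket_y, action, cfg)
    b = cfg.ball_size
    H = cfg.court_height
    Lb = H - b  # max ball top row
    x0, y0, dx, dy = state.ball_x, state.ball_y, state.ball_dx, state.ball_dy

    def advance_y(y: int, vy: int) -> Tuple[int, int, bool]:
        """One full-step vertical move with top/bottom reflection."""
        yy = y + vy
        bounced = False
        if yy < 0:
            yy, vy, bounced = -yy, -vy, True
        elif yy > Lb:
            yy, vy, bounced = 2 * Lb - yy, -vy, True
        return yy, vy, bounced

    event = "none"
    score_delta = 0.0

    if dx < 0 and x0 + dx < 0:
        # left-wall bounce: flip horizontal direction, redraw vertical velocity
        y1, dy1, _ = advance_y(y0, dy)
        nxt = GameState(-(x0 + dx), y1, abs(dx), _redraw_dy(rng), ry,
                        state.score, state.step_index + 1, "wall_bounce")
        return nxt, StepOutcome("none", 0.0, critic)

    if dx <= 0:
        y1, dy1, bounced = advance_y(y0, dy)
        nxt = GameState(x0 + dx, y1, dx, dy1, ry, state.score,
                        state.step_index + 1, "wall_bounce" if bounced else "none")
        return nxt, StepOutcome("none", 0.0, critic)

    # Ball moving toward the racket: sweep in n sub-steps (integer arithmetic,
    # positions scaled by n so no rounding occurs mid-flight).
    n = max(abs(dx), abs(dy), 1)
    Rx, rw, rh = cfg.racket_x, cfg.racket_width, cfg.racket_height
    xx = x0 * n
    yy = y0 * n
    vy = dy
    bounced = False
    hit = False
    contact_r2 = 0  # ball-center offset from racket top at contact, doubled
    for _ in range(n):
        xx += dx
        yy += vy
        if yy < 0:
            yy, vy, bounced = -yy, -vy, True
        elif yy > Lb * n:
            yy, vy, bounced = 2 * Lb * n - yy, -vy, True
        x_overlap = xx + (b - 1) * n >= Rx * n and xx <= (Rx + rw - 1) * n
        if x_overlap:
            y_overlap = (yy + (b - 1) * n >= ry * n) and (yy <= (ry + rh - 1) * n)
            if y_overlap:
                hit = True
                # 2*(ball_center - racket_top), exact in units of 1/n
                contact_r2 = (2 * yy + (b - 1) * n - 2 * ry * n)
                break
        if xx > (Rx + rw - 1) * n:  # fully past the racket: a miss
            break

    if hit:
        edge = contact_r2 < (rh * n) // 2 or contact_r2 >= (3 * rh * n) // 2
        new_dy = _redraw_dy(rng)
        if edge:
            new_dx = -min(2 * abs(dx), cfg.speed_cap)
            new_dy = int(np.sign(new_dy)) * min(2 * abs(new_dy), cfg.speed_cap)
        else:
            new_dx = -abs(dx)
        y_contact = int(np.clip(round(yy / n), 0, Lb))
        nxt = GameState(Rx - b, y_contact, new_dx, new_dy, ry,
                        state.score + cfg.hit_reward, state.step_index + 1, "hit")
        return nxt, StepOutcome("hit", cfg.hit_reward, critic)

    if xx > (Rx + rw - 1) * n:
        # missed: deduct a point and re-serve immediately
        bx, by, ndx, ndy = _serve(cfg, rng)
        nxt = GameState(bx, by, ndx, ndy, ry,
                        state.score + cfg.miss_penalty, state.step_index + 1, "miss")
        return nxt, StepOutcome("miss", cfg.miss_penalty, critic)

    y1 = int(round(yy / n))
    nxt = GameState(x0 + dx, y1, dx, vy, ry, state.score,
                    state.step_index + 1, "wall_bounce" if bounced else "none")
    return nxt, StepOutcome("none", 0.0, critic)


def _intercept_folded(state: GameState, config: GameConfig) -> Optional[Tuple[int, int]]:
    """Exact intercept of the ball center with the racket column.

    Returns ``(m, dx)`` where the folded linear extrapolation of the ball's
    top row at the crossing time equals ``m / dx``, or None if the ball moves
    away from the racket.  Wall reflections preserve the vertical speed, so
    the no-racket trajectory is a deterministic triangle wave and can be
    folded in closed form with integer arithmetic.
    """
    dx = state.ball_dx
    if dx <= 0:
        return None
    b = config.ball_size
    L = config.court_height - b
    p = config.racket_x - state.ball_x - b + 1  # sub-steps until right edge arrives
    if p <= 0:
        return state.ball_y * dx, dx
    Y = state.ball_y * dx + state.ball_dy * p
    P = 2 * L * dx
    m = Y % P
    if m > L * dx:
        m = P - m
    return m, dx


def project_ball_intercept(state: GameState, config: GameConfig) -> Optional[float]:
    """Row where the ball's center will cross the racket column.

    Assumes wall reflections and no racket; None if the ball is moving away.
    """
    folded = _intercept_folded(state, config)
    if folded is None:
        return None
    m, dx = folded
    return m / dx + (config.ball_size - 1) / 2


def intermediate_critic(prev_state: GameState, action: Action,
                        config: GameConfig) -> Optional[float]:
    """Per-action critic of the intermediate reward paradigm.

    +0.1 when the action moved the racket center toward the projected
    intercept row, or kept it on target (within half a racket step, the
    finest alignment the actuator can achieve); -0.01 otherwise.  None when
    the ball is moving away from the racket (no projection).  A move that
    leaves the distance unchanged while off target — holding still away
    from the ball, or pressing into the court wall — did not contribute to
    reaching the ball and is punished.  Distances are compared in exact
    integer units to avoid tie-breaking on floating-point noise.
    """
    folded = _intercept_folded(prev_state, config)
    if folded is None:
        return None
    m, dx = folded
    b, rh = config.ball_size, config.racket_height
    ic2dx = 2 * m + (b - 1) * dx  # 2*dx*(intercept center row)

    def dist(ry: int) -> int:
        return abs((2 * ry + rh - 1) * dx - ic2dx)

    d_before = dist(prev_state.racket_y)
    d_after = dist(_move_racket(prev_state.racket_y, action, config))
    # d is |racket_center - intercept| in units of 1/(2 dx) pixels
    on_target = d_after <= config.racket_step * dx
    if d_after < d_before or on_target:
        return config.intermediate_reward
    return config.intermediate_penalty


def render_frame(state: GameState, config: GameConfig) -> np.ndarray:
    """Binary frame (uint8, shape ``(court_height, court_width)``, y-major)."""
    frame = np.zeros((config.court_height, config.court_width), dtype=np.uint8)
    b = config.ball_size
    frame[state.ball_y:state.ball_y + b, state.ball_x:state.ball_x + b] = 1
    frame[state.racket_y:state.racket_y + config.racket_height,
          config.racket_x:config.racket_x + config.racket_width] = 1
    return frame


class GameEnv:
    """Gym-style wrapper: owns a config, an RNG and the current state."""

    def __init__(self, config: Optional[GameConfig] = None, seed: int = 0):
        self.config = config or GameConfig()
        self._rng = np.random.default_rng(seed)
        self.state: Optional[GameState] = None

    def reset(self, init_ball: Optional[Tuple[int, int]] = None,
              init_racket: Optional[int] = None) -> GameState:
        self.state = reset(self.config, self._rng, init_ball, init_racket)
        return self.state

    def step(self, action: Action) -> Tuple[GameState, StepOutcome]:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        self.state, outcome = step(self.state, action, self.config, self._rng)
        return self.state, outcome

    def render(self) -> np.ndarray:
        if self.state is None:
            raise RuntimeError("call reset() before render()")
        return render_frame(self.state, self.config)
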