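"""Closed-loop training: sense -> spike -> decide -> act -> reward.

Each game-step the current frame is rendered, encoded into retinal spike
trains, the network is advanced one action interval, the motor populations
are read out winner-take-all, the game advances, and the resulting critics
(intermediate per-action rewards and/or sparse hit/miss rewards) modulate
the tagged plastic synapses.  Training runs in episodes; every episode
resets the game and all dynamic network state but keeps the learned weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decoder import decode_action
from .engine import EventEngine
from .game import Action, GameConfig, GameEnv
from .network import (Network, NetworkSpec, NoiseSpec, PopulationSpec,
                      ProjectionSpec, build_network, feedforward_spec,
                      recurrent_spec)
from .plasticity import CriticEvent, PlasticityConfig, PlasticityState
from .retina import (DIRECTIONS, EncodingConfig, generate_input_spikes,
                     motion_direction_field, preprocess_frame, _poisson_times)

__all__ = ["RunConfig", "EpisodeLog", "run_episode", "run_training",
           "evaluate_checkpoint", "save_checkpoint", "load_checkpoint",
           "TrainingResult", "hit_miss_ratio"]

PARADIGMS = ("intermediate", "sparse", "both")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a training or evaluation run."""

    architecture: str = "feedforward"
    scale: int = 1                     # court and network reduction factor
    episode_duration: float = 500.0    # seconds
    n_episodes: int = 20
    reward_paradigm: str = "both"
    plasticity: PlasticityConfig = dc_field(default_factory=PlasticityConfig)
    master_seed: int = 0
    record_spikes: bool = True

    def __post_init__(self) -> None:
        if self.reward_paradigm not in PARADIGMS:
            raise ValueError(f"unknown reward paradigm {self.reward_paradigm!r}")
        if self.architecture not in ("feedforward", "recurrent"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.episode_duration <= 0:
            raise ValueError("episode duration must be positive")

    # -- derived configurations ----------------------------------------------

    def game_config(self) -> GameConfig:
        return GameConfig().scaled(self.scale)

    def encoding_config(self) -> EncodingConfig:
        g = self.game_config()
        if self.architecture == "feedforward":
            rate, step = 20.0, 20.0
        else:
            rate, step = 35.0, 50.0
        return EncodingConfig(input_width=g.court_width // 2,
                              input_height=g.court_height // 2,
                              location_rate=rate, game_step=step)

    def network_spec(self) -> NetworkSpec:
        enc = self.encoding_config()
        shape = (enc.input_height, enc.input_width)
        if self.architecture == "feedforward":
            return feedforward_spec(input_shape=shape, scale=self.scale)
        return recurrent_spec(input_shape=shape, scale=self.scale)

    @property
    def steps_per_episode(self) -> int:
        return int(round(self.episode_duration * 1000.0
                         / self.encoding_config().game_step))


@dataclass
class EpisodeLog:
    """Time-stamped record of one episode.

    Per game-step arrays hold the state *before* the step (the state the
    frame was rendered from), the decoded action, the motor spike counts,
    the resulting event and the intermediate critic value (NaN when the
    ball was moving away).  The spike raster covers all populations.
    """

    game_config: GameConfig
    game_step_ms: float
    ball_x: np.ndarray = None
    ball_y: np.ndarray = None
    ball_dx: np.ndarray = None
    ball_dy: np.ndarray = None
    racket_y: np.ndarray = None
    action: np.ndarray = None          # -1 UP, 0 STAY, +1 DOWN (Action.value)
    count_up: np.ndarray = None
    count_down: np.ndarray = None
    event: np.ndarray = None           # "none" | "hit" | "miss"
    critic: np.ndarray = None
    spikes_t: np.ndarray = None
    spikes_i: np.ndarray = None
    pop_slices: Dict[str, Tuple[int, int]] = dc_field(default_factory=dict)
    hits: int = 0
    misses: int = 0
    score: float = 0.0
    mean_weights: Dict[str, float] = dc_field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.action)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ball_x": self.ball_x, "ball_y": self.ball_y,
            "ball_dx": self.ball_dx, "ball_dy": self.ball_dy,
            "racket_y": self.racket_y, "action": self.action,
            "count_up": self.count_up, "count_down": self.count_down,
            "event": self.event, "critic": self.critic,
        })

    def raster_frame(self) -> pd.DataFrame:
        pop = np.empty(len(self.spikes_i), dtype=object)
        for name, (a, b) in self.pop_slices.items():
            mask = (self.spikes_i >= a) & (self.spikes_i < b)
            pop[mask] = name
        return pd.DataFrame({"neuron": self.spikes_i, "population": pop,
                             "time_ms": self.spikes_t})


def hit_miss_ratio(hits: int, misses: int) -> float:
    """Cumulative hits over misses; +inf flags a spotless record."""
    if misses == 0:
        return float("inf") if hits > 0 else float("nan")
    return hits / misses


def _episode_rngs(master_seed: int, episode: int):
    """Independent deterministic streams for game, retina and noise."""
    mk = lambda tag: np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(1, episode, tag)))
    return mk(0), mk(1), mk(2)


def run_episode(net: Network, engine: EventEngine, env: GameEnv,
                config: RunConfig, episode: int = 0, train: bool = True,
                plast: Optional[PlasticityState] = None,
                init_ball: Optional[Tuple[int, int]] = None,
                init_racket: Optional[int] = None) -> EpisodeLog:
    """Simulate one episode; weights mutate only when ``train`` is True."""
    enc = config.encoding_config()
    if abs(engine.stdp_window - config.plasticity.stdp_window) > 1e-12:
        raise ValueError("engine STDP window inconsistent with run config")
    game_rng, retina_rng, noise_rng = _episode_rngs(config.master_seed, episode)
    env._rng = game_rng
    state = env.reset(init_ball=init_ball, init_racket=init_racket)
    engine.reset_state(0.0)
    if plast is None:
        plast = PlasticityState(net, engine, config.plasticity)
    checksum = net.weights_checksum() if not train else None

    up_sl = net.pop_slices["EMUP"]
    down_sl = net.pop_slices["EMDOWN"]
    dir_drives = {d: net.drives[f"retina_dir:{d}"]["syn"]
                  for d in DIRECTIONS if f"retina_dir:{d}" in net.drives}
    loc_drive = net.drives["retina_loc"]["syn"]
    noise_drives = [(v["syn"], v["rate_hz"]) for k, v in net.drives.items()
                    if k.startswith("noise:") and v["rate_hz"] > 0]

    intermediate_on = config.reward_paradigm in ("intermediate", "both")
    sparse_on = config.reward_paradigm in ("sparse", "both")

    n_steps = config.steps_per_episode
    cols = {k: [] for k in ("ball_x", "ball_y", "ball_dx", "ball_dy",
                            "racket_y", "action", "count_up", "count_down",
                            "event", "critic")}
    all_sp_t: List[np.ndarray] = []
    all_sp_i: List[np.ndarray] = []
    hits = misses = 0
    prev_proc = preprocess_frame(env.render())

    for step_i in range(n_steps):
        t0 = step_i * enc.game_step
        t1 = t0 + enc.game_step
        frame = preprocess_frame(env.render())
        field = motion_direction_field(frame, prev_proc, enc)
        prev_proc = frame
        loc_idx, loc_t, dir_events = generate_input_spikes(
            frame, field, enc, retina_rng, t0)
        if len(loc_idx):
            engine.schedule_external(loc_drive[loc_idx], loc_t)
        for d, (idx, times) in dir_events.items():
            if d in dir_drives:
                engine.schedule_external(dir_drives[d][idx], times)
        for syn, rate in noise_drives:
            u, t = _poisson_times(rate, t0, enc.game_step, len(syn), noise_rng)
            if len(u):
                engine.schedule_external(syn[u], t)

        sp_t, sp_i = engine.run_until(t1)
        if config.record_spikes and len(sp_t):
            all_sp_t.append(sp_t)
            all_sp_i.append(sp_i)
        n_up = int(np.count_nonzero((sp_i >= up_sl.start) & (sp_i < up_sl.stop)))
        n_down = int(np.count_nonzero((sp_i >= down_sl.start) & (sp_i < down_sl.stop)))
        action = decode_action(n_up, n_down)

        cols["ball_x"].append(state.ball_x)
        cols["ball_y"].append(state.ball_y)
        cols["ball_dx"].append(state.ball_dx)
        cols["ball_dy"].append(state.ball_dy)
        cols["racket_y"].append(state.racket_y)
        cols["action"].append(action.value)
        cols["count_up"].append(n_up)
        cols["count_down"].append(n_down)

        state, outcome = env.step(action)
        cols["event"].append(outcome.event)
        cols["critic"].append(np.nan if outcome.intermediate_critic is None
                              else outcome.intermediate_critic)
        if outcome.event == "hit":
            hits += 1
        elif outcome.event == "miss":
            misses += 1

        if train:
            if intermediate_on and outcome.intermediate_critic is not None:
                plast.apply_critic(CriticEvent(outcome.intermediate_critic,
                                               t1, action))
            if sparse_on and outcome.event in ("hit", "miss"):
                plast.apply_critic(CriticEvent(outcome.score_delta, t1, action))

    if not train and net.weights_checksum() != checksum:
        raise RuntimeError("evaluation mutated weights")  # pragma: no cover

    log = EpisodeLog(
        game_config=env.config, game_step_ms=enc.game_step,
        pop_slices={k: (v.start, v.stop) for k, v in net.pop_slices.items()},
        hits=hits, misses=misses, score=state.score,
        mean_weights=plast.mean_weights(),
    )
    for k, v in cols.items():
        setattr(log, k, np.asarray(v))
    log.spikes_t = (np.concatenate(all_sp_t) if all_sp_t else np.empty(0))
    log.spikes_i = (np.concatenate(all_sp_i) if all_sp_i
                    else np.empty(0, dtype=np.int64))
    return log


@dataclass
class TrainingResult:
    net: Network
    logs: List[EpisodeLog]
    weight_snapshots: List[np.ndarray]   # s_w after each episode

    def summary(self) -> pd.DataFrame:
        rows = [{"episode": i, "hits": lg.hits, "misses": lg.misses,
                 "hit_miss_ratio": hit_miss_ratio(lg.hits, lg.misses)}
                for i, lg in enumerate(self.logs)]
        return pd.DataFrame(rows)


def run_training(config: RunConfig,
                 net: Optional[Network] = None) -> TrainingResult:
    """Sequential training episodes; each resumes from the previous weights."""
    if net is None:
        net = build_network(config.network_spec(),
                            np.random.SeedSequence(entropy=config.master_seed,
                                                   spawn_key=(0,)))
    if net.spec.architecture != config.architecture:
        raise ValueError(
            f"checkpoint architecture {net.spec.architecture!r} does not "
            f"match run config {config.architecture!r}")
    engine = EventEngine(net, stdp_window=config.plasticity.stdp_window)
    plast = PlasticityState(net, engine, config.plasticity)
    env = GameEnv(config.game_config())
    logs, snaps = [], []
    for ep in range(config.n_episodes):
        logs.append(run_episode(net, engine, env, config, episode=ep,
                                train=True, plast=plast))
        snaps.append(net.s_w.copy())
    return TrainingResult(net, logs, snaps)


def evaluate_checkpoint(net: Network, config: RunConfig, n_repeats: int = 6,
                        init_positions: Optional[Sequence[Tuple[int, int]]] = None,
                        episode_offset: int = 10_000) -> pd.DataFrame:
    """Frozen-weight evaluation over repeats with distinct initial positions.

    Returns one row per repeat (hits, misses, hit/miss ratio) plus the mean
    ratio in ``DataFrame.attrs['mean_ratio']``.  Weights are guaranteed
    untouched (checksum-verified inside :func:`run_episode`).
    """
    if n_repeats < 1:
        raise ValueError("need at least one evaluation repeat")
    g = config.game_config()
    if init_positions is None:
        ys = list(g.serve_y_choices)
        rows = np.linspace(0, g.court_height - g.racket_height, n_repeats)
        init_positions = [(ys[i % len(ys)], int(round(rows[i])))
                          for i in range(n_repeats)]
    engine = EventEngine(net, stdp_window=config.plasticity.stdp_window)
    env = GameEnv(g)
    records = []
    for i, (ball_y, racket_y) in enumerate(init_positions[:n_repeats]):
        log = run_episode(net, engine, env, config,
                          episode=episode_offset + i, train=False,
                          init_ball=(0, ball_y), init_racket=racket_y)
        records.append({"repeat": i, "init_ball_y": ball_y,
                        "init_racket_y": racket_y, "hits": log.hits,
                        "misses": log.misses,
                        "hit_miss_ratio": hit_miss_ratio(log.hits, log.misses)})
    df = pd.DataFrame(records)
    finite = df["hit_miss_ratio"].replace([np.inf], np.nan)
    df.attrs["mean_ratio"] = float(df["hit_miss_ratio"].mean())
    df.attrs["mean_ratio_finite"] = float(finite.mean())
    return df


#: Learning parameters of the desk-scale study (see docs/methods.md):
#: moderate learning rate with a tight weight corridor so that plastic
#: weights stay out of the depolarization-blockade regime over a short
#: training budget, and a small opposite-population fraction to keep the
#: winner-take-all competition balanced.
DESK_PLASTICITY = PlasticityConfig(
    mode="targeted", learning_rate=0.15, w_max_mult=2.0,
    opposite_fraction=0.1, w_min_mult=0.25, punishment_gain=0.25)


def desk_scale_study(seed: int, n_episodes: int = 10,
                     episode_duration: float = 60.0,
                     eval_duration: float = 20.0,
                     n_repeats: int = 6,
                     plasticity: Optional[PlasticityConfig] = None) -> Dict:
    """End-to-end scaled-down learning experiment for one seed.

    A 4x-reduced feedforward model on a 40x40 court is evaluated with
    frozen weights, trained with the combined intermediate + sparse reward
    stream under targeted RL, and evaluated again on the *same* frozen
    serve sequences and initial positions (a paired comparison, so the
    before/after difference reflects only the learned weights).
    """
    plasticity = plasticity or DESK_PLASTICITY
    train_cfg = RunConfig(architecture="feedforward", scale=4,
                          episode_duration=episode_duration,
                          n_episodes=n_episodes, reward_paradigm="both",
                          plasticity=plasticity, master_seed=seed,
                          record_spikes=False)
    eval_cfg = replace(train_cfg, episode_duration=eval_duration, n_episodes=0)
    net = build_network(train_cfg.network_spec(),
                        np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    pre = evaluate_checkpoint(net, eval_cfg, n_repeats=n_repeats)
    result = run_training(train_cfg, net=net)
    post = evaluate_checkpoint(net, eval_cfg, n_repeats=n_repeats)
    # performance = mean of per-repeat cumulative hit/miss ratios
    pre_ratio = float(pre["hit_miss_ratio"].mean())
    post_ratio = float(post["hit_miss_ratio"].mean())
    return {
        "seed": seed,
        "pre": pre, "post": post,
        "pre_ratio": pre_ratio, "post_ratio": post_ratio,
        "improved": post_ratio > pre_ratio,
        "training": result.summary(),
    }


# -- checkpointing -------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def _h5_group(parent, name: str):
    """Create a subgroup without object-header timestamps.

    Keeps checkpoint files byte-reproducible: identical content always
    serializes to identical bytes.
    """
    import h5py
    from h5py import h5g, h5p

    gcpl = h5p.create(h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    return h5py.Group(h5g.create(parent.id, name.encode(), gcpl=gcpl))


def save_checkpoint(net: Network, path) -> None:
    """Portable HDF5 checkpoint: wiring, delays, weights, blueprint."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = _CHECKPOINT_VERSION
        f.attrs["architecture"] = net.spec.architecture
        f.attrs["seed_entropy"] = str(net.seed_entropy)
        f.attrs["blueprint_hash"] = net.blueprint_hash()
        f.attrs["spec_json"] = json.dumps(asdict(net.spec))
        g = _h5_group(f, "synapses")
        for name in ("s_pre", "s_post", "s_kind", "s_w", "s_w_init",
                     "s_delay", "s_plastic"):
            g.create_dataset(name, data=getattr(net, name), track_times=False)
        pj = _h5_group(f, "projections")
        for name in sorted(net.projection_slices):
            sl = net.projection_slices[name]
            pj.attrs[name] = (sl.start, sl.stop)
        dr = _h5_group(f, "drives")
        for name in sorted(net.drives):
            d = net.drives[name]
            sub = _h5_group(dr, name)
            sub.attrs["pop"] = d["pop"]
            sub.attrs["rate_hz"] = d["rate_hz"]
            sub.create_dataset("syn", data=d["syn"], track_times=False)


def _spec_from_json(payload: dict) -> NetworkSpec:
    pops = tuple(PopulationSpec(**p) for p in payload.pop("populations"))
    projs = tuple(ProjectionSpec(**p) for p in payload.pop("projections"))
    noise = tuple(NoiseSpec(**n) for n in payload.pop("noise"))
    for key in ("input_shape", "dir_grid"):
        if payload.get(key) is not None:
            payload[key] = tuple(payload[key])
    return NetworkSpec(populations=pops, projections=projs, noise=noise,
                       **payload)


def load_checkpoint(path, expect_architecture: Optional[str] = None) -> Network:
    """Rebuild a network exactly from a checkpoint file."""
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        arch = f.attrs["architecture"]
        if expect_architecture is not None and arch != expect_architecture:
            raise ValueError(
                f"checkpoint holds a {arch!r} network, expected "
                f"{expect_architecture!r}")
        spec = _spec_from_json(json.loads(f.attrs["spec_json"]))
        net = Network(spec, int(f.attrs["seed_entropy"]))
        g = f["synapses"]
        for name in ("s_pre", "s_post", "s_kind", "s_w", "s_w_init",
                     "s_delay", "s_plastic"):
            setattr(net, name, g[name][...])
        net.s_plastic = net.s_plastic.astype(bool)
        net.projection_slices = {
            name: slice(int(a), int(b))
            for name, (a, b) in f["projections"].attrs.items()}
        for name, sub in f["drives"].items():
            net.drives[name] = {"pop": sub.attrs["pop"],
                                "rate_hz": float(sub.attrs["rate_hz"]),
                                "syn": sub["syn"][...]}
        net._build_csr()
        stored_hash = f.attrs["blueprint_hash"]
    if net.blueprint_hash() != stored_hash:
        raise ValueError(f"checkpoint {path} is corrupt (blueprint hash mismatch)")
    return net
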