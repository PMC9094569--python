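"""Minimal targeted-RL circuit: a two-armed bandit played with spikes.

One input neuron projects through plastic AMPA synapses onto two motor
neurons (UP and DOWN).  Every decision window the motor spike counts are
compared winner-take-all; choosing the fixed correct action earns a small
reward (+0.1) delivered targeted (potentiate the chosen population, depress
the other), choosing the wrong action earns a small punishment (-0.01), and
STAY earns nothing.  Independent background noise onto the motor neurons
provides the coincidences that bootstrap exploration.

This is the smallest circuit in which the reward-modulated STDP rule can be
watched converging: the correct synapse should potentiate until the input
alone drives its motor neuron, while the opposite synapse depresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List

import numpy as np

from .decoder import decode_action
from .engine import EventEngine
from .game import Action
from .network import NetworkSpec, NoiseSpec, PopulationSpec, ProjectionSpec, \
    build_network
from .plasticity import CriticEvent, PlasticityConfig, PlasticityState
from .retina import _poisson_times

__all__ = ["BanditConfig", "run_bandit"]


@dataclass(frozen=True)
class BanditConfig:
    n_decisions: int = 500
    decision_interval: float = 100.0    # ms
    input_rate_hz: float = 50.0
    input_drive_weight: float = 40.0    # drive -> input neuron (fires ~1:1)
    initial_weight: float = 10.0        # plastic input -> motor weight
    noise_rate_hz: float = 30.0
    noise_weight: float = 18.0          # subthreshold alone; fires on coincidence
    correct_action: Action = Action.UP
    reward: float = 0.1
    punishment: float = -0.01
    plasticity: PlasticityConfig = dc_field(
        default_factory=lambda: PlasticityConfig(
            mode="targeted", tau_eligibility=50.0, learning_rate=5.0))


def _bandit_spec(cfg: BanditConfig) -> NetworkSpec:
    pops = (
        PopulationSpec("IN", 1, "E"),
        PopulationSpec("EMUP", 1, "E"),
        PopulationSpec("EMDOWN", 1, "E"),
    )
    projections = (
        ProjectionSpec("IN", "EMUP", "AM2", 1, cfg.initial_weight, plastic=True),
        ProjectionSpec("IN", "EMDOWN", "AM2", 1, cfg.initial_weight, plastic=True),
    )
    noise = (
        NoiseSpec("IN", cfg.input_rate_hz, cfg.input_drive_weight),
        NoiseSpec("EMUP", cfg.noise_rate_hz, cfg.noise_weight),
        NoiseSpec("EMDOWN", cfg.noise_rate_hz, cfg.noise_weight),
    )
    return NetworkSpec(architecture="bandit", populations=pops,
                       projections=projections, noise=noise)


def run_bandit(seed: int, cfg: BanditConfig | None = None) -> Dict:
    """Play the bandit for ``cfg.n_decisions`` windows; returns the history.

    The result dict carries per-decision actions, the per-decision trailing
    correct-action frequency (window of 100), the final plastic weights and
    whether the trailing frequency exceeded 0.75 at any point.
    """
    cfg = cfg or BanditConfig()
    net = build_network(_bandit_spec(cfg),
                        np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    engine = EventEngine(net, stdp_window=cfg.plasticity.stdp_window)
    plast = PlasticityState(net, engine, cfg.plasticity)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    drives = [(v["syn"], v["rate_hz"]) for v in net.drives.values()]
    up_sl, down_sl = net.pop_slices["EMUP"], net.pop_slices["EMDOWN"]

    actions: List[Action] = []
    trailing: List[float] = []
    window = 100
    reached = False
    for i in range(cfg.n_decisions):
        t0 = i * cfg.decision_interval
        t1 = t0 + cfg.decision_interval
        for syn, rate in drives:
            u, t = _poisson_times(rate, t0, cfg.decision_interval, len(syn), rng)
            if len(u):
                engine.schedule_external(syn[u], t)
        sp_t, sp_i = engine.run_until(t1)
        n_up = int(np.count_nonzero((sp_i >= up_sl.start) & (sp_i < up_sl.stop)))
        n_down = int(np.count_nonzero((sp_i >= down_sl.start)
                                      & (sp_i < down_sl.stop)))
        action = decode_action(n_up, n_down)
        actions.append(action)
        if action == cfg.correct_action:
            plast.apply_critic(CriticEvent(cfg.reward, t1, action))
        elif action != Action.STAY:
            plast.apply_critic(CriticEvent(cfg.punishment, t1, action))
        recent = actions[-window:]
        frac = sum(a == cfg.correct_action for a in recent) / len(recent)
        trailing.append(frac)
        if len(recent) >= window and frac > 0.75:
            reached = True

    w = {name: float(net.s_w[sl].mean())
         for name, sl in net.projection_slices.items()
         if net.s_plastic[sl].any()}
    return {
        "actions": actions,
        "trailing_correct": np.array(trailing),
        "final_correct_fraction": trailing[-1],
        "reached_criterion": reached,
        "weights": w,
    }
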