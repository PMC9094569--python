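"""Reward-modulated STDP with eligibility traces.

A causal pre->post spike pair within the STDP window tags the synapse with
an eligibility trace that decays exponentially (tag times are maintained by
the event engine).  When a critic — a scalar reward or punishment — arrives,
every eligible plastic synapse changes weight proportionally to its trace:

    dW = learning_rate * gain(critic) * critic_value * trace * mode_scale

with ``gain`` asymmetric (punishments scaled down relative to rewards) and
``mode_scale`` selecting the credit-assignment variant:

* ``non_targeted`` — every plastic synapse receives the critic equally;
* ``targeted`` — synapses onto the motor population that generated the
  action receive the full critic, synapses onto the opposite motor
  population receive the critic with opposite sign and reduced magnitude,
  and other plastic synapses receive nothing (STAY generates no critic);
* ``retrograde_targeted`` — as targeted, but plastic synapses k excitatory
  hops upstream of the motor layer also receive the critic scaled by
  ``retrograde_decay_per_hop ** k``.

Weights are clipped to [0, w_max] with w_max a multiple of each synapse's
initial weight.  Traces persist after a critic (they keep decaying and can
be consumed by several critics) and re-tagging replaces the tag time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from .game import Action
from .network import Network, motor_hops

__all__ = ["PlasticityConfig", "CriticEvent", "PlasticityState",
           "tag_eligibility", "eligibility_value_at"]

MODES = ("non_targeted", "targeted", "retrograde_targeted")


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning-rule parameters.

    ``tau_eligibility`` is 50 ms for intermediate-reward training (each
    critic refers to the immediately preceding action) and 10 s for
    sparse-reward training (the critic must reach back across a whole ball
    trajectory).
    """

    mode: str = "targeted"
    stdp_window: float = 10.0          # ms
    tau_eligibility: float = 50.0      # ms
    learning_rate: float = 1.0
    reward_gain: float = 1.0
    punishment_gain: float = 0.5
    opposite_fraction: float = 0.5
    retrograde_decay_per_hop: float = 0.5
    w_max_mult: float = 4.0
    w_min_mult: float = 0.0   # optional weight floor (fraction of initial)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown plasticity mode {self.mode!r}")
        if not self.punishment_gain < self.reward_gain:
            raise ValueError("punishment gain must be smaller than reward gain")
        if self.tau_eligibility <= 0 or self.stdp_window <= 0:
            raise ValueError("time constants must be positive")
        if not 0 <= self.opposite_fraction <= 1:
            raise ValueError("opposite_fraction must lie in [0, 1]")
        if not 0 < self.retrograde_decay_per_hop <= 1:
            raise ValueError("retrograde_decay_per_hop must lie in (0, 1]")

    def for_sparse(self) -> "PlasticityConfig":
        return replace(self, tau_eligibility=10_000.0)


@dataclass(frozen=True)
class CriticEvent:
    """Scalar reward (+) or punishment (-) delivered at a point in time."""

    value: float
    time: float
    action: Action = Action.STAY


def tag_eligibility(tag_time: Optional[float], pre_spike_t: float,
                    post_spike_t: float, stdp_window: float) -> Optional[float]:
    """Replace-semantics tagging rule (scalar reference form).

    Returns the new tag time: the post-spike time if the pair is causal and
    within the window, otherwise the existing tag unchanged.
    """
    if 0.0 < post_spike_t - pre_spike_t <= stdp_window:
        return post_spike_t
    return tag_time


def eligibility_value_at(tag_time: Optional[float], t: float,
                         tau_eligibility: float) -> float:
    """Trace value at time ``t``; 0 for a never-tagged synapse."""
    if tag_time is None:
        return 0.0
    if t < tag_time:
        raise ValueError("cannot evaluate a trace before its tag time")
    return float(np.exp(-(t - tag_time) / tau_eligibility))


class PlasticityState:
    """Binds a learning rule to a built network and an engine.

    Precomputes, for every plastic synapse, which motor subpopulation it
    targets and how many excitatory hops upstream of the motor layer it
    sits, so that critics apply as a few vectorized operations.
    """

    def __init__(self, net: Network, engine, config: PlasticityConfig):
        self.net = net
        self.engine = engine
        self.config = config
        self.idx = np.flatnonzero(net.s_plastic)
        self.w_max = config.w_max_mult * net.s_w_init[self.idx]
        self.w_min = config.w_min_mult * net.s_w_init[self.idx]
        # motor-subpopulation membership of each plastic synapse's target
        group = np.zeros(len(self.idx), dtype=np.int64)
        for name, g in (("EMUP", 1), ("EMDOWN", -1)):
            if name in net.pop_slices:
                sl = net.pop_slices[name]
                posts = net.s_post[self.idx]
                group[(posts >= sl.start) & (posts < sl.stop)] = g
        self.group = group
        hops = motor_hops(net.spec)
        hop_arr = np.zeros(len(self.idx), dtype=np.int64)
        for name, sl in net.pop_slices.items():
            posts = net.s_post[self.idx]
            mask = (posts >= sl.start) & (posts < sl.stop)
            hop_arr[mask] = hops.get(name, 1 << 20)
        self.hop = hop_arr

    def _mode_scale(self, action: Action) -> Optional[np.ndarray]:
        cfg = self.config
        if cfg.mode == "non_targeted":
            return np.ones(len(self.idx))
        if action == Action.STAY:
            return None  # no population generated the action
        act_group = 1 if action == Action.UP else -1
        scale = np.zeros(len(self.idx))
        scale[self.group == act_group] = 1.0
        scale[self.group == -act_group] = -cfg.opposite_fraction
        if cfg.mode == "retrograde_targeted":
            upstream = self.group == 0
            scale[upstream] = cfg.retrograde_decay_per_hop ** self.hop[upstream]
        return scale

    def apply_critic(self, critic: CriticEvent) -> np.ndarray:
        """Apply one critic; returns the weight deltas over plastic synapses."""
        cfg = self.config
        zeros = np.zeros(len(self.idx))
        if critic.value == 0.0:
            return zeros
        scale = self._mode_scale(critic.action)
        if scale is None:
            return zeros
        trace = self.engine.eligibility(critic.time, cfg.tau_eligibility,
                                        idx=self.idx)
        gain = cfg.reward_gain if critic.value > 0 else cfg.punishment_gain
        dw = cfg.learning_rate * gain * critic.value * trace * scale
        w = self.net.s_w[self.idx]
        new_w = np.clip(w + dw, self.w_min, self.w_max)
        self.net.s_w[self.idx] = new_w
        return new_w - w

    def mean_weights(self) -> Dict[str, float]:
        """Mean weight per plastic projection (episode-log bookkeeping)."""
        out = {}
        for name in self.net.projection_slices:
            sl = self.net.projection_slices[name]
            if len(self.net.s_w[sl]) and self.net.s_plastic[sl].all():
                out[name] = float(self.net.s_w[sl].mean())
        return out
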