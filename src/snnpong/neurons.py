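"""Event-driven point-neuron model for E, I and IL cells.

Neurons are rule-based dynamical units: between events every state variable
decays along its closed-form exponential, so the state only needs updating
lazily when an event (synaptic delivery) arrives.  The membrane voltage is
composed from the per-synapse-type voltages, the after-hyperpolarization
variable and the resting potential:

    V_m = V_rest + V_AM2 + V_NM2 - V_GA - V_GA2 - V_AHP

A cell fires when an event pushes V_m across the (dynamic) threshold, unless
it sits in its absolute refractory period or V_m exceeds the depolarization
blockade voltage V_block (spike failure at extreme depolarization).  A spike
increments V_AHP (subtracted from V_m), raises the threshold toward V_block
by the relative-refractory weight, and starts the absolute refractory clock.

This module is the scalar reference semantics; :mod:`snnpong.engine`
implements the same rules vectorized over whole networks and is tested for
agreement against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from math import exp
from typing import Dict, Tuple

from .synapses import SYNAPSE_KINDS, SynapseParams, psp_increment

__all__ = ["CellParams", "CellState", "CELL_TYPES",
           "membrane_state_at", "integrate_event", "register_spike"]


@dataclass(frozen=True)
class CellParams:
    """Membrane parameters of one cell class (all voltages absolute mV)."""

    v_rest: float
    v_thresh: float
    v_block: float
    tau_ar: float    # absolute refractory period, ms
    w_rr: float      # relative refractory weight, unitless in [0, 1]
    tau_rr: float    # relative refractory decay, ms
    dv_ahp: float    # AHP increment per spike, mV
    tau_ahp: float   # AHP decay, ms

    def __post_init__(self) -> None:
        if not self.v_rest < self.v_thresh < self.v_block:
            raise ValueError("require v_rest < v_thresh < v_block")
        if min(self.tau_ar, self.tau_rr, self.tau_ahp) <= 0:
            raise ValueError("time constants must be positive")
        if not 0 <= self.w_rr <= 1:
            raise ValueError("w_rr must lie in [0, 1]")


#: Excitatory, fast-spiking inhibitory and low-threshold inhibitory classes.
CELL_TYPES: Dict[str, CellParams] = {
    "E": CellParams(-65.0, -40.0, -25.0, 5.0, 0.75, 8.0, 1.0, 400.0),
    "I": CellParams(-63.0, -40.0, -10.0, 2.5, 0.25, 1.5, 0.5, 50.0),
    "IL": CellParams(-65.0, -47.0, -10.0, 2.5, 0.25, 1.5, 0.5, 50.0),
}


@dataclass
class CellState:
    """Mutable per-neuron state; decaying variables are stored at ``last_update``."""

    v_syn: Dict[str, float] = dc_field(
        default_factory=lambda: {k: 0.0 for k in SYNAPSE_KINDS})
    v_ahp: float = 0.0
    dthresh: float = 0.0          # dynamic threshold excess over v_thresh
    refractory_until: float = -1e18
    last_update: float = 0.0


def _vm(state: CellState, params: CellParams) -> float:
    vs = state.v_syn
    return (params.v_rest + vs["AM2"] + vs["NM2"] - vs["GA"] - vs["GA2"]
            - state.v_ahp)


def membrane_state_at(state: CellState, params: CellParams,
                      t: float) -> Tuple[float, float, float]:
    """Instantaneous ``(v_m, v_ahp, thresh_dyn)`` at time ``t`` (no mutation)."""
    dt = t - state.last_update
    if dt < 0:
        raise ValueError("time must not run backward")
    v_ahp = state.v_ahp * exp(-dt / params.tau_ahp)
    thresh = params.v_thresh + state.dthresh * exp(-dt / params.tau_rr)
    vm = params.v_rest - v_ahp
    for kind in SYNAPSE_KINDS:
        p = SynapseParams.of(kind)
        contrib = state.v_syn[kind] * exp(-dt / p.tau_syn)
        vm += p.sign * contrib
    return vm, v_ahp, thresh


def _advance(state: CellState, params: CellParams, t: float) -> None:
    dt = t - state.last_update
    if dt < 0:
        raise ValueError("time must not run backward")
    if dt == 0:
        return
    for kind in SYNAPSE_KINDS:
        state.v_syn[kind] *= exp(-dt / SynapseParams.of(kind).tau_syn)
    state.v_ahp *= exp(-dt / params.tau_ahp)
    state.dthresh *= exp(-dt / params.tau_rr)
    state.last_update = t


def integrate_event(state: CellState, params: CellParams, kind: str,
                    w_syn: float, t: float) -> bool:
    """Deliver a synaptic event of ``kind`` with weight ``w_syn`` at time ``t``.

    Returns True iff the event makes the cell fire (threshold crossed, not
    refractory, not in depolarization blockade).  On a spike the post-spike
    bookkeeping of :func:`register_spike` is applied.
    """
    _advance(state, params, t)
    v_dev = _vm(state, params) - params.v_rest
    p = SynapseParams.of(kind)
    state.v_syn[kind] += psp_increment(w_syn, v_dev, p.e_syn)
    vm = _vm(state, params)
    spiked = (vm >= params.v_thresh + state.dthresh
              and vm <= params.v_block
              and t >= state.refractory_until)
    if spiked:
        register_spike(state, params, t)
    return spiked


def register_spike(state: CellState, params: CellParams, t: float) -> None:
    """Post-spike update: AHP increment, refractory clock, threshold bump."""
    _advance(state, params, t)
    state.v_ahp += params.dv_ahp
    state.refractory_until = t + params.tau_ar
    state.dthresh = params.w_rr * (params.v_block - params.v_thresh)
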