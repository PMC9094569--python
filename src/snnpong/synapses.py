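"""Synapse types and the stepwise driving-force update rule.

Four synapse kinds are modeled: AM2 (AMPA), NM2 (NMDA), GA (somatic GABAA)
and GA2 (dendritic GABAA).  A presynaptic spike arriving with weight W makes
a stepwise change to the matching synaptic voltage,

    dV = W * (1 - V_dev / E_syn)

where ``V_dev`` is the membrane deviation from rest and ``E_syn`` the
reversal potential relative to rest.  Between events each synaptic voltage
decays exponentially toward 0 with its own time constant.  GABAA voltages
accumulate through the same formula but are *subtracted* from the membrane
voltage, which reproduces a zero increment exactly at the -15 mV reversal
and hyperpolarization at rest.

Delays are drawn once at wiring time and fixed: dendritic synapses
(AM2/NM2/GA2) uniform 3-5 ms, somatic synapses (GA) uniform 1.8-2.2 ms.
External (retinal/noise) drive uses the somatic delay range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = ["SYNAPSE_KINDS", "SynapseParams", "psp_increment", "draw_delays",
           "DENDRITIC_DELAY", "SOMATIC_DELAY"]

SYNAPSE_KINDS = ("AM2", "NM2", "GA", "GA2")

DENDRITIC_DELAY = (3.0, 5.0)
SOMATIC_DELAY = (1.8, 2.2)


@dataclass(frozen=True)
class SynapseParams:
    """Fixed per-kind synapse parameters."""

    kind: str
    e_syn: float          # reversal potential relative to rest, mV
    tau_syn: float        # decay time constant, ms
    delay_range: Tuple[float, float]
    sign: int             # +1 excitatory, -1 inhibitory

    _REGISTRY: Dict[str, "SynapseParams"] = None  # type: ignore[assignment]

    @classmethod
    def of(cls, kind: str) -> "SynapseParams":
        try:
            return _SYNAPSE_PARAMS[kind]
        except KeyError:
            raise KeyError(f"unknown synapse kind {kind!r}") from None


_SYNAPSE_PARAMS: Dict[str, SynapseParams] = {
    "AM2": SynapseParams("AM2", 65.0, 10.0, DENDRITIC_DELAY, +1),
    "NM2": SynapseParams("NM2", 90.0, 300.0, DENDRITIC_DELAY, +1),
    "GA": SynapseParams("GA", -15.0, 10.0, SOMATIC_DELAY, -1),
    "GA2": SynapseParams("GA2", -15.0, 20.0, DENDRITIC_DELAY, -1),
}


def psp_increment(w_syn: float, v_dev: float, e_syn: float) -> float:
    """Stepwise synaptic voltage change ``W * (1 - V_dev / E_syn)``.

    ``v_dev`` is the membrane deviation from rest; the increment vanishes at
    the reversal potential and equals the weight at rest.
    """
    if e_syn == 0:
        raise ValueError("reversal potential must be non-zero")
    return w_syn * (1.0 - v_dev / e_syn)


def draw_delays(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-synapse conduction delays (ms), fixed after wiring."""
    lo, hi = SynapseParams.of(kind).delay_range
    return rng.uniform(lo, hi, size=n)
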