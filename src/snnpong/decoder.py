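"""Winner-take-all motor decoding.

Every action interval the spike counts of the two motor populations are
compared; the larger count wins (UP or DOWN) and equality — including total
silence — yields STAY.  Both populations have equal size, so raw counts and
population rates give identical decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .game import Action

__all__ = ["DecoderConfig", "decode_action"]


@dataclass(frozen=True)
class DecoderConfig:
    """Action cadence: 20 ms for the feedforward model, 50 ms recurrent."""

    action_interval: float = 20.0

    def __post_init__(self) -> None:
        if self.action_interval <= 0:
            raise ValueError("action interval must be positive")


def decode_action(count_up: int, count_down: int) -> Action:
    """Winner-take-all over the motor populations' spike counts."""
    if count_up < 0 or count_down < 0:
        raise ValueError("spike counts must be non-negative")
    if count_up > count_down:
        return Action.UP
    if count_down > count_up:
        return Action.DOWN
    return Action.STAY
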