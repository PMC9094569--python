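"""Retinal interface: frames -> input spike trains.

Game frames are binarized, 2x block-downsampled and turned into Poisson spike
trains: one location-encoding input per pixel (driving EV1 topographically)
and eight direction-selective channels (E, NE, N, NW, W, SW, S, SE) driven at
the pixels of any object that moved between the last two frames.  The
direction-selective populations are coarser 4x4-block topographic grids.

North means decreasing y (screen-up), matching the image-frame convention of
:mod:`snnpong.game`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS",
    "EncodingConfig",
    "DirectionField",
    "preprocess_frame",
    "motion_direction_field",
    "generate_input_spikes",
    "direction_bin",
]

#: Compass order used for the eight direction-selective populations.
DIRECTIONS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

#: Unit angle (radians, y-down image coordinates) of each compass bin.
_DIR_ANGLES = {name: i * math.pi / 4 for i, name in enumerate(DIRECTIONS)}


@dataclass(frozen=True)
class EncodingConfig:
    """Input layer geometry and drive rates.

    ``location_rate`` is the Poisson rate (Hz) of a driven location pixel:
    20 Hz for the feedforward model, 35 Hz for the recurrent one.  The
    direction channels default to the same rate.  ``game_step`` is the
    sense-act interval in ms (20 feedforward / 50 recurrent).
    """

    input_width: int = 80
    input_height: int = 80
    location_rate: float = 20.0
    direction_rate: Optional[float] = None
    direction_block: int = 4
    game_step: float = 20.0

    def __post_init__(self) -> None:
        if self.location_rate < 0 or (self.direction_rate or 0) < 0:
            raise ValueError("rates must be non-negative")
        if self.game_step <= 0:
            raise ValueError("game_step must be positive")

    @property
    def dir_rate(self) -> float:
        return self.location_rate if self.direction_rate is None else self.direction_rate

    @property
    def n_location(self) -> int:
        return self.input_width * self.input_height

    @property
    def dir_grid(self) -> Tuple[int, int]:
        return (self.input_height // self.direction_block,
                self.input_width // self.direction_block)

    @property
    def n_direction(self) -> int:
        h, w = self.dir_grid
        return h * w


#: Mapping direction-name -> flat indices of driven direction neurons.
DirectionField = Dict[str, np.ndarray]


def preprocess_frame(raw: np.ndarray) -> np.ndarray:
    """Binarize and 2x2 block-downsample a court-sized frame.

    Color frames (H, W, 3) are reduced by any-channel > 0; a downsampled
    block is set if any of its four constituent pixels is set.
    """
    if raw.ndim == 3:
        raw = raw.max(axis=2)
    if raw.ndim != 2 or raw.shape[0] % 2 or raw.shape[1] % 2:
        raise ValueError(f"expected an even-sized 2D frame, got shape {raw.shape}")
    binary = (raw > 0).astype(np.uint8)
    h, w = binary.shape
    blocks = binary.reshape(h // 2, 2, w // 2, 2)
    return blocks.max(axis=(1, 3))


def direction_bin(dx: float, dy: float) -> str:
    """Nearest of the eight compass bins for a displacement (y-down frame)."""
    if dx == 0 and dy == 0:
        raise ValueError("zero displacement has no direction")
    # screen-up is north: flip y for the conventional math angle
    ang = math.atan2(-dy, dx)
    k = int(round(ang / (math.pi / 4))) % 8
    return DIRECTIONS[k]


_LABEL_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _objects(frame: np.ndarray) -> List[Tuple[np.ndarray, np.ndarray, Tuple[float, float]]]:
    """Connected components of a binary frame with their centroids."""
    labels, n = ndimage.label(frame, structure=_LABEL_STRUCTURE)
    if n == 0:
        return []
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    order = np.argsort(lab, kind="stable")
    ys, xs, lab = ys[order], xs[order], lab[order]
    bounds = np.searchsorted(lab, np.arange(1, n + 2))
    out = []
    for i in range(n):
        a, b = bounds[i], bounds[i + 1]
        oy, ox = ys[a:b], xs[a:b]
        out.append((oy, ox, (float(ox.mean()), float(oy.mean()))))
    return out


def motion_direction_field(frame_t: np.ndarray, frame_prev: np.ndarray,
                           config: EncodingConfig) -> DirectionField:
    """Direction-selective drive from the last two consecutive frames.

    Objects (connected components) are matched between frames by nearest
    centroid; each displaced object contributes its current pixels to the
    compass bin nearest its displacement.  Unmoved objects drive nothing.
    The returned indices address the coarse direction grid (one neuron per
    ``direction_block`` x ``direction_block`` pixel block).
    """
    if frame_t.shape != frame_prev.shape:
        raise ValueError("frames must have identical shapes")
    curr = _objects(frame_t)
    prev = _objects(frame_prev)
    field: Dict[str, set] = {}
    gh, gw = config.dir_grid
    blk = config.direction_block
    for ys, xs, (cx, cy) in curr:
        if not prev:
            continue
        # nearest previous object by centroid
        dists = [(px - cx) ** 2 + (py - cy) ** 2 for _, _, (px, py) in prev]
        j = int(np.argmin(dists))
        px, py = prev[j][2]
        dx, dy = cx - px, cy - py
        if dx == 0 and dy == 0:
            continue
        name = direction_bin(dx, dy)
        rows = np.minimum(ys // blk, gh - 1)
        cols = np.minimum(xs // blk, gw - 1)
        field.setdefault(name, set()).update((rows * gw + cols).tolist())
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in field.items()}


def _poisson_times(rate_hz: float, t0: float, dt: float, n_units: int,
                   rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson spikes for ``n_units`` independent processes.

    Sampled by exponential inter-arrival times within [t0, t0+dt) ms.
    Returns (unit_index, time_ms) arrays sorted by time.
    """
    if rate_hz <= 0 or n_units == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    rate_ms = rate_hz / 1000.0
    units: List[int] = []
    times: List[float] = []
    for u in range(n_units):
        t = t0 + rng.exponential(1.0 / rate_ms)
        while t < t0 + dt:
            units.append(u)
            times.append(t)
            t += rng.exponential(1.0 / rate_ms)
    unit_arr = np.array(units, dtype=np.int64)
    time_arr = np.array(times)
    order = np.argsort(time_arr, kind="stable")
    return unit_arr[order], time_arr[order]


def generate_input_spikes(frame: np.ndarray, field: DirectionField,
                          config: EncodingConfig, rng: np.random.Generator,
                          t0: float = 0.0):
    """Spike events for the location and direction input channels.

    Returns ``(loc_idx, loc_t, dir_events)`` where ``loc_idx`` are flat
    pixel indices of the location channel, ``loc_t`` their spike times in
    ``[t0, t0 + game_step)`` ms, and ``dir_events`` maps direction name ->
    ``(neuron_idx, times)`` over the coarse direction grid.
    """
    if frame.shape != (config.input_height, config.input_width):
        raise ValueError(
            f"frame shape {frame.shape} does not match input layout "
            f"({config.input_height}, {config.input_width})")
    driven = np.flatnonzero(frame.ravel())
    u, t = _poisson_times(config.location_rate, t0, config.game_step,
                          len(driven), rng)
    loc_idx, loc_t = driven[u], t
    dir_events = {}
    for name in DIRECTIONS:
        idx = field.get(name)
        if idx is None or len(idx) == 0:
            continue
        u, t = _poisson_times(config.dir_rate, t0, config.game_step, len(idx), rng)
        if len(u):
            dir_events[name] = (idx[u], t)
    return loc_idx, loc_t, dir_events
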