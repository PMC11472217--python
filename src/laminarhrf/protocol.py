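"""Gas-challenge protocol description.

A run is a fixed sequence of gas blocks. The default protocol reproduces the
study conditions this package is built around: after a 30 s baseline, a 200 s
room-air period, 120 s at +5 mmHg end-tidal CO2, 120 s at +10 mmHg CO2 and
120 s at +350 mmHg end-tidal O2. Those blocks account for 590 s of the 697 s
run (820 volumes at TR 0.85 s); the remaining 107 s are modeled as a terminal
room-air period, since the protocol itself leaves them unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: gas-condition labels in protocol order (baseline is a pre-task rest period)
BLOCK_LABELS = ("baseline", "room_air", "hc5", "hc10", "ho")


@dataclass(frozen=True)
class GasBlock:
    label: str
    duration: float            # s
    dpetco2: float = 0.0       # target end-tidal CO2 offset from baseline, mmHg
    dpeto2: float = 0.0        # target end-tidal O2 offset from baseline, mmHg

    def __post_init__(self) -> None:
        if self.label not in BLOCK_LABELS:
            raise ValueError(f"unknown block label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("block duration must be > 0")
        if self.dpetco2 < 0 or self.dpeto2 < 0:
            raise ValueError("gas targets are offsets from baseline and must be >= 0")


@dataclass(frozen=True)
class GasProtocol:
    """Ordered gas blocks plus baseline end-tidal pressures.

    Parameters
    ----------
    blocks
        Ordered gas blocks; durations must sum to the run duration.
    baseline_petco2, baseline_peto2
        Resting end-tidal partial pressures in mmHg (typical resting values
        are ~38 mmHg CO2 and ~100 mmHg O2).
    transition_tau
        Exponential time constant (s) with which the end-tidal level
        approaches each block's target.
    """

    blocks: tuple[GasBlock, ...]
    baseline_petco2: float = 38.0
    baseline_peto2: float = 100.0
    transition_tau: float = 10.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("protocol needs at least one block")
        if self.transition_tau < 0:
            raise ValueError("transition_tau must be >= 0")
        if self.baseline_petco2 <= 0 or self.baseline_peto2 <= 0:
            raise ValueError("baseline pressures must be positive")

    @property
    def duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def boundaries(self) -> np.ndarray:
        """Block start times plus the run end, shape (n_blocks + 1,)."""
        edges = np.concatenate([[0.0], np.cumsum([b.duration for b in self.blocks])])
        return edges

    def block_at(self, t: float) -> GasBlock:
        """Block containing time ``t`` (s); the run end maps to the last block."""
        edges = self.boundaries
        if t < 0 or t > edges[-1]:
            raise ValueError(f"t={t} outside run [0, {edges[-1]}]")
        idx = int(np.searchsorted(edges, t, side="right") - 1)
        return self.blocks[min(idx, len(self.blocks) - 1)]

    def labels_at(self, t: np.ndarray) -> np.ndarray:
        edges = self.boundaries
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.blocks) - 1)
        return np.array([self.blocks[i].label for i in idx])


def default_protocol(
    tail_duration: float = 107.0,
    baseline_petco2: float = 38.0,
    baseline_peto2: float = 100.0,
    transition_tau: float = 10.0,
) -> GasProtocol:
    """The default 697 s four-challenge protocol (see module docstring)."""
    blocks = [
        GasBlock("baseline", 30.0),
        GasBlock("room_air", 200.0),
        GasBlock("hc5", 120.0, dpetco2=5.0),
        GasBlock("hc10", 120.0, dpetco2=10.0),
        GasBlock("ho", 120.0, dpeto2=350.0),
    ]
    if tail_duration > 0:
        blocks.append(GasBlock("room_air", tail_duration))
    return GasProtocol(
        blocks=tuple(blocks),
        baseline_petco2=baseline_petco2,
        baseline_peto2=baseline_peto2,
        transition_tau=transition_tau,
    )
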