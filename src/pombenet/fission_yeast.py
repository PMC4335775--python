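"""The fission-yeast (S. pombe) cell-cycle threshold Boolean network.

Ten nodes — Start, SK, Cdc2/Cdc13, Ste9, Rum1, Slp1, Cdc2/Cdc13*, Wee1/Mik1,
Cdc25, PP — with 27 signed interactions (8 activating, 19 inhibiting,
self-degradation loops included).  Under synchronous updating the network,
started from the START state, walks through the ten printed cell-cycle states
(START → G1 → G1/S → G2 → G2/M → M → G1) and converges to the stationary G1
fixed point.

The parameters and the target sequence are shipped as data files
(``data/wildtype.json``, ``data/cell_cycle_sequence.tsv``) rather than
hard-coded; their correctness is enforced by the trajectory and basin-size
tests, not by trust.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .network import (
    ThresholdNetwork,
    UpdateScheme,
    scheme_step,
    state_to_index,
)

__all__ = [
    "NODE_LABELS",
    "TargetSequence",
    "wildtype",
    "cell_cycle_sequence",
    "g1_fixed_point",
]

NODE_LABELS = (
    "Start",
    "SK",
    "Cdc2/Cdc13",
    "Ste9",
    "Rum1",
    "Slp1",
    "Cdc2/Cdc13*",
    "Wee1/Mik1",
    "Cdc25",
    "PP",
)


@dataclass(frozen=True)
class TargetSequence:
    """The ten cell-cycle state vectors and their phase labels."""

    states: tuple[tuple[int, ...], ...]
    phases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != 10 or len(self.phases) != 10:
            raise ValueError("the cell-cycle sequence has exactly 10 rows")
        if any(len(s) != 10 for s in self.states):
            raise ValueError("each cell-cycle state has exactly 10 nodes")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, k: int) -> tuple[int, ...]:
        return self.states[k]


def _data_text(name: str) -> str:
    return resources.files("pombenet.data").joinpath(name).read_text()


def wildtype() -> ThresholdNetwork:
    """The wildtype fission-yeast cell-cycle network (10 nodes, 27 edges)."""
    raw = json.loads(_data_text("wildtype.json"))
    return ThresholdNetwork.from_theta(raw["labels"], raw["W"], raw["theta"])


def cell_cycle_sequence() -> TargetSequence:
    """The ten-state cell-cycle trajectory the network must reproduce."""
    lines = _data_text("cell_cycle_sequence.tsv").strip().splitlines()
    header = lines[0].split("\t")
    assert tuple(header[1:11]) == NODE_LABELS
    states, phases = [], []
    for line in lines[1:]:
        cells = line.split("\t")
        states.append(tuple(int(b) for b in cells[1:11]))
        phases.append(cells[11])
    return TargetSequence(states=tuple(states), phases=tuple(phases))


def g1_fixed_point() -> tuple[int, ...]:
    """The stationary G1 state (final row of the cell-cycle sequence).

    Asserts the defining property: the state is its own parallel successor.
    """
    g1 = cell_cycle_sequence()[9]
    assert scheme_step(wildtype(), g1, UpdateScheme("parallel")) == g1
    return g1


def g1_index() -> int:
    """Integer encoding of the G1 fixed point (Start = most significant bit)."""
    return state_to_index(g1_fixed_point())
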