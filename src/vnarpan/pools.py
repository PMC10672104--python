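"""Phage-pool identities.

A biopanning experiment produces one phage pool per (selection condition,
round).  Pools are labelled with the condition letter followed by the round
digit ("N3" = normal conditions, round 3); the pre-panning library is the
special pool "Input" (round 0).
"""
from __future__ import annotations

from dataclasses import dataclass

#: Selection conditions: N = normal, L = low temperature, S = high salt,
#: U = high urea, H = preheat.  "Input" is the unpanned library.
CONDITIONS = ("Input", "N", "L", "S", "U", "H")


@dataclass(frozen=True, order=True)
class PoolId:
    """Identity of a panning pool: condition plus round number."""

    condition: str
    round: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.condition == "Input":
            if self.round != 0:
                raise ValueError("the Input pool has no round number (round must be 0)")
        elif not 1 <= self.round <= 3:
            raise ValueError(f"round must be 1-3 for condition pools, got {self.round}")

    @property
    def label(self) -> str:
        """Render as the conventional pool name, e.g. ``"N3"`` or ``"Input"``."""
        if self.condition == "Input":
            return "Input"
        return f"{self.condition}{self.round}"

    @classmethod
    def from_label(cls, label: str) -> "PoolId":
        """Parse a pool label such as ``"L2"`` or ``"Input"``."""
        if label == "Input":
            return cls("Input", 0)
        if len(label) == 2 and label[0] in CONDITIONS and label[1].isdigit():
            return cls(label[0], int(label[1]))
        raise ValueError(f"cannot parse pool label {label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


INPUT_POOL = PoolId("Input", 0)
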