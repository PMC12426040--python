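"""Signal catalog and state codes for the dialysis-cycle controller.

The controller is a clocked Moore machine with a 5-bit state register
(flip-flops A..E, A most significant).  Sixteen boolean inputs -- operator
buttons plus thresholded sensor lines -- drive the transitions, and each of
the eighteen named states asserts one output (stand-by, heater on, filling
start, flush stage, ...).  States ``S_0``..``S_16`` occupy codes
``00000``..``10000`` in binary order; the error alarm ``A`` sits at
``11111``, and the fourteen codes in between are deliberately unused.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "INPUT_NAMES",
    "TRANSITION_NAMES",
    "N_INPUTS",
    "N_STATE_BITS",
    "STANDBY",
    "ALARM",
    "StateCode",
    "OutputState",
    "SignalCatalog",
    "load_catalog",
    "shipped_catalog_path",
]

#: Canonical input order (first table column to last); used everywhere --
#: files, vectors, logs -- so that no column drift is possible.
INPUT_NAMES: tuple[str, ...] = (
    "S", "DM", "FM", "AI", "P", "T", "SD",
    "F1", "F2", "F3", "F4", "L", "PR", "TU", "DV", "F",
)

#: Transition-symbol vocabulary used in the excitation equations.
TRANSITION_NAMES: tuple[str, ...] = tuple(f"T_{n}" for n in INPUT_NAMES)

N_INPUTS = len(INPUT_NAMES)
N_STATE_BITS = 5

STANDBY = 0
ALARM = 0b11111

_INPUT_INDEX = {name: i for i, name in enumerate(INPUT_NAMES)}


@dataclass(frozen=True, order=True)
class StateCode:
    """A 5-bit state-register value ABCDE, A most significant."""

    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < 2 ** N_STATE_BITS:
            raise ValueError(f"state code out of range: {self.value}")

    @classmethod
    def from_bits(cls, bits: str) -> "StateCode":
        bits = bits.strip()
        if len(bits) != N_STATE_BITS or any(b not in "01" for b in bits):
            raise ValueError(f"expected a 5-character binary string, got {bits!r}")
        return cls(int(bits, 2))

    @property
    def bits(self) -> str:
        return format(self.value, f"0{N_STATE_BITS}b")

    @property
    def is_unused(self) -> bool:
        """True for the codes 10001..11110 that no state occupies."""
        return STANDBY < self.value < ALARM and self.value > 0b10000

    @property
    def is_named(self) -> bool:
        return not self.is_unused

    def bit(self, position: int) -> int:
        """Flip-flop bit by position: 0 = A (most significant) .. 4 = E."""
        return (self.value >> (N_STATE_BITS - 1 - position)) & 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.bits


@dataclass(frozen=True)
class OutputState:
    """One Moore output: the state that asserts it."""

    name: str
    description: str
    label: str  # S_0 .. S_17
    code: StateCode


@dataclass
class SignalCatalog:
    """The controller's I/O surface: 16 inputs and 18 named output states."""

    inputs: tuple[str, ...] = INPUT_NAMES
    input_descriptions: dict[str, str] = field(default_factory=dict)
    outputs: tuple[OutputState, ...] = ()

    def __post_init__(self) -> None:
        if len(self.inputs) != N_INPUTS:
            raise ValueError(f"expected {N_INPUTS} inputs, got {len(self.inputs)}")
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("input names must be unique")
        if self.outputs:
            if len(self.outputs) != 18:
                raise ValueError(f"expected 18 outputs, got {len(self.outputs)}")
            names = [o.name for o in self.outputs]
            codes = [o.code.value for o in self.outputs]
            if len(set(names)) != len(names):
                raise ValueError("output names must be unique")
            if len(set(codes)) != len(codes):
                raise ValueError("output state codes must be unique")
            # S_0..S_16 in binary order, alarm at 11111
            for i, out in enumerate(self.outputs[:-1]):
                if out.code.value != i:
                    raise ValueError(
                        f"output {out.name} bound to {out.code.bits}, expected "
                        f"{format(i, '05b')}"
                    )
            if self.outputs[-1].code.value != ALARM:
                raise ValueError("last output (alarm) must be bound to 11111")

    def input_index(self, name: str) -> int:
        return _INPUT_INDEX[name]

    def state_name(self, code: StateCode | int) -> str:
        """Human name of a state code; unused codes report themselves."""
        value = code.value if isinstance(code, StateCode) else code
        for out in self.outputs:
            if out.code.value == value:
                return out.name
        return f"UNUSED({format(value, '05b')})"

    def __iter__(self) -> Iterator[OutputState]:
        return iter(self.outputs)


def shipped_catalog_path() -> Path:
    """Path of the packaged signal-catalog file."""
    return Path(resources.files("pdfsm").joinpath("data/signal_catalog.csv"))


def load_catalog(path: str | Path | None = None) -> SignalCatalog:
    """Read a signal-catalog file (CSV, one row per numbered I/O line).

    The file mirrors the machine's I/O description table: input name,
    transition symbol, output name, state label and 5-bit state code.  Rows
    17 and 18 carry outputs only (there are two more outputs than inputs).
    """
    path = Path(path) if path is not None else shipped_catalog_path()
    inputs: list[str] = []
    descriptions: dict[str, str] = {}
    outputs: list[OutputState] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["input"]:
                inputs.append(row["input"])
                descriptions[row["input"]] = row["input_description"]
            outputs.append(
                OutputState(
                    name=row["output"],
                    description=row["output_description"],
                    label=row["state_label"],
                    code=StateCode.from_bits(row["state_code"]),
                )
            )
    return SignalCatalog(
        inputs=tuple(inputs),
        input_descriptions=descriptions,
        outputs=tuple(outputs),
    )
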