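"""Ternary-pattern (cube) algebra.

A pattern assigns each input line one of ``0``, ``1`` or ``X`` (don't-care).
A pattern of width *w* matches ``2**(#X)`` of the ``2**w`` full input
vectors.  Internally a pattern is a pair of integers -- a care mask and a
value -- with the first symbol in the most significant bit, so matching a
packed input vector is a single mask-and-compare.

The subtraction primitive (cube minus cube, yielding disjoint remainder
cubes) is what lets the synthesiser build a disjoint cover from overlapping
table rows and compute the uncovered residue of a state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import N_INPUTS

__all__ = ["TernaryPattern", "InputVector"]

_SYMBOLS = frozenset("01X")


@dataclass(frozen=True)
class TernaryPattern:
    """An immutable ternary pattern over ``width`` boolean lines."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [s for s in self.symbols if s not in _SYMBOLS]
        if bad:
            raise ValueError(f"pattern symbols must be 0/1/X, got {bad[0]!r}")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "TernaryPattern":
        return cls(tuple(str(s).upper() for s in symbols))

    @classmethod
    def from_string(cls, text: str) -> "TernaryPattern":
        return cls.from_symbols(text)

    @classmethod
    def all_dontcare(cls, width: int = N_INPUTS) -> "TernaryPattern":
        return cls(("X",) * width)

    # -- basic views --------------------------------------------------
    @property
    def width(self) -> int:
        return len(self.symbols)

    @property
    def care_mask(self) -> int:
        m = 0
        for s in self.symbols:
            m = (m << 1) | (s != "X")
        return m

    @property
    def value(self) -> int:
        v = 0
        for s in self.symbols:
            v = (v << 1) | (s == "1")
        return v

    @property
    def num_dontcare(self) -> int:
        return sum(1 for s in self.symbols if s == "X")

    @property
    def num_specified(self) -> int:
        return self.width - self.num_dontcare

    @property
    def coverage(self) -> int:
        """Number of full input vectors this pattern matches (2^#X)."""
        return 1 << self.num_dontcare

    # -- relations ----------------------------------------------------
    def matches_int(self, vector: int) -> bool:
        return (vector & self.care_mask) == self.value

    def matches(self, bits: Sequence[int]) -> bool:
        return self.matches_int(_pack(bits, self.width))

    def intersects(self, other: "TernaryPattern") -> bool:
        common = self.care_mask & other.care_mask
        return (self.value & common) == (other.value & common)

    def subsumes(self, other: "TernaryPattern") -> bool:
        """True if every vector ``other`` matches is matched by ``self``."""
        return (
            (self.care_mask & other.care_mask) == self.care_mask
            and (other.value & self.care_mask) == self.value
        )

    def with_symbol(self, index: int, symbol: str) -> "TernaryPattern":
        s = list(self.symbols)
        s[index] = symbol
        return TernaryPattern(tuple(s))

    def subtract(self, other: "TernaryPattern") -> list["TernaryPattern"]:
        """Disjoint cubes covering exactly self's vectors not in ``other``.

        Standard cube peeling: walk the lines where ``other`` is specified
        but ``self`` is free, splitting off the half that disagrees.
        """
        if not self.intersects(other):
            return [self]
        pieces: list[TernaryPattern] = []
        current = self
        for i, (a, b) in enumerate(zip(self.symbols, other.symbols)):
            if b != "X" and a == "X":
                pieces.append(current.with_symbol(i, "0" if b == "1" else "1"))
                current = current.with_symbol(i, b)
        # `current` is now fully inside `other` and is dropped.
        return pieces

    def __str__(self) -> str:
        return "".join(self.symbols)


def _pack(bits: Sequence[int], width: int) -> int:
    if len(bits) != width:
        raise ValueError(f"expected {width} bits, got {len(bits)}")
    v = 0
    for b in bits:
        if b not in (0, 1, False, True):
            raise ValueError(f"input bits must be 0/1, got {b!r}")
        v = (v << 1) | int(b)
    return v


def subtract_all(
    cubes: Iterable[TernaryPattern], minus: Iterable[TernaryPattern]
) -> list[TernaryPattern]:
    """Subtract every cube in ``minus`` from the union of ``cubes``."""
    result = list(cubes)
    for m in minus:
        result = [piece for c in result for piece in c.subtract(m)]
    return result


@dataclass(frozen=True)
class InputVector:
    """One joint boolean reading of the 16 input lines, catalog order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_INPUTS:
            raise ValueError(f"expected {N_INPUTS} bits, got {len(self.bits)}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("input bits must be 0 or 1")

    @classmethod
    def from_names(cls, _default: int = 0, **named_bits: int) -> "InputVector":
        """Build a vector from named bits; unnamed lines take ``_default``.

        >>> InputVector.from_names(S=1, DM=1).as_int() >> 14
        3
        """
        from .catalog import INPUT_NAMES

        unknown = set(named_bits) - set(INPUT_NAMES)
        if unknown:
            raise ValueError(f"unknown input names: {sorted(unknown)}")
        return cls(tuple(int(named_bits.get(n, _default)) for n in INPUT_NAMES))

    @classmethod
    def from_int(cls, value: int) -> "InputVector":
        return cls(tuple((value >> (N_INPUTS - 1 - i)) & 1 for i in range(N_INPUTS)))

    def as_int(self) -> int:
        return _pack(self.bits, N_INPUTS)

    def as_dict(self) -> dict[str, int]:
        from .catalog import INPUT_NAMES

        return dict(zip(INPUT_NAMES, self.bits))

    def __getitem__(self, name: str) -> int:
        from .catalog import INPUT_NAMES

        return self.bits[INPUT_NAMES.index(name)]
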