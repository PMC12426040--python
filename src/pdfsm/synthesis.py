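"""Flip-flop excitation synthesis and exhaustive equivalence checking.

Each state-register bit of the clocked machine is fed by a D flip-flop
whose excitation function ``D_A``..``D_E`` maps the 21 boolean variables
(state bits ``A``..``E`` plus the 16 input transitions ``T_S``..``T_F``) to
that bit of the next state.  The synthesiser derives each function as a
sum-of-products directly from the transition table:

* one product term per effective (priority-resolved) row cube whose
  next-state bit is 1 -- state literals fully specified, input literals
  only for the pattern's non-don't-care symbols;
* completion terms for the uncovered residue of each state (under the
  ``hold`` policy a state keeps its own bits; under ``alarm`` the residue
  raises every bit);
* trap terms sending every unused register code to the alarm state.

The equivalence oracle is deliberately brute force: every synthesised
expression is evaluated on all 2,097,152 assignments (2^5 state codes x
2^16 input vectors) and compared bit-for-bit with the table's next-state
function.  Simplification (iterated adjacency merging plus absorption)
re-checks itself against the same oracle and can therefore never change
the function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import ALARM, INPUT_NAMES, N_INPUTS, N_STATE_BITS, StateCode, TRANSITION_NAMES
from .patterns import TernaryPattern
from .table import UNIVERSE, TransitionTable

__all__ = [
    "STATE_VARS",
    "VARIABLES",
    "FLIPFLOPS",
    "Literal",
    "ProductTerm",
    "SOPExpression",
    "EquivalenceReport",
    "extract_on_set",
    "synthesize_sop",
    "simplify",
    "equivalent",
    "reconstruct_next_state",
]

STATE_VARS: tuple[str, ...] = ("A", "B", "C", "D", "E")
VARIABLES: tuple[str, ...] = STATE_VARS + TRANSITION_NAMES
FLIPFLOPS: tuple[str, ...] = tuple(f"D_{v}" for v in STATE_VARS)

_VAR_INDEX = {v: i for i, v in enumerate(VARIABLES)}


def _flipflop_position(flipflop: str) -> int:
    if flipflop not in FLIPFLOPS:
        raise ValueError(
            f"unknown flip-flop {flipflop!r}; expected one of {list(FLIPFLOPS)}"
        )
    return FLIPFLOPS.index(flipflop)


@dataclass(frozen=True)
class Literal:
    """A possibly negated variable from the 21-symbol vocabulary."""

    variable: str
    negated: bool = False

    def __post_init__(self) -> None:
        if self.variable not in _VAR_INDEX:
            raise ValueError(f"unknown variable {self.variable!r}")

    def __str__(self) -> str:
        return self.variable + ("'" if self.negated else "")


@dataclass(frozen=True)
class ProductTerm:
    """An AND of literals; at most one polarity per variable."""

    literals: frozenset[Literal]

    def __post_init__(self) -> None:
        seen: dict[str, bool] = {}
        for lit in self.literals:
            if lit.variable in seen and seen[lit.variable] != lit.negated:
                raise ValueError(
                    f"variable {lit.variable} appears with both polarities"
                )
            seen[lit.variable] = lit.negated

    @classmethod
    def from_polarities(cls, polarities: dict[str, bool]) -> "ProductTerm":
        """Build from a variable -> value map (True means plain literal)."""
        return cls(
            frozenset(Literal(v, negated=not val) for v, val in polarities.items())
        )

    def polarities(self) -> dict[str, bool]:
        return {lit.variable: not lit.negated for lit in self.literals}

    def sorted_literals(self) -> list[Literal]:
        return sorted(self.literals, key=lambda l: _VAR_INDEX[l.variable])

    def __str__(self) -> str:
        if not self.literals:
            return "1"
        return "·".join(str(l) for l in self.sorted_literals())


@dataclass
class SOPExpression:
    """A sum-of-products excitation function for one flip-flop."""

    flipflop: str
    terms: list[ProductTerm]

    def __post_init__(self) -> None:
        _flipflop_position(self.flipflop)

    def evaluate(self, state: StateCode, input_vector: int) -> bool:
        assignment = _assignment_bits(state.value, input_vector)
        return any(
            all(
                assignment[lit.variable] != lit.negated for lit in term.literals
            )
            for term in self.terms
        )

    def evaluate_universe(self) -> np.ndarray:
        """Truth values on all 2^21 assignments (index = state<<16 | inputs)."""
        bits = _universe_bits()
        out = np.zeros(UNIVERSE, dtype=bool)
        for term in self.terms:
            acc = np.ones(UNIVERSE, dtype=bool)
            for lit in term.literals:
                b = bits[lit.variable]
                acc &= ~b if lit.negated else b
            out |= acc
        return out

    def to_text(self) -> str:
        if not self.terms:
            return f"{self.flipflop} = 0"
        return f"{self.flipflop} = " + " + ".join(str(t) for t in self.terms)

    def to_json_dict(self) -> dict:
        return {
            "flipflop": self.flipflop,
            "terms": [
                {str(l.variable): ("neg" if l.negated else "pos") for l in t.sorted_literals()}
                for t in self.terms
            ],
        }


def _assignment_bits(state_value: int, input_vector: int) -> dict[str, int]:
    bits = {}
    for i, v in enumerate(STATE_VARS):
        bits[v] = (state_value >> (N_STATE_BITS - 1 - i)) & 1
    for i, v in enumerate(TRANSITION_NAMES):
        bits[v] = (input_vector >> (N_INPUTS - 1 - i)) & 1
    return bits


_UNIVERSE_BITS: dict[str, np.ndarray] = {}


def _universe_bits() -> dict[str, np.ndarray]:
    """Boolean value of each of the 21 variables across the full universe."""
    if not _UNIVERSE_BITS:
        idx = np.arange(UNIVERSE, dtype=np.uint32)
        for i, v in enumerate(STATE_VARS):
            shift = N_INPUTS + N_STATE_BITS - 1 - i
            _UNIVERSE_BITS[v] = ((idx >> shift) & 1).astype(bool)
        for i, v in enumerate(TRANSITION_NAMES):
            shift = N_INPUTS - 1 - i
            _UNIVERSE_BITS[v] = ((idx >> shift) & 1).astype(bool)
    return _UNIVERSE_BITS


# ----------------------------------------------------------------------


def extract_on_set(
    table: TransitionTable, flipflop: str, state: StateCode | None = None
) -> np.ndarray:
    """Minterm indices (21-bit) on which the next-state bit is 1.

    Restricting to one current ``state`` keeps only the 65,536 assignments
    with that register value.
    """
    pos = _flipflop_position(flipflop)
    nxt = table.next_state_array()
    on = (nxt >> (N_STATE_BITS - 1 - pos)) & 1
    indices = np.flatnonzero(on.astype(bool)).astype(np.uint32)
    if state is not None:
        lo = state.value << N_INPUTS
        hi = lo + (1 << N_INPUTS)
        indices = indices[(indices >= lo) & (indices < hi)]
    return indices


def _state_polarities(value: int) -> dict[str, bool]:
    return {
        v: bool((value >> (N_STATE_BITS - 1 - i)) & 1)
        for i, v in enumerate(STATE_VARS)
    }


def _cube_term(state_value: int, cube: TernaryPattern) -> ProductTerm:
    pol = _state_polarities(state_value)
    for name, sym in zip(TRANSITION_NAMES, cube.symbols):
        if sym != "X":
            pol[name] = sym == "1"
    return ProductTerm.from_polarities(pol)


def synthesize_sop(table: TransitionTable, flipflop: str) -> SOPExpression:
    """Derive the excitation SOP for one flip-flop from the table."""
    pos = _flipflop_position(flipflop)
    terms: list[ProductTerm] = []
    listed = {s.value for s in table.current_states()}
    for value in range(1 << N_STATE_BITS):
        state = StateCode(value)
        if state.is_unused and value not in listed:
            # Unused register codes trap to 11111, so every bit is high:
            # one all-input-don't-care term per code.
            terms.append(ProductTerm.from_polarities(_state_polarities(value)))
            continue
        for cube, nxt in table.effective_cover(state):
            if nxt.bit(pos):
                terms.append(_cube_term(value, cube))
        # Inputs no row covers: unused codes still trap; defined states
        # follow the completion policy.
        if state.is_unused or table.completion_policy == "alarm":
            residue_next: StateCode = StateCode(ALARM)
        else:
            residue_next = state
        if residue_next.bit(pos):
            for cube in table.residue(state):
                terms.append(_cube_term(value, cube))
    return SOPExpression(flipflop=flipflop, terms=terms)


# ----------------------------------------------------------------------
# simplification: adjacency merging + absorption, oracle-checked


def _try_merge(a: dict[str, bool], b: dict[str, bool]) -> dict[str, bool] | None:
    if set(a) != set(b):
        return None
    diff = [v for v in a if a[v] != b[v]]
    if len(diff) != 1:
        return None
    merged = dict(a)
    del merged[diff[0]]
    return merged


def _absorbs(a: dict[str, bool], b: dict[str, bool]) -> bool:
    """True if cube a contains cube b (a's literals are a subset of b's)."""
    return all(v in b and b[v] == val for v, val in a.items())


def simplify(expr: SOPExpression) -> SOPExpression:
    """Shrink an SOP without changing its on-set.

    Repeats single-variable adjacency merges (``A·B + A·B' -> A``) and
    absorption (``A + A·B -> A``) to a fixed point, then proves the result
    equivalent to the input by exhaustive evaluation; a disagreement (which
    would indicate a bug) raises rather than returning a wrong expression.
    """
    cubes = [t.polarities() for t in expr.terms]
    # dedupe
    unique: list[dict[str, bool]] = []
    for c in cubes:
        if c not in unique:
            unique.append(c)
    cubes = unique
    changed = True
    while changed:
        changed = False
        # absorption: drop any cube contained in a strictly smaller one
        kept: list[dict[str, bool]] = []
        for c in cubes:
            if any(other != c and _absorbs(other, c) for other in cubes):
                changed = True
                continue
            kept.append(c)
        cubes = kept
        # adjacency merge
        merged_result = None
        for i in range(len(cubes)):
            for j in range(i + 1, len(cubes)):
                m = _try_merge(cubes[i], cubes[j])
                if m is not None:
                    merged_result = (i, j, m)
                    break
            if merged_result:
                break
        if merged_result:
            i, j, m = merged_result
            cubes = [c for k, c in enumerate(cubes) if k not in (i, j)]
            if m not in cubes:
                cubes.append(m)
            changed = True
    result = SOPExpression(
        flipflop=expr.flipflop,
        terms=[ProductTerm.from_polarities(c) for c in cubes],
    )
    if len(result.terms) > len(expr.terms):  # pragma: no cover - by construction
        return expr
    if not np.array_equal(result.evaluate_universe(), expr.evaluate_universe()):
        raise AssertionError(
            "simplification changed the on-set; refusing to return the result"
        )  # pragma: no cover - internal safety net
    return result


# ----------------------------------------------------------------------


@dataclass
class EquivalenceReport:
    flipflop: str
    holds: bool
    universe: int
    mismatch_count: int
    counterexamples: list[tuple[str, int]] = field(default_factory=list)

    def summary(self) -> str:
        status = "PASS" if self.holds else f"FAIL ({self.mismatch_count} mismatches)"
        return f"{self.flipflop}: {status} over {self.universe} assignments"


def equivalent(
    expr: SOPExpression,
    table: TransitionTable,
    flipflop: str | None = None,
    counterexample_cap: int = 100,
) -> EquivalenceReport:
    """Exhaustively compare an SOP with the table-derived excitation bit.

    Evaluates the expression on all 2,097,152 assignments and reports any
    disagreement with the corresponding bit of ``next_state``, listing up
    to ``counterexample_cap`` counterexample (state, input) pairs.
    """
    flipflop = flipflop or expr.flipflop
    pos = _flipflop_position(flipflop)
    table_bit = (
        (table.next_state_array() >> (N_STATE_BITS - 1 - pos)) & 1
    ).astype(bool)
    expr_bit = expr.evaluate_universe()
    mismatch = np.flatnonzero(table_bit != expr_bit)
    examples = [
        (format(int(i) >> N_INPUTS, "05b"), int(i) & ((1 << N_INPUTS) - 1))
        for i in mismatch[:counterexample_cap]
    ]
    return EquivalenceReport(
        flipflop=flipflop,
        holds=mismatch.size == 0,
        universe=UNIVERSE,
        mismatch_count=int(mismatch.size),
        counterexamples=examples,
    )


def reconstruct_next_state(expressions: dict[str, SOPExpression]) -> np.ndarray:
    """Next-state code array implied by five excitation functions.

    Concatenates the D_A..D_E truth values per assignment; equality with
    ``TransitionTable.next_state_array`` is the soundness invariant.
    """
    missing = [ff for ff in FLIPFLOPS if ff not in expressions]
    if missing:
        raise ValueError(f"missing flip-flops: {missing}")
    code = np.zeros(UNIVERSE, dtype=np.uint8)
    for i, ff in enumerate(FLIPFLOPS):
        bit = expressions[ff].evaluate_universe().astype(np.uint8)
        code |= bit << (N_STATE_BITS - 1 - i)
    return code
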