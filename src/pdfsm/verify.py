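"""Safety-property verification and reachability analysis.

Every property is checked by exhaustive enumeration against the table's
total next-state function — no sampling, no abstraction:

* **fault -> alarm**: from every defined state, any input with the start
  gate high and both fault lines raised must go to ``11111``;
* **alarm recovery**: every input matching the recovery pattern must send
  ``11111`` back to standby;
* **unused-code trap**: each of the fourteen unused register codes must go
  to ``11111`` under all 65,536 input vectors;
* **totality**: the next-state function is defined on all 2,097,152
  (state, input) pairs and always yields a valid 5-bit code.

Reachability runs symbolically on the row graph (an edge per table row
with nonempty effective coverage, plus the unused-code traps) with a
brute-force vector-level closure available as an independent cross-check.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .catalog import ALARM, N_INPUTS, N_STATE_BITS, STANDBY, StateCode
from .table import UNIVERSE, TransitionTable

__all__ = [
    "PropertyResult",
    "ReachabilitySet",
    "check_fault_to_alarm",
    "check_alarm_recovery",
    "check_unused_trap",
    "check_totality",
    "reachable",
    "reachable_exhaustive",
    "verification_report",
]

_COUNTEREXAMPLE_CAP = 100


@dataclass
class PropertyResult:
    name: str
    holds: bool
    universe: int
    counterexamples: list[tuple[str, int]] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        assert self.holds == (not self.counterexamples)

    def summary(self) -> str:
        status = "holds" if self.holds else (
            f"FAILS ({len(self.counterexamples)} counterexamples shown)"
        )
        return f"{self.name}: {status} over {self.universe} pairs"

    def to_json_dict(self) -> dict:
        return {
            "property": self.name,
            "holds": self.holds,
            "universe": self.universe,
            "counterexamples": [
                {"state": s, "inputs": format(v, f"0{N_INPUTS}b")}
                for s, v in self.counterexamples
            ],
            "description": self.description,
        }


def _defined_states(table: TransitionTable) -> list[StateCode]:
    return [StateCode(v) for v in range(1 << N_STATE_BITS) if not StateCode(v).is_unused]


def _collect(
    table: TransitionTable,
    states: list[StateCode],
    input_mask: int,
    input_value: int,
    expected: int,
) -> tuple[int, list[tuple[str, int]]]:
    """Enumerate (state, input) pairs under an input constraint."""
    nxt = table.next_state_array()
    vectors = np.arange(1 << N_INPUTS, dtype=np.uint32)
    sel = (vectors & np.uint32(input_mask)) == np.uint32(input_value)
    chosen = vectors[sel]
    universe = 0
    bad: list[tuple[str, int]] = []
    for state in states:
        block = nxt[(state.value << N_INPUTS) + chosen]
        universe += chosen.size
        wrong = chosen[block != expected]
        for v in wrong[: max(0, _COUNTEREXAMPLE_CAP - len(bad))]:
            bad.append((state.bits, int(v)))
    return universe, bad


def _input_bit_mask(table: TransitionTable, *names: str) -> int:
    mask = 0
    for name in names:
        mask |= 1 << (N_INPUTS - 1 - table.catalog.input_index(name))
    return mask


def check_fault_to_alarm(
    table: TransitionTable, require_start: bool = True
) -> PropertyResult:
    """Any fault (danger value + system fault raised) forces the alarm state.

    The table's alarm rows sample the start gate, so the faithful property
    is guarded by ``S = 1``; ``require_start=False`` checks the stricter,
    unguarded variant (reported separately because the table does not
    promise it).
    """
    guard_names = ["DV", "F"] + (["S"] if require_start else [])
    mask = _input_bit_mask(table, *guard_names)
    universe, bad = _collect(table, _defined_states(table), mask, mask, ALARM)
    name = "fault_to_alarm" if require_start else "fault_to_alarm_unguarded"
    return PropertyResult(
        name=name,
        holds=not bad,
        universe=universe,
        counterexamples=bad,
        description=(
            "every defined state with "
            + ("S=1, " if require_start else "")
            + "DV=1, F=1 steps to 11111"
        ),
    )


def check_alarm_recovery(table: TransitionTable) -> PropertyResult:
    """Clearing the fault while started returns the alarm state to standby."""
    mask = _input_bit_mask(table, "S", "DV", "F")
    value = _input_bit_mask(table, "S")  # S=1, DV=0, F=0
    universe, bad = _collect(table, [StateCode(ALARM)], mask, value, STANDBY)
    return PropertyResult(
        name="alarm_recovery",
        holds=not bad,
        universe=universe,
        counterexamples=bad,
        description="11111 with S=1, DV=0, F=0 steps to 00000",
    )


def check_unused_trap(table: TransitionTable) -> PropertyResult:
    """Every unused register code traps to the alarm under all inputs."""
    unused = [StateCode(v) for v in range(1 << N_STATE_BITS) if StateCode(v).is_unused]
    universe, bad = _collect(table, unused, 0, 0, ALARM)
    return PropertyResult(
        name="unused_code_trap",
        holds=not bad,
        universe=universe,
        counterexamples=bad,
        description="codes 10001..11110 step to 11111 for every input vector",
    )


def check_totality(table: TransitionTable) -> PropertyResult:
    """next_state is a total function onto valid 5-bit codes."""
    nxt = table.next_state_array()
    ok = nxt.size == UNIVERSE and bool((nxt < (1 << N_STATE_BITS)).all())
    return PropertyResult(
        name="totality",
        holds=ok,
        universe=int(nxt.size),
        counterexamples=[],
        description="next_state defined on all 2^21 (state, input) pairs",
    )


# ----------------------------------------------------------------------


@dataclass
class ReachabilitySet:
    start: StateCode
    reached: set[StateCode]
    order: list[StateCode]  # first-visit order

    def __post_init__(self) -> None:
        assert self.start in self.reached

    @property
    def codes(self) -> list[str]:
        return [s.bits for s in self.order]


def _successors_symbolic(table: TransitionTable, state: StateCode) -> list[StateCode]:
    if state.is_unused:
        # the trap is structural (next_state hardwires it), rows or not
        return [StateCode(ALARM)]
    succ = {nxt for cube, nxt in table.effective_cover(state)}
    if table.completion_policy == "alarm" and table.residue(state):
        succ.add(StateCode(ALARM))
    # hold completion only yields the state itself; it adds no new node
    return sorted(succ)


def reachable(table: TransitionTable, start: StateCode) -> ReachabilitySet:
    """Breadth-first closure on the row graph (patterns, not vectors).

    An edge exists only where a row retains nonempty effective coverage
    after priority resolution, so fully shadowed rows contribute nothing.
    """
    order = [start]
    seen = {start}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        for nxt in _successors_symbolic(table, state):
            if nxt not in seen:
                seen.add(nxt)
                order.append(nxt)
                queue.append(nxt)
    return ReachabilitySet(start=start, reached=seen, order=order)


def reachable_exhaustive(table: TransitionTable, start: StateCode) -> ReachabilitySet:
    """Vector-level closure over all 65,536 inputs per state (oracle path)."""
    nxt = table.next_state_array()
    order = [start]
    seen = {start}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        block = nxt[state.value << N_INPUTS : (state.value + 1) << N_INPUTS]
        for value in sorted(int(v) for v in np.unique(block)):
            code = StateCode(value)
            if code not in seen:
                seen.add(code)
                order.append(code)
                queue.append(code)
    return ReachabilitySet(start=start, reached=seen, order=order)


def verification_report(table: TransitionTable) -> dict:
    """Run every property plus reachability; JSON-ready."""
    results = [
        check_totality(table),
        check_fault_to_alarm(table),
        check_fault_to_alarm(table, require_start=False),
        check_alarm_recovery(table),
        check_unused_trap(table),
    ]
    reach = reachable(table, StateCode(STANDBY))
    report = {
        "properties": [r.to_json_dict() for r in results],
        "reachable_from_standby": reach.codes,
        "n_reachable": len(reach.reached),
        # the unguarded fault variant is informational, not a promise of the table
        "all_hold": all(
            r.holds for r in results if r.name != "fault_to_alarm_unguarded"
        ),
    }
    return report


def report_text(report: dict) -> str:
    lines = []
    for prop in report["properties"]:
        status = "holds" if prop["holds"] else "FAILS"
        lines.append(
            f"{prop['property']:28s} {status:6s} universe={prop['universe']}"
        )
    lines.append(
        f"reachable from standby: {report['n_reachable']} states "
        f"({', '.join(report['reachable_from_standby'])})"
    )
    lines.append("overall: " + ("PASS" if report["all_hold"] else "FAIL"))
    return "\n".join(lines)
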