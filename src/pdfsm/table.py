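"""The transition-table engine.

The controller's complete behaviour is a list of ternary rows: (current
state, input pattern, next state).  ``next_state`` makes the table a total
function over all ``2**21`` (state-register, input) pairs:

* unused register codes (10001..11110) trap to the alarm state ``11111``;
* among matching rows, the most specific one (fewest don't-cares) wins —
  self-loop "stay" rows act as defaults that their exit rows override;
* a pair no row covers falls to the completion policy: ``hold`` keeps the
  current state, ``alarm`` escalates to ``11111``.

``validate`` reports genuinely ambiguous row conflicts (overlapping
patterns, different next states, neither subsuming the other), per-state
uncovered-input fractions, and sink states; ``audit_cases`` cross-checks
every row's printed case count against ``2**(#X)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    ALARM,
    INPUT_NAMES,
    N_INPUTS,
    N_STATE_BITS,
    SignalCatalog,
    StateCode,
    load_catalog,
)
from .patterns import InputVector, TernaryPattern, subtract_all

__all__ = [
    "TransitionRow",
    "TransitionTable",
    "TableParseError",
    "ConsistencyError",
    "ValidationReport",
    "AuditReport",
    "parse_table",
    "matches",
    "coverage_count",
    "next_state",
    "shipped_table_path",
    "load_shipped_table",
]

N_STATES = 1 << N_STATE_BITS
UNIVERSE = 1 << (N_STATE_BITS + N_INPUTS)  # 2,097,152 (state, input) pairs


class TableParseError(ValueError):
    """A transition-table file violates the dialect."""


class ConsistencyError(RuntimeError):
    """Matching rows disagree in a way validation should have caught."""


@dataclass(frozen=True)
class TransitionRow:
    current: StateCode
    pattern: TernaryPattern
    next: StateCode
    comment: str = ""
    printed_cases: int | None = None

    def __post_init__(self) -> None:
        if self.pattern.width != N_INPUTS:
            raise ValueError(
                f"row pattern must have {N_INPUTS} symbols, got {self.pattern.width}"
            )
        if self.printed_cases is not None and self.printed_cases < 0:
            raise ValueError("printed_cases must be nonnegative")


def matches(row: TransitionRow, state: StateCode, inputs: InputVector) -> bool:
    """True iff the row applies: same current state and pattern match."""
    return state == row.current and row.pattern.matches_int(inputs.as_int())


def coverage_count(row: TransitionRow) -> int:
    """Number of full input vectors the row's pattern matches (2^#X)."""
    return row.pattern.coverage


@dataclass
class ValidationReport:
    conflicts: list[tuple[TransitionRow, TransitionRow]]
    priority_overlaps: list[tuple[TransitionRow, TransitionRow]]
    uncovered_fraction: dict[str, float]
    sinks: list[StateCode]

    @property
    def ok(self) -> bool:
        return not self.conflicts

    def summary(self) -> str:
        lines = [
            f"conflicts: {len(self.conflicts)}",
            f"priority overlaps (specific row overrides default): "
            f"{len(self.priority_overlaps)}",
            "sinks: " + (", ".join(s.bits for s in self.sinks) or "none"),
        ]
        for code, frac in sorted(self.uncovered_fraction.items()):
            if frac:
                lines.append(f"state {code}: uncovered input fraction {frac:.4f}")
        return "\n".join(lines)


@dataclass
class AuditReport:
    n_rows: int
    mismatches: list[tuple[int, TransitionRow, int]]  # (row index, row, computed)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def summary(self) -> str:
        if self.ok:
            return f"{self.n_rows} rows, 0 case mismatches"
        lines = [f"{self.n_rows} rows, {len(self.mismatches)} case mismatches:"]
        for idx, row, computed in self.mismatches:
            lines.append(
                f"  row {idx + 1} ({row.current.bits} -> {row.next.bits}): "
                f"printed {row.printed_cases}, computed {computed}"
            )
        return "\n".join(lines)


@dataclass
class TransitionTable:
    """A validated, totalised controller behaviour."""

    catalog: SignalCatalog
    rows: list[TransitionRow]
    completion_policy: str = "hold"

    _next_array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.completion_policy not in ("hold", "alarm"):
            raise ValueError("completion_policy must be 'hold' or 'alarm'")

    # ------------------------------------------------------------------
    def rows_for(self, state: StateCode) -> list[TransitionRow]:
        return [r for r in self.rows if r.current == state]

    def current_states(self) -> list[StateCode]:
        return sorted({r.current for r in self.rows})

    def _completion_next(self, state: StateCode) -> StateCode:
        return state if self.completion_policy == "hold" else StateCode(ALARM)

    # ------------------------------------------------------------------
    def next_state(self, state: StateCode, inputs: InputVector) -> StateCode:
        """Total next-state function (see module docstring for semantics)."""
        if state.is_unused:
            return StateCode(ALARM)
        matching = [r for r in self.rows_for(state) if matches(r, state, inputs)]
        if not matching:
            return self._completion_next(state)
        targets = {r.next for r in matching}
        if len(targets) == 1:
            return targets.pop()
        # Specificity resolution: fewest don't-cares wins.
        best = min(r.pattern.num_dontcare for r in matching)
        winners = {r.next for r in matching if r.pattern.num_dontcare == best}
        if len(winners) != 1:
            raise ConsistencyError(
                f"ambiguous rows for state {state.bits}, inputs "
                f"{inputs.as_int():016b}; validation should have rejected this table"
            )
        return winners.pop()

    def next_state_array(self) -> np.ndarray:
        """Next-state code for every (state, input) pair as a uint8 array.

        Index layout: ``(state << 16) | input_vector`` with the S input in
        the vector's most significant bit.  Cached after first computation.
        """
        if self._next_array is not None:
            return self._next_array
        vectors = np.arange(1 << N_INPUTS, dtype=np.uint32)
        out = np.empty(UNIVERSE, dtype=np.uint8)
        for value in range(N_STATES):
            state = StateCode(value)
            base = value << N_INPUTS
            if state.is_unused:
                out[base : base + (1 << N_INPUTS)] = ALARM
                continue
            block = np.full(
                1 << N_INPUTS, self._completion_next(state).value, dtype=np.uint8
            )
            # Apply least-specific rows first so that more specific rows
            # overwrite them -- the array realises the priority semantics.
            ordered = sorted(
                self.rows_for(state), key=lambda r: -r.pattern.num_dontcare
            )
            for row in ordered:
                mask = (vectors & row.pattern.care_mask) == row.pattern.value
                block[mask] = row.next.value
            out[base : base + (1 << N_INPUTS)] = block
        self._next_array = out
        return out

    # ------------------------------------------------------------------
    def effective_cover(
        self, state: StateCode
    ) -> list[tuple[TernaryPattern, StateCode]]:
        """Disjoint (cube, next-state) cover realising the priority semantics.

        Rows are processed most specific first; each later row keeps only
        the part of its pattern not claimed by an earlier one.
        """
        ordered = sorted(self.rows_for(state), key=lambda r: r.pattern.num_dontcare)
        cover: list[tuple[TernaryPattern, StateCode]] = []
        claimed: list[TernaryPattern] = []
        for row in ordered:
            for piece in subtract_all([row.pattern], claimed):
                cover.append((piece, row.next))
            claimed.append(row.pattern)
        return cover

    def residue(self, state: StateCode) -> list[TernaryPattern]:
        """Cubes of the input space no row of ``state`` covers."""
        return subtract_all(
            [TernaryPattern.all_dontcare(N_INPUTS)],
            [r.pattern for r in self.rows_for(state)],
        )

    # ------------------------------------------------------------------
    def validate(self) -> ValidationReport:
        conflicts: list[tuple[TransitionRow, TransitionRow]] = []
        overlaps: list[tuple[TransitionRow, TransitionRow]] = []
        by_state: dict[int, list[TransitionRow]] = {}
        for row in self.rows:
            by_state.setdefault(row.current.value, []).append(row)
        for rows in by_state.values():
            for i, a in enumerate(rows):
                for b in rows[i + 1 :]:
                    if a.next == b.next or not a.pattern.intersects(b.pattern):
                        continue
                    # strict one-way subsumption is resolvable by priority;
                    # identical patterns or partial overlap are genuine
                    # ambiguities
                    if a.pattern.subsumes(b.pattern) != b.pattern.subsumes(a.pattern):
                        overlaps.append((a, b))
                    else:
                        conflicts.append((a, b))

        uncovered = {}
        for value, rows in by_state.items():
            state = StateCode(value)
            residue = self.residue(state)
            uncovered[state.bits] = sum(c.coverage for c in residue) / float(
                1 << N_INPUTS
            )

        fault_index = self.catalog.input_index("F")
        sinks = [
            StateCode(value)
            for value, rows in sorted(by_state.items())
            if not any(r.pattern.symbols[fault_index] in ("0", "X") for r in rows)
        ]
        return ValidationReport(conflicts, overlaps, uncovered, sinks)

    def audit_cases(self) -> AuditReport:
        mismatches = []
        for idx, row in enumerate(self.rows):
            if row.printed_cases is None:
                continue
            computed = coverage_count(row)
            if computed != row.printed_cases:
                mismatches.append((idx, row, computed))
        return AuditReport(n_rows=len(self.rows), mismatches=mismatches)


# ----------------------------------------------------------------------
# module-level operation aliases (functional surface)

def next_state(
    table: TransitionTable, state: StateCode, inputs: InputVector
) -> StateCode:
    return table.next_state(state, inputs)


def validate(table: TransitionTable) -> ValidationReport:
    return table.validate()


def audit_cases(table: TransitionTable) -> AuditReport:
    return table.audit_cases()


# ----------------------------------------------------------------------
# parsing

_REQUIRED_COLUMNS = ["state", *INPUT_NAMES, "next"]


def parse_table(
    path: str | Path,
    catalog: SignalCatalog | None = None,
    completion_policy: str = "hold",
) -> TransitionTable:
    """Read a transition-table file (comma- or tab-separated, header row).

    Columns: ``cases`` (optional printed case count), ``state`` (5-bit
    binary), one column per input line with values 0/1/X, ``next`` (5-bit
    binary) and ``comment``.  Exact duplicate rows are dropped with a
    warning; any symbol outside 0/1/X is a parse error naming the cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(
            path, sep=None, engine="python", dtype=str, keep_default_na=False
        )
    except Exception as exc:  # malformed delimiter structure
        raise TableParseError(f"{path}: cannot read table: {exc}") from exc
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableParseError(
            f"{path}: wrong column set, missing {missing} "
            f"(found {list(frame.columns)})"
        )

    catalog = catalog if catalog is not None else load_catalog()
    rows: list[TransitionRow] = []
    seen: dict[tuple, int] = {}
    for i, record in enumerate(frame.to_dict("records")):
        rownum = i + 2  # 1-based, after header
        symbols = []
        for name in INPUT_NAMES:
            sym = str(record[name]).strip().upper()
            if sym not in ("0", "1", "X"):
                raise TableParseError(
                    f"{path}: row {rownum}, column {name!r}: invalid symbol "
                    f"{record[name]!r} (expected 0, 1 or X)"
                )
            symbols.append(sym)
        try:
            current = StateCode.from_bits(str(record["state"]))
            nxt = StateCode.from_bits(str(record["next"]))
        except ValueError as exc:
            raise TableParseError(f"{path}: row {rownum}: {exc}") from exc
        printed = None
        if "cases" in frame.columns and str(record["cases"]).strip():
            text = str(record["cases"]).replace(",", "").strip()
            try:
                printed = int(text)
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: row {rownum}, column 'cases': {record['cases']!r} "
                    "is not an integer"
                ) from exc
        row = TransitionRow(
            current=current,
            pattern=TernaryPattern.from_symbols(symbols),
            next=nxt,
            comment=str(record.get("comment", "")).strip(),
            printed_cases=printed,
        )
        key = (current.value, row.pattern.symbols, nxt.value)
        if key in seen:
            warnings.warn(
                f"{path}: row {rownum} duplicates row {seen[key]}; dropped",
                stacklevel=2,
            )
            continue
        seen[key] = rownum
        rows.append(row)
    return TransitionTable(
        catalog=catalog, rows=rows, completion_policy=completion_policy
    )


def shipped_table_path() -> Path:
    """Path of the packaged transition-table fixture."""
    return Path(resources.files("pdfsm").joinpath("data/transition_table.csv"))


def load_shipped_table(completion_policy: str = "hold") -> TransitionTable:
    return parse_table(shipped_table_path(), completion_policy=completion_policy)
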