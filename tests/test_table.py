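"""Transition-table engine: parsing, matching, next-state semantics, audits."""

import numpy as np
import pytest

from pdfsm.catalog import ALARM, INPUT_NAMES, StateCode
from pdfsm.patterns import InputVector, TernaryPattern
from pdfsm.table import (
    ConsistencyError,
    TableParseError,
    TransitionRow,
    coverage_count,
    matches,
    parse_table,
)

from conftest import make_table


def row_for(table, current, nxt):
    found = [
        r
        for r in table.rows
        if r.current.bits == current and r.next.bits == nxt
    ]
    assert len(found) == 1, f"expected one row {current}->{nxt}, got {len(found)}"
    return found[0]


# ----------------------------------------------------------------------
# parsing


class TestParsing:
    def test_shipped_fixture_shape(self, table):
        assert len(table.rows) == 49
        assert len(table.current_states()) == 20
        assert all(r.printed_cases is not None for r in table.rows)

    def test_header_only_file(self, tmp_path, catalog):
        p = tmp_path / "empty.csv"
        p.write_text("cases,state," + ",".join(INPUT_NAMES) + ",next,comment\n")
        t = parse_table(p)
        assert t.rows == []
        # with no rows, every state's input space is entirely uncovered
        assert sum(c.coverage for c in t.residue(StateCode(0))) == 1 << 16

    def test_invalid_symbol_names_cell(self, tmp_path):
        header = "cases,state," + ",".join(INPUT_NAMES) + ",next,comment\n"
        body = "4,00000," + ",".join(["2"] + ["X"] * 15) + ",00001,bad\n"
        p = tmp_path / "bad.csv"
        p.write_text(header + body)
        with pytest.raises(TableParseError, match=r"row 2, column 'S'"):
            parse_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "short.csv"
        p.write_text("state,S,next\n00000,1,00001\n")
        with pytest.raises(TableParseError, match="missing"):
            parse_table(p)

    def test_duplicate_rows_deduplicated_with_warning(self, tmp_path):
        header = "cases,state," + ",".join(INPUT_NAMES) + ",next,comment\n"
        line = "32768,00000," + ",".join(["0"] + ["X"] * 15) + ",00000,stay\n"
        p = tmp_path / "dup.csv"
        p.write_text(header + line + line)
        with pytest.warns(UserWarning, match="duplicates"):
            t = parse_table(p)
        assert len(t.rows) == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_table(tmp_path / "nope.csv")


# ----------------------------------------------------------------------
# row matching and coverage


class TestMatching:
    def test_standby_hold_row(self, table):
        row = row_for(table, "00000", "00000")
        assert matches(row, StateCode(0), InputVector.from_names(S=0, DM=1, TU=1))
        assert not matches(row, StateCode(0), InputVector.from_names(S=1))

    @pytest.mark.parametrize("filler", [0, 1])
    def test_stay_in_filling_ignores_dontcares(self, table, filler):
        row = row_for(table, "00101", "00101")
        v = InputVector.from_names(
            filler, S=1, DM=1, FM=0, T=1, F2=1, L=1, PR=1, DV=0, F=0
        )
        assert matches(row, StateCode.from_bits("00101"), v)

    def test_wrong_state_never_matches(self, table):
        row = row_for(table, "00101", "00101")
        v = InputVector.from_names(S=1, DM=1, T=1, F2=1, L=1, PR=1)
        assert not matches(row, StateCode.from_bits("00100"), v)

    @pytest.mark.parametrize(
        "current,nxt,expected",
        [
            ("00000", "00000", 32768),  # only S specified
            ("00101", "00101", 128),  # nine specified bits
            ("10001", "11111", 65536),  # all don't-care
        ],
    )
    def test_coverage_count(self, table, current, nxt, expected):
        assert coverage_count(row_for(table, current, nxt)) == expected

    def test_fully_specified_pattern_covers_one(self, catalog):
        row = TransitionRow(
            current=StateCode(0),
            pattern=TernaryPattern.from_string("0" * 16),
            next=StateCode(0),
        )
        assert coverage_count(row) == 1


# ----------------------------------------------------------------------
# next-state semantics


class TestNextState:
    def test_standby_to_written_instructions(self, table):
        v = InputVector.from_names(S=1, DM=1, FM=0, DV=0, F=0, TU=1, P=1)
        assert table.next_state(StateCode(0), v).bits == "00001"

    def test_clear_drainage_returns_to_standby(self, table):
        v = InputVector.from_names(S=1, DM=1, FM=0, TU=0, DV=0, F=0)
        assert table.next_state(StateCode.from_bits("10000"), v).bits == "00000"

    def test_unused_code_traps_to_alarm(self, table):
        for vec in (0, 0xFFFF, 0x1234):
            out = table.next_state(StateCode.from_bits("10010"), InputVector.from_int(vec))
            assert out.value == ALARM

    def test_uncovered_pair_holds_by_default(self, table):
        # draining-end state has no fault-free exit row: hold keeps it
        v = InputVector.from_names(S=1, DM=1, FM=0, DV=0, F=0)
        assert table.next_state(StateCode.from_bits("01010"), v).bits == "01010"

    def test_uncovered_pair_escalates_under_alarm_policy(self, alarm_table):
        v = InputVector.from_names(S=1, DM=1, FM=0, DV=0, F=0)
        out = alarm_table.next_state(StateCode.from_bits("01010"), v)
        assert out.value == ALARM

    def test_specific_exit_overrides_stay_default(self, table):
        # heater-off: pressing start-dialysis must win over the stay row
        v = InputVector.from_names(S=1, DM=1, FM=0, T=1, SD=1, DV=0, F=0)
        assert table.next_state(StateCode.from_bits("00100"), v).bits == "00101"
        # flush: flow-4 stopping must win over the stay row
        v = InputVector.from_names(S=1, DM=0, FM=1, F4=0, DV=0, F=0)
        assert table.next_state(StateCode.from_bits("01101"), v).bits == "01110"

    def test_ambiguous_equal_specificity_raises(self, catalog):
        t = make_table(
            catalog,
            [
                ("00000", "1" + "X" * 15, "00001"),
                ("00000", "X0" + "X" * 14, "00010"),
            ],
        )
        with pytest.raises(ConsistencyError):
            t.next_state(StateCode(0), InputVector.from_names(S=1, DM=0))


# ----------------------------------------------------------------------
# validation and audit


class TestValidate:
    def test_shipped_fixture_clean(self, table):
        report = table.validate()
        assert report.conflicts == []
        assert len(report.priority_overlaps) == 2
        overlap_states = {a.current.bits for a, _ in report.priority_overlaps}
        assert overlap_states == {"00100", "01101"}

    def test_constructed_collision_reported(self, catalog):
        t = make_table(
            catalog,
            [("00000", "X" * 16, "00001"), ("00000", "X" * 16, "00010")],
        )
        report = t.validate()
        assert len(report.conflicts) == 1

    def test_draining_end_is_a_sink(self, table):
        report = table.validate()
        assert [s.bits for s in report.sinks] == ["01010"]

    def test_uncovered_fraction_standby(self, table):
        # 65,536 - (8,192 + 32,768 + 2,048 + 2,048) = 20,480 uncovered
        assert table.validate().uncovered_fraction["00000"] == pytest.approx(
            20480 / 65536
        )


class TestAudit:
    def test_shipped_fixture_no_mismatches(self, table):
        audit = table.audit_cases()
        assert audit.ok and audit.n_rows == 49

    def test_constructed_mismatch(self, catalog):
        t = make_table(catalog, [("00000", "1" * 13 + "XXX", "00001")])
        t.rows[0] = TransitionRow(
            current=t.rows[0].current,
            pattern=t.rows[0].pattern,
            next=t.rows[0].next,
            printed_cases=100,
        )
        audit = t.audit_cases()
        assert not audit.ok
        assert audit.mismatches[0][2] == 8  # computed 2^3


# ----------------------------------------------------------------------
# whole-table invariants


class TestInvariants:
    def test_totality_over_full_universe(self, table):
        nxt = table.next_state_array()
        assert nxt.size == 2_097_152
        assert int(nxt.max()) < 32

    def test_effective_cover_partitions_input_space(self, table):
        for state in table.current_states():
            cover = sum(c.coverage for c, _ in table.effective_cover(state))
            residue = sum(c.coverage for c in table.residue(state))
            assert cover + residue == 1 << 16

    def test_raw_rows_partition_where_no_overlap(self, table):
        overlapping = {"00100", "01101"}
        for state in table.current_states():
            if state.bits in overlapping:
                continue
            rows_cov = sum(coverage_count(r) for r in table.rows_for(state))
            residue = sum(c.coverage for c in table.residue(state))
            assert rows_cov + residue == 1 << 16

    def test_fault_absorbs_from_every_defined_state(self, table):
        nxt = table.next_state_array()
        vecs = np.arange(1 << 16, dtype=np.uint32)
        # S, DV, F are catalog columns 0, 14, 15
        mask = (1 << 15) | (1 << 1) | 1
        fault_vecs = vecs[(vecs & mask) == mask]
        assert fault_vecs.size == 1 << 13
        for value in list(range(17)) + [31]:
            block = nxt[(value << 16) + fault_vecs]
            assert (block == ALARM).all()

    def test_unused_codes_always_trap(self, table):
        nxt = table.next_state_array()
        for value in range(17, 31):
            assert (nxt[value << 16 : (value + 1) << 16] == ALARM).all()
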