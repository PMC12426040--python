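"""Discrete-time session simulation with synthetic sensor traces.

The simulator stands in for the physical machine: a small analog plant
model (heater, tank level, four flow lines, pressure, turbidity) produces
continuous values each clock tick, a sensor panel thresholds them into the
16 boolean input lines, and the transition table advances the state
register exactly once per tick.

Phase behaviour emulated here:

* **Heating** -- the solution warms toward the body-temperature setpoint
  while the machine sits in the heater-on state; the ``T`` line is the
  comparator ``temperature >= setpoint``.
* **Filling** -- the upper tank empties into the patient at the fill flow
  rate; the level line ``L`` drops once the tank passes the low mark,
  ending the fill.
* **Dwell and timed waits** -- the table marks several transitions "with
  delay" but no row holds those states, so during a countdown the
  supervisor releases the start gate (``S = 0``); no row matches, the
  hold completion keeps the state, and when the timer expires the
  successor row's own pattern is presented.  The dwell state uses the
  (much longer) dwell duration; the other delay states share one delay
  parameter.
* **Draining and loop stage** -- drained dialysate returns through flow
  line 4 while the tank refills; the loop-stage pumps (lines 1 and 3) stop
  once the tank is full, which is exactly the loop-stage exit pattern.
* **Flush** -- the tubing is rinsed at a controlled flow rate for at least
  the configured minimum duration each cycle; flow line 4 is held active
  until the minimum has elapsed, and its falling edge is the flush exit.
* **Turbidity termination** -- the drained fluid's turbidity decays by a
  fixed ratio each exchange; the ``TU`` line asserts only after the raw
  turbidity has been at or above threshold for a persistence window of
  consecutive ticks, so a momentary spike cannot force another cycle.
* **Faults** -- an active fault raises the danger-value and system-fault
  lines together (and keeps the start gate high) so the alarm rows match;
  the machine must reach ``11111`` on the next tick and return to standby
  one tick after the fault clears.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .catalog import ALARM, STANDBY, StateCode
from .patterns import InputVector
from .table import TransitionTable

__all__ = [
    "SimConfig",
    "AnalogState",
    "OperatorIntent",
    "FaultSpec",
    "SessionRecord",
    "SessionLog",
    "SessionTimeout",
    "InputGenerator",
    "generate_inputs",
    "run_session",
    "turbidity_cycles",
    "flush_metrics",
    "FlushInterval",
    "FlushReport",
    "SessionSimulator",
]

# State codes by role (values, to keep comparisons cheap)
_S_WINS = 0b00001
_S_HEAT_ON = 0b00011
_S_HEAT_OFF = 0b00100
_S_FILL = 0b00101
_S_FILL_END = 0b00110
_S_DWELL = 0b00111
_S_DRAIN = 0b01000
_S_V4F = 0b01001
_S_DRAIN_END = 0b01010
_S_LOOP = 0b01011
_S_V31F = 0b01100
_S_FLUSH = 0b01101
_S_V456F = 0b01110
_S_V31N = 0b01111
_S_V1F = 0b10000

#: States whose exit is timed rather than sensor-driven.
DELAY_STATES = frozenset({_S_FILL_END, _S_DWELL, _S_V4F, _S_V31F, _S_V456F})


class SimConfig(BaseModel):
    """Run configuration; defaults are the nominal study conditions."""

    temperature_setpoint: float = Field(37.0, gt=0, description="deg C")
    fill_volume: float = Field(1000.0, gt=0, description="ml per exchange")
    dwell_duration: float = Field(1800.0, gt=0, description="s in the dwell state")
    delay_duration: float = Field(5.0, gt=0, description="s for 'with delay' waits")
    flush_flow_rate: float = Field(200.0, gt=0, description="ml/min")
    flush_min_duration: float = Field(2.0, gt=0, description="min per flush cycle")
    turbidity_threshold: float = Field(10.0, gt=0, description="turbidity units")
    turbidity_initial: float = Field(50.0, ge=0, description="first drain, units")
    turbidity_persistence_window: int = Field(3, ge=1, description="ticks")
    turbidity_decay_ratio: float = Field(0.4, gt=0, lt=1, description="per cycle")
    tick_length: float = Field(1.0, gt=0, description="s per clock tick")
    random_seed: int = Field(0, ge=0)

    # plant parameters (benign defaults; the table only sees thresholds)
    ambient_temperature: float = Field(25.0, gt=0, description="deg C")
    heater_rate: float = Field(0.05, gt=0, description="deg C per s while heating")
    fill_flow_rate: float = Field(200.0, gt=0, description="ml/min into patient")
    drain_flow_rate: float = Field(200.0, gt=0, description="ml/min back to tank")
    level_mark: float = Field(50.0, gt=0, description="ml; L = level > mark")
    pressure_center: float = Field(100.0, gt=0, description="arbitrary units")
    pressure_band: float = Field(50.0, gt=0, description="half-width of safe band")
    max_cycles: int = Field(50, ge=1, description="cap for turbidity_cycles")
    tick_cap: int = Field(200_000, ge=1, description="simulation timeout")

    @model_validator(mode="after")
    def _check_marks(self) -> "SimConfig":
        if self.level_mark >= self.fill_volume:
            raise ValueError("level_mark must be below fill_volume")
        return self


@dataclass
class AnalogState:
    """Continuous plant values one tick's sensors read."""

    temperature: float
    level: float
    pressure: float
    flow1: float = 0.0
    flow2: float = 0.0
    flow3: float = 0.0
    flow4: float = 0.0
    turbidity: float = 0.0

    def __post_init__(self) -> None:
        if self.level < 0 or self.turbidity < 0:
            raise ValueError("level and turbidity must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {
            "temperature": round(self.temperature, 4),
            "level": round(self.level, 4),
            "pressure": round(self.pressure, 4),
            "flow1": round(self.flow1, 4),
            "flow2": round(self.flow2, 4),
            "flow3": round(self.flow3, 4),
            "flow4": round(self.flow4, 4),
            "turbidity": round(self.turbidity, 4),
        }


@dataclass(frozen=True)
class OperatorIntent:
    """Button settings the operator (or supervisor logic) holds this tick."""

    start: bool = True
    dialysis_mode: bool = True
    flush_mode: bool = False
    audible: bool = False
    pass_button: bool = True
    start_dialysis: bool = True


@dataclass(frozen=True)
class FaultSpec:
    """An injected fault, active from ``tick`` until ``cleared_at``."""

    tick: int
    kind: str = "sensor_fault"  # or "danger_value"
    cleared_at: int | None = None

    def __post_init__(self) -> None:
        if self.tick < 0:
            raise ValueError("fault tick must be nonnegative")
        if self.cleared_at is not None and self.cleared_at <= self.tick:
            raise ValueError("cleared_at must be after tick")
        if self.kind not in ("sensor_fault", "danger_value"):
            raise ValueError(f"unknown fault kind {self.kind!r}")

    def active(self, tick: int) -> bool:
        return tick >= self.tick and (self.cleared_at is None or tick < self.cleared_at)


class InputGenerator:
    """Thresholds analog values into the 16 boolean input lines.

    Stateful only in the turbidity persistence counter: ``TU`` goes high
    when the raw turbidity has been at or above threshold for at least the
    configured window of *consecutive* ticks.
    """

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        self._persistence = 0

    def generate(
        self,
        analog: AnalogState,
        state: StateCode,
        intent: OperatorIntent,
        fault_active: bool = False,
    ) -> InputVector:
        cfg = self.config
        if analog.turbidity >= cfg.turbidity_threshold:
            self._persistence += 1
        else:
            self._persistence = 0
        tu = int(self._persistence >= cfg.turbidity_persistence_window)
        pr = int(abs(analog.pressure - cfg.pressure_center) <= cfg.pressure_band)
        return InputVector.from_names(
            S=int(intent.start or fault_active),
            DM=int(intent.dialysis_mode),
            FM=int(intent.flush_mode),
            AI=int(intent.audible),
            P=int(intent.pass_button),
            T=int(analog.temperature >= cfg.temperature_setpoint),
            SD=int(intent.start_dialysis),
            F1=int(analog.flow1 > 0),
            F2=int(analog.flow2 > 0),
            F3=int(analog.flow3 > 0),
            F4=int(analog.flow4 > 0),
            L=int(analog.level > cfg.level_mark),
            PR=pr,
            TU=tu,
            DV=int(fault_active),
            F=int(fault_active),
        )


def generate_inputs(
    analog: AnalogState,
    config: SimConfig,
    state: StateCode,
    intent: OperatorIntent,
    fault_active: bool = False,
) -> InputVector:
    """One-shot thresholding (fresh persistence counter; see InputGenerator)."""
    return InputGenerator(config).generate(analog, state, intent, fault_active)


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SessionRecord:
    tick: int
    state: StateCode
    state_name: str
    inputs: InputVector
    analog: AnalogState

    def to_json_dict(self) -> dict:
        return {
            "tick": self.tick,
            "state_code": self.state.bits,
            "state_name": self.state_name,
            "inputs": self.inputs.as_dict(),
            "analog": self.analog.as_dict(),
        }


@dataclass
class SessionLog:
    """Tick-by-tick record of one simulated session."""

    records: list[SessionRecord] = field(default_factory=list)
    config: SimConfig | None = None
    mode: str = "dialysis"
    completed: bool = False

    @property
    def first_visit_codes(self) -> list[str]:
        seen: list[str] = []
        for rec in self.records:
            if rec.state.bits not in seen:
                seen.append(rec.state.bits)
        return seen

    @property
    def first_visit_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.state_name)
        return list(seen)

    @property
    def path_codes(self) -> list[str]:
        """First-visit order plus the terminal return to standby.

        A completed nominal dialysis session yields the 16-code canonical
        path 00000, 00001, 00011, ..., 10000, 00000.
        """
        path = self.first_visit_codes
        if self.completed and self.records and self.records[-1].state.value == STANDBY:
            path = path + [StateCode(STANDBY).bits]
        return path

    @property
    def cycle_count(self) -> int:
        """Entries into the filling state (one per exchange)."""
        count = 0
        prev = None
        for rec in self.records:
            if rec.state.value == _S_FILL and prev != _S_FILL:
                count += 1
            prev = rec.state.value
        return count

    def flush_volume_delivered(self, config: SimConfig | None = None) -> float:
        cfg = config or self.config
        if cfg is None:
            raise ValueError("a SimConfig is needed to compute flush volume")
        return sum(iv.volume_ml for iv in flush_metrics(self, cfg).intervals)

    def summary(self) -> dict:
        out = {
            "mode": self.mode,
            "ticks": len(self.records),
            "completed": self.completed,
            "first_visit_codes": self.first_visit_codes,
            "first_visit_names": self.first_visit_names,
            "path_codes": self.path_codes,
            "cycle_count": self.cycle_count,
            "alarm_ticks": sum(1 for r in self.records if r.state.value == ALARM),
        }
        if self.config is not None:
            out["flush_volume_ml"] = round(self.flush_volume_delivered(), 3)
        return out

    def replay(self, table: TransitionTable) -> bool:
        """Check every consecutive record pair against ``next_state``."""
        for a, b in zip(self.records, self.records[1:]):
            if b.tick <= a.tick:
                raise ValueError(f"ticks not strictly increasing at {a.tick}")
            expected = table.next_state(a.state, a.inputs)
            if expected != b.state:
                raise ValueError(
                    f"replay mismatch at tick {a.tick}: table gives "
                    f"{expected.bits}, log has {b.state.bits}"
                )
        return True

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_json_dict(), sort_keys=True) + "\n")

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


class SessionTimeout(RuntimeError):
    """The tick cap was reached before the session returned to standby."""

    def __init__(self, message: str, log: SessionLog) -> None:
        super().__init__(message)
        self.partial_log = log


# ----------------------------------------------------------------------


class SessionSimulator:
    """Drives the state machine through a dialysis or flush session."""

    def __init__(
        self,
        table: TransitionTable,
        config: SimConfig | None = None,
        faults: Sequence[FaultSpec] = (),
        mode: str = "dialysis",
    ) -> None:
        if mode not in ("dialysis", "flush"):
            raise ValueError("mode must be 'dialysis' or 'flush'")
        self.table = table
        self.config = config or SimConfig()
        self.faults = tuple(faults)
        self.mode = mode
        self.rng = np.random.default_rng(self.config.random_seed)

    # -- plant helpers -------------------------------------------------
    def _ticks(self, seconds: float) -> int:
        return max(1, round(seconds / self.config.tick_length))

    def _flow_per_tick(self, rate_ml_min: float) -> float:
        return rate_ml_min / 60.0 * self.config.tick_length

    def run(self) -> SessionLog:
        cfg = self.config
        table = self.table
        gen = InputGenerator(cfg)
        log = SessionLog(config=cfg, mode=self.mode)

        state = StateCode(STANDBY)
        temperature = cfg.ambient_temperature
        level = cfg.fill_volume
        turbidity = 0.0
        fills = 0
        wait_remaining = 0
        flush_elapsed = 0
        flush_ticks_required = self._ticks(cfg.flush_min_duration * 60.0)

        for tick in range(cfg.tick_cap):
            fault_active = any(f.active(tick) for f in self.faults)
            value = state.value

            # ---- plant dynamics for this tick -------------------------
            flows = [0.0, 0.0, 0.0, 0.0]
            if value == _S_HEAT_ON:
                temperature = min(
                    temperature + cfg.heater_rate * cfg.tick_length,
                    cfg.temperature_setpoint + 0.5,
                )
            else:
                temperature = max(
                    cfg.ambient_temperature,
                    temperature - 0.0005 * cfg.tick_length,
                )
            if value == _S_FILL:
                flows[1] = cfg.fill_flow_rate
                level = max(0.0, level - self._flow_per_tick(cfg.fill_flow_rate))
            elif value in (_S_DRAIN, _S_V4F):
                flows[3] = cfg.drain_flow_rate
                level = min(
                    cfg.fill_volume, level + self._flow_per_tick(cfg.drain_flow_rate)
                )
            elif value == _S_LOOP:
                if level < cfg.fill_volume:
                    flows[0] = flows[2] = cfg.drain_flow_rate
                    level = min(
                        cfg.fill_volume,
                        level + self._flow_per_tick(cfg.drain_flow_rate),
                    )
            elif value == _S_FLUSH:
                if flush_elapsed < flush_ticks_required:
                    flows[3] = cfg.flush_flow_rate
                flush_elapsed += 1
            pressure = cfg.pressure_center + float(
                self.rng.normal(0.0, cfg.pressure_band * 0.02)
            )
            analog = AnalogState(
                temperature=temperature,
                level=level,
                pressure=pressure,
                flow1=flows[0],
                flow2=flows[1],
                flow3=flows[2],
                flow4=flows[3],
                turbidity=turbidity,
            )

            # ---- supervisor intent ------------------------------------
            intent = self._intent_for(state, wait_remaining, level)

            inputs = gen.generate(analog, state, intent, fault_active)
            log.records.append(
                SessionRecord(
                    tick=tick,
                    state=state,
                    state_name=table.catalog.state_name(state),
                    inputs=inputs,
                    analog=analog,
                )
            )

            nxt = table.next_state(state, inputs)

            # ---- timers / cycle bookkeeping on state change -----------
            if nxt != state:
                if nxt.value in DELAY_STATES:
                    duration = (
                        cfg.dwell_duration
                        if nxt.value == _S_DWELL
                        else cfg.delay_duration
                    )
                    wait_remaining = self._ticks(duration)
                if nxt.value == _S_FILL:
                    fills += 1
                if nxt.value == _S_DRAIN:
                    # drained fluid of this exchange: decayed turbidity
                    turbidity = cfg.turbidity_initial * (
                        cfg.turbidity_decay_ratio ** fills
                    )
                if nxt.value == _S_FLUSH:
                    flush_elapsed = 0
            elif state.value in DELAY_STATES and wait_remaining > 0:
                wait_remaining -= 1
                # keep draining into the tank while valve-4 closes
                if state.value == _S_V4F and level < cfg.fill_volume:
                    wait_remaining = max(wait_remaining, 1)

            if nxt.value == STANDBY and tick > 0:
                log.records.append(
                    SessionRecord(
                        tick=tick + 1,
                        state=nxt,
                        state_name=table.catalog.state_name(nxt),
                        inputs=inputs,
                        analog=analog,
                    )
                )
                log.completed = True
                return log
            state = nxt

        raise SessionTimeout(
            f"session did not return to standby within {cfg.tick_cap} ticks",
            log,
        )

    # ------------------------------------------------------------------
    def _intent_for(
        self, state: StateCode, wait_remaining: int, level: float
    ) -> OperatorIntent:
        """Buttons the operator/supervisor presents in a given state.

        The mode lines behave as controller-driven signals outside standby:
        the flush stage requires the flush-mode pattern and the return leg
        requires the dialysis-mode pattern regardless of which button the
        operator pressed at the start.
        """
        value = state.value
        base = OperatorIntent(
            start=True,
            dialysis_mode=self.mode == "dialysis",
            flush_mode=self.mode == "flush",
            audible=False,
            pass_button=True,
            start_dialysis=True,
        )
        if value in DELAY_STATES and wait_remaining > 0:
            # countdown: release the start gate so no row matches (hold)
            return replace(base, start=False)
        if value in (_S_V31F, _S_FLUSH):
            return replace(base, dialysis_mode=False, flush_mode=True)
        if value in (_S_V456F, _S_V31N, _S_V1F):
            return replace(base, dialysis_mode=True, flush_mode=False)
        return base


def run_session(
    table: TransitionTable,
    config: SimConfig | None = None,
    faults: Sequence[FaultSpec] = (),
    mode: str = "dialysis",
) -> SessionLog:
    """Run one session; see :class:`SessionSimulator`."""
    return SessionSimulator(table, config, faults, mode).run()


# ----------------------------------------------------------------------


def turbidity_cycles(config: SimConfig) -> int:
    """Exchanges a session performs before the drainage runs clear.

    The drained turbidity after exchange *n* is
    ``turbidity_initial * turbidity_decay_ratio ** n``; the session stops
    at the first exchange whose drainage is below threshold, capped at
    ``max_cycles``.
    """
    for n in range(1, config.max_cycles + 1):
        drained = config.turbidity_initial * config.turbidity_decay_ratio ** n
        if drained < config.turbidity_threshold:
            return n
    return config.max_cycles


@dataclass(frozen=True)
class FlushInterval:
    start_tick: int
    end_tick: int  # inclusive
    duration_min: float
    volume_ml: float


@dataclass
class FlushReport:
    intervals: list[FlushInterval]

    @property
    def total_volume_ml(self) -> float:
        return sum(iv.volume_ml for iv in self.intervals)

    @property
    def min_duration_min(self) -> float | None:
        if not self.intervals:
            return None
        return min(iv.duration_min for iv in self.intervals)


def flush_metrics(log: SessionLog, config: SimConfig) -> FlushReport:
    """Duration and delivered volume of every flush-stage interval."""
    intervals: list[FlushInterval] = []
    start: int | None = None
    prev_tick = None
    for rec in [*log.records, None]:
        in_flush = rec is not None and rec.state.value == _S_FLUSH
        if in_flush and start is None:
            start = rec.tick
        elif not in_flush and start is not None:
            end = prev_tick
            n_ticks = end - start + 1
            duration_min = n_ticks * config.tick_length / 60.0
            intervals.append(
                FlushInterval(
                    start_tick=start,
                    end_tick=end,
                    duration_min=duration_min,
                    volume_ml=config.flush_flow_rate * duration_min,
                )
            )
            start = None
        if rec is not None:
            prev_tick = rec.tick
    return FlushReport(intervals=intervals)
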