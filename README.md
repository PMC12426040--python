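# pdfsm — a verifiable state-machine controller for automated peritoneal dialysis

Peritoneal dialysis (PD) machines cycle dialysate through fill, dwell and
drain phases using the patient's peritoneum as the filtration membrane. A
low-cost automated PD design with reusable tubing adds two stages to the
classic cycle: a **flush stage** that rinses the tubing at a controlled
flow rate before and after each session, and a **turbidity check** that
ends the session as soon as the drained fluid runs persistently clear
instead of after a fixed number of hours.

`pdfsm` implements that controller as a clocked Moore machine with a 5-bit
state register (flip-flops *A..E*, *A* most significant) and makes every
claim about it machine-checkable:

* **Transition-table engine** — the controller's behaviour is a table of
  ternary rows (current state, 16-symbol input pattern with don't-cares
  `X`, next state). `next_state` is a *total* function over all
  2<sup>5+16</sup> = 2,097,152 (state, input) pairs: unused register codes
  trap to the alarm state `11111`, the most specific matching row wins,
  and uncovered pairs follow a configurable completion policy (`hold` or
  `alarm`). Each row's "cases" annotation (the number of full input
  vectors it matches, 2<sup>#X</sup>) is audited automatically.
* **Excitation synthesis** — the five D flip-flop input equations
  `D_A .. D_E` are derived as sum-of-products expressions over the 21
  variables (*A..E*, `T_S .. T_F`) and proven equivalent to the table by
  exhaustive evaluation of all 2,097,152 assignments. An optional
  simplifier (adjacency merging + absorption) re-proves equivalence after
  every reduction.
* **Session simulator** — a discrete-time plant model (heater, tank level,
  four flow lines, pressure, turbidity with per-exchange decay) is
  thresholded into the 16 boolean inputs each clock tick, driving full
  dialysis or flush sessions with fault injection and replay-validated
  JSON-Lines logs.
* **Safety verifier** — exhaustive one-step properties (any fault with the
  start gate high forces the alarm state; the 14 unused codes always trap;
  clearing a fault returns the alarm to standby) plus reachability
  analysis on the row graph with a brute-force cross-check.

The 16 inputs are operator buttons (start `S`, dialysis mode `DM`, flush
mode `FM`, audible instructions `AI`, pass `P`, start dialysis `SD`) and
thresholded sensors (temperature `T`, flows `F1..F4`, level `L`, pressure
`PR`, turbidity `TU`, danger value `DV`, system fault `F`). The 18 named
states occupy codes `00000`..`10000` plus the alarm at `11111`. The
canonical transition table (49 rows) and signal catalog ship as package
fixtures under `src/pdfsm/data/`.

## Worked example

Verify the shipped table, synthesize and prove one excitation function,
and simulate a session:

```sh
$ pdfsm --output-dir out validate
49 rows, 0 conflicts, 0 case mismatches
sink states (no fault-free exit): 01010

$ pdfsm --output-dir out synthesize --flipflops D_A,D_E --simplify
D_A: PASS over 2097152 assignments (16 terms)
D_E: PASS over 2097152 assignments (47 terms)

$ pdfsm --output-dir out simulate
dialysis session: 5299 ticks, 2 exchange cycle(s), path 00000 -> 00001 ->
00011 -> 00100 -> 00101 -> 00110 -> 00111 -> 01000 -> 01001 -> 01011 ->
01100 -> 01101 -> 01110 -> 01111 -> 10000 -> 00000
INFO pdfsm: flush interval ticks 2629-2749: 2.02 min, 403.3 ml
INFO pdfsm: flush interval ticks 5169-5289: 2.02 min, 403.3 ml

$ pdfsm --output-dir out verify
totality                     holds  universe=2097152
fault_to_alarm               holds  universe=147456
fault_to_alarm_unguarded     FAILS  universe=294912
alarm_recovery               holds  universe=8192
unused_code_trap             holds  universe=917504
reachable from standby: 18 states (...)
overall: PASS
```

Reading the output: validation confirms the 49 transcribed rows are
deterministic (after specificity resolution) and that every printed case
count equals 2<sup>#X</sup>; the draining-end state `01010` is flagged as
a sink because the table gives it no fault-free exit. The simulated
session walks the 16-code canonical path once per exchange — with the
default turbidity settings (first drain at 50 units decaying by 0.4 per
exchange against a threshold of 10) the drainage runs clear after two
exchanges — and each flush interval lasts at least the required 2 minutes
at 200 ml/min (≈ 403 ml delivered). The verifier's `fault_to_alarm`
property is guarded by `S = 1` exactly as the table states it; the
stricter unguarded variant is reported for information and does **not**
hold, because no alarm row matches while the start button is off.

The same operations are available as a library:

```python
from pdfsm import load_shipped_table, synthesize_sop, equivalent, SimConfig, run_session

table = load_shipped_table()
report = equivalent(synthesize_sop(table, "D_C"), table, "D_C")
print(report.summary())          # D_C: PASS over 2097152 assignments
log = run_session(table, SimConfig())
print(log.summary()["path_codes"])
```

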