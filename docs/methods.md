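# Methods

## The controller model

The controller is a synchronous (clocked) Moore machine. Its state lives
in five D flip-flops *A..E* (*A* most significant), giving 32 register
codes of which 18 are meaningful: `00000` (standby) through `10000`
(valve-1-off, the last step before the turbidity decision) in binary
order, plus the error alarm at `11111`. The codes `10001`..`11110` are
deliberately unused. Sixteen boolean inputs — six operator buttons and ten
thresholded sensor lines — are sampled once per clock tick, and exactly
one transition fires per tick.

Behaviour is specified as a table of ternary rows: a current state, a
16-symbol pattern over `{0, 1, X}` (with `X` = don't-care), and a next
state. A row *matches* a (state, input) pair when the state equals the
row's current state and every specified symbol equals the corresponding
input bit; it *covers* `2^(#X)` of the 65,536 input vectors, which is the
number its "cases" column records.

### Total next-state semantics

`next_state` is total over all 2^21 = 2,097,152 (state, input) pairs:

1. **Unused-code trap.** Any register value in 17..30 steps to `11111`
   regardless of inputs. This is structural — a corrupted register must
   fail safe — and holds even for a table that omits the explicit
   unused-code rows.
2. **Specificity priority.** Among matching rows with different targets,
   the row with the fewest don't-cares wins. The canonical table needs
   this in exactly two places: the heater-off "stay" row (start-dialysis
   line unspecified) is overridden by the go-to-filling row when
   `SD = 1`, and the flush "stay" row (flow-4 unspecified) is overridden
   by the exit row when `F4 = 0`. In both, the exit pattern is a strict
   subset of the stay pattern, so the stay rows act as defaults — the
   natural reading of a transition table with self-loops. `validate`
   therefore reports as *conflicts* only genuine ambiguities (intersecting
   patterns, different targets, neither a strict subset of the other, or
   bit-identical patterns), and surfaces strict-subset pairs separately as
   *priority overlaps*. Equal-specificity ambiguity at evaluation time
   raises an internal-consistency error rather than guessing.
3. **Completion policy.** Pairs no row covers (for example standby with
   the start button held while a fault line is high but the other is not)
   fall to a configurable policy: `hold` (default — remain in the current
   state, consistent with the table's pervasive self-loops) or `alarm`
   (escalate to `11111`, the conservative choice). The policy is a
   visible safety trade-off, not a hidden patch: validation reports each
   state's uncovered-input fraction.

The draining-end state `01010` has no fault-free outgoing row. It is kept
verbatim and reported by `validate` as a *sink*; under `hold` completion
a machine that entered it would wait there until a fault or power-down.
Nominal simulations never enter it (flow line 4 stays active during the
drain), and entry would be visible in any session log.

## Excitation synthesis and the equivalence oracle

Each flip-flop's excitation function maps the 21 variables (5 state bits,
16 input transitions `T_S..T_F`) to one bit of the next state. Synthesis
walks every register code and emits product terms from the *effective*
(priority-resolved, mutually disjoint) row cover: rows are processed most
specific first, each later row keeping only the cube fragments not claimed
by an earlier one (cube subtraction by peeling). Completion residues
contribute terms wherever the completion target has the bit set — under
`hold`, a state with its own bit high keeps it on its uncovered inputs;
under `alarm`, every residue raises every bit — and each unused register
code contributes one all-don't-care trap term. Synthesising from the
covered rows only (no completion terms) is possible by setting the
`alarm` policy on an otherwise-hold table, and the two variants differ
exactly on the residues; the shipped expressions are synthesised from the
completed table so that equivalence is total.

The equivalence check is exhaustive by design: the expression and the
table's next-state bit are both evaluated on all 2,097,152 assignments
(vectorised bitwise evaluation, ~1 s per flip-flop on one core) and any
disagreement is reported with up to 100 counterexample (state, input)
pairs. No BDD/SAT shortcut stands between the claim and the check.
Simplification — iterated single-variable adjacency merges and absorption
— re-runs the same exhaustive comparison on its own output and refuses to
return an expression whose on-set changed. The transition table is the
single source of truth: the excitation equations are always derived from
it and proven against it, never transcribed from hand-written algebra
(transcription is error-prone; exhaustive equivalence is not), and
equivalence-to-table is the correctness criterion.

## Session simulation

The simulator stands in for the physical two-tank machine. Each tick it
(1) advances a small analog plant model, (2) thresholds the analog values
into the input lines, (3) logs (tick, state, inputs, analog snapshot), and
(4) steps the table. Logs are replayed against `next_state` before being
written, so a published log is by construction a witness trace.

Plant and threshold semantics:

* **Temperature** ramps at `heater_rate` (default 0.05 °C/s) toward
  `temperature_setpoint + 0.5` while the heater state is active, and
  decays negligibly otherwise; `T = temperature >= setpoint` (inclusive).
  Default setpoint 37 °C (body temperature).
* **Level** models the upper tank: filling empties it into the patient at
  `fill_flow_rate` (default 200 ml/min) from `fill_volume` (default
  1000 ml, the tank size); draining and the loop stage refill it at
  `drain_flow_rate`. `L = level > level_mark` (default 50 ml), so the
  fill ends when the tank is nearly empty and the loop stage completes
  when it is full again.
* **Flows** `F1..F4` are simply "corresponding line active"; the
  supervisor drives them per phase (fill uses line 2, drain and flush use
  line 4, the loop stage uses lines 1 and 3).
* **Pressure** is the band centre plus small seeded Gaussian noise;
  `PR = |pressure - centre| <= band`.
* **Turbidity** of the drained fluid after exchange *n* is
  `turbidity_initial * turbidity_decay_ratio^n` (defaults 50 units,
  0.4/exchange, threshold 10 units — two exchanges per default session).
  `TU` asserts only after the raw value has been at or above threshold
  for `turbidity_persistence_window` consecutive ticks (default 3), so a
  momentary spike cannot force an extra exchange and a momentary dip
  cannot end a dirty session. `turbidity_cycles(config)` gives the
  closed-form exchange count, and a nominal run's filling-state entries
  must equal it. The threshold and units are configuration values, not
  clinical claims.
* **Timed waits.** The table marks five transitions "with delay"
  (filling-end, dwell, valve-4-off, valves-3/1-off, valves-4/5/6-off) but
  holds none of those states with a self-loop row. During a countdown the
  supervisor releases the start gate (`S = 0`): no row matches, the
  `hold` completion keeps the state, and when the timer expires the
  successor row's pattern is presented. (Masking any single button would
  not work uniformly — one delay state's exit row specifies nothing but
  `S`, `DV`, `F`.) The dwell state uses `dwell_duration` (default 1800 s;
  a real dwell is hours, compressible via `tick_length`), the others
  share `delay_duration` (default 5 s). The valve-4-off wait additionally
  extends until the tank has refilled.
* **Flush** holds flow line 4 active for `flush_min_duration` (default
  2 min) at `flush_flow_rate` (default 200 ml/min); the line's falling
  edge is the flush exit, so every interval lasts at least the minimum
  (the measured interval is one tick longer than the minimum because the
  exit fires on the tick after the flow stops). Delivered volume is
  rate x duration (~403 ml per interval under defaults).
* **Modes.** The flush-stage rows pattern-match `DM = 0, FM = 1` and the
  return leg requires `DM = 1, FM = 0`, regardless of which button the
  operator pressed at standby; the simulator treats the mode lines as
  controller-driven outside standby. The audible-instructions branch is
  taken only when the operator sets `AI` without `P`; nominal runs press
  pass.
* **Faults.** The table's alarm rows require `S = 1, DV = 1, F = 1`
  simultaneously, so an active `FaultSpec` raises the danger-value and
  system-fault lines together and keeps the start gate high (a system
  fault latch); the `kind` field records provenance only. The machine
  must reach `11111` on the next tick and returns to standby one tick
  after the fault clears. A fault that never clears leaves the machine in
  the alarm state until the tick cap, reported as a timeout carrying the
  partial log.

Identical configuration and seed produce bit-identical logs; the only
randomness is the pressure sensor noise, drawn from a generator seeded by
`random_seed`.

### What the synthetic traces do not show

The plant model is threshold-faithful, not physical: no thermal or
hydraulic dynamics beyond linear ramps, no solute kinetics (the turbidity
decay is a geometric stand-in, and turbidity itself is an imperfect proxy
for clearance of large solutes), no sensor drift or redundancy
disagreement, and operator behaviour limited to held button settings.
Passing simulation tests therefore demonstrates that the *controller*
responds correctly to threshold crossings, delays and faults — not that a
physical machine built to this design would meet clinical targets.

## Verification

All safety properties are one-step and checked by enumeration against the
totalised next-state array: fault-to-alarm over the 18 defined states x
2^13 vectors with `S = DV = F = 1` (147,456 pairs); the unused-code trap
over 14 codes x 65,536 vectors (917,504); alarm recovery over the 8,192
vectors matching the recovery pattern; totality over the full 2,097,152.
The *unguarded* fault variant (alarm regardless of the start gate) is
computed and reported separately; it does not hold on the canonical table
— with `S = 0` the standby self-loop or the hold completion wins — and is
deliberately excluded from the overall verdict, since the table never
promises it. Reachability runs on the row graph using effective (not raw)
row coverage, so fully shadowed rows contribute no edges; a vector-level
exhaustive closure serves as the independent cross-check. From standby,
exactly the 18 defined states are reachable and no unused code is.

## Problem sizes and runtimes

All computations are desk-scale by construction: the enumeration universe
is 2^21, synthesis produces 16-103 terms per flip-flop (42-103 before
simplification), and a default nominal session is ~5,300 ticks (two
exchanges with a 30-minute dwell at 1-second ticks). The full test suite
runs in well under a minute; the acceptance script in a few seconds.

## Known limitations

* The priority (most-specific-wins) semantics is this package's
  resolution of the two overlapping stay/exit row pairs in the canonical
  table; a controller that instead treats overlap as nondeterminism or
  as an error would need the table itself amended.
* The completion policy for uncovered pairs, the delay durations, the
  turbidity threshold/decay and the pressure band are configuration, not
  sourced constants; defaults are chosen to be physically plausible and
  are stated above.
* The draining-end sink and the unreachability of the alarm while the
  start button is off are properties of the table, faithfully preserved
  and surfaced by the tooling rather than repaired.
* No temporal-logic model checking: properties are one-step or
  reachability-based. No HDL export, electrical modelling, or GUI.
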