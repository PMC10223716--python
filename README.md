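# cstrtwin

A desk-scale digital twin of an automated continuous-manufacturing line for
aryl sulfonyl chlorides, together with the design computations that size and
tune it.  The plant is two heated continuous stirred-tank reactors (CSTRs)
in series — chlorosulfonic acid chemistry at reflux — feeding a stirred
quench/isolation vessel, with peristaltic pumps driven over 0–10 V and
gravimetric balances under the feed stock and both reactors.  Because the
process stream corrodes ordinary flow sensors, *everything* the control
system knows comes from those balances: a loss-in-weight estimator
differentiates the quantized feed-balance stream, and three PI(D) loops hold
the feed flowrate and both reactor fill masses while a supervisor state
machine sequences startup, a batch hold, steady state, and a drain-down
shutdown.

The package is aimed at process-development and control engineers who want
to rehearse, tune, or regression-test this class of gravimetric control
stack without touching corrosive chemistry.

## What it computes

**Reactor sizing.** With excess chlorosulfonic acid the aryl substrate
disappears pseudo-first order: batch fraction remaining `exp(-k t)`; for *n*
equal CSTRs with per-tank residence time τ, `(1 + k τ)^-n`.  A 99%
conversion in 60 min fixes `k ≈ 0.077 min⁻¹`, and two tanks at τ = 60 min
then deliver 97% conversion (nearest percent) — the design point behind the
twin's two 150 mL reactors.

**Batch response surfaces.** The batch screen is a rotatable two-factor
central composite design in temperature (A: 130/140/150 °C) and ClSO₃H
equivalents (B: 5/7.5/10).  Coded-unit OLS models with p-value term
elimination describe product LCAP R1 (cubic), starting-material LCAP R2
(quadratic) and the sulfonic-acid impurity via 1/R3 (quadratic); the
published coefficients ship as fixtures, e.g.

    R1 = 58.02 + 14.24·A + 8.13·B − 3.64·AB + 2.84·A² − 4.55·B²
         − 7.92·A²B − 0.7728·AB²

Derringer–Suich desirability (maximize R1, minimize R2, keep R3 in range,
geometric mean) finds the operating region; at the selected solution
(155.1 °C, 7.3 eq) the models predict 87.2 / 1.0 / 16.4 LCAP.

**The twin and its control stack.** Explicit-Euler plant stepping (1 s) with
exact mass ledgers, 0.1 g / 20 Hz balance emulation, pump miscalibration and
tubing-degradation drift, scripted disturbances (tare shifts, stalls, heater
faults), and the full supervisor + estimator + PID stack.  Four campaign
scenario fixtures reproduce the behaviours that motivated automation: a
well-behaved small run, a grossly miscalibrated drifting manual run, a
miscalibrated PTFE manual run, and the automated PID run.

## Worked example

```bash
python examples/run_automated_campaign.py
```

prints (abridged):

```
supervisor transitions:
  t=      0 s  FILL_CSTR1   (user start)
  t=   1172 s  FILL_CSTR2   (WS-2 reached target)
  t=   2332 s  TOPOFF_CSTR1 (WS-3 reached target)
  t=   2474 s  BATCH_HOLD   (WS-2 topped off)
  t=   9674 s  STEADY       (hold elapsed)
  t=  39600 s  SHUTDOWN     (user shutdown)

PID run:    CSTR-1  150.0 +/-  0.0 mL, CSTR-2  150.0 +/-  0.1 mL
            feed 2.517 mL/min (target 2.5, R^2 = 1.0000); spacetime yield 0.170 g/mL/h
manual run: CSTR-1  143.7 +/-  3.6 mL, CSTR-2  118.9 +/- 18.0 mL, feed 2.400 mL/min
```

Reading: under feedback both reactors sit on the 150 mL target (residence
time held at an hour per tank) and the feed tracks its 2.5 mL/min setpoint;
the identical plant run open-loop drifts off target because small pump
miscalibrations go uncorrected.  The other examples cover reactor sizing,
the response-surface/desirability workflow, and the loss-in-weight
estimator in isolation.

The same capabilities are exposed on the command line:

```bash
cstrtwin size-cstr --k 0.077 --tau 60 --n 2
cstrtwin make-scenario --run 4 --seed 7 --out run4.toml
cstrtwin simulate --run 4 --seed 7 --out run4.csv
cstrtwin metrics --telemetry run4.csv
cstrtwin optimize
```

## Layout

- `src/cstrtwin/kinetics.py` — batch / tanks-in-series design equations
- `src/cstrtwin/plant.py` — the plant twin (tanks, pumps, balances, faults)
- `src/cstrtwin/control.py` — estimator, PID, supervisor, closed loop
- `src/cstrtwin/doe.py` — CCD, response-surface fitting, desirability
- `src/cstrtwin/scenarios.py` — campaign fixtures and run metrics
- `src/cstrtwin/config.py`, `telemetry.py`, `cli.py` — TOML configs,
  telemetry CSV round-trip, command line
- `docs/methods.md` — modelling assumptions, tuning, limitations
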