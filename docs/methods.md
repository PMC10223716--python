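# Methods

## Scope and model of the plant

The twin reproduces a laboratory continuous chlorosulfonation train:
feed stock → P-1 → CSTR-1 → P-2 → CSTR-2 → P-3 → ISO-CSTR (stirred
quench/isolation) → P-4/P-5 → filter, with balances WS-1 (feed stock),
WS-2 (CSTR-1) and WS-3 (CSTR-2).  It is a *control-fidelity* model: it is
faithful to what the automation stack can observe (quantized balance
masses, pump commands and reported RPM) and deliberately coarse everywhere
else.

Per vessel the state is total mass (primary; volume = mass/density), the
mass of reactive solute on a starting-material basis, and the composition
of that solute (starting material / sulfonyl-chloride product /
sulfonic-acid impurity, fractions summing to ≤ 1).  Transfers move mass and
solute proportionally from a perfectly stirred source; compositions blend
solute-weighted.  Each transfer is computed once and debited/credited on
both sides with cumulative per-pump ledgers, so global mass balance closes
to float round-off by construction (tests assert ≤ 1e−6 of throughput).

**Reaction.** Pseudo-first-order disappearance of the starting material
(`k = 0.077 min⁻¹` by default, per-scenario) converted in place to product,
switched on only at or above a temperature threshold (default 150 °C).
Heat transfer is instantaneous — stirred small vessels in oil baths — so
temperature is configuration, not state.  No Arrhenius dependence is
modelled because the kinetics were characterized at reflux only.  An
optional two-step channel (starting material → sulfonic acid → product) is
provided but off by default; no rate for the second step was ever
characterized, so enabling it requires the user to supply one.  Within a
step the decay uses the exact exponential factor; everything else is
explicit Euler.

**Integration.** Explicit Euler at `dt = 1 s` (configurable).  Residence
times are of order 3600 s, so the stiffness ratio is ~10⁻⁴ and the
discretization error on the steady-state composition is ≲ 0.1% (the
single-CSTR test checks the analytic limit `inlet/(1 + kV/q)` at 0.1%).

**Pumps.** Delivered flow = command(V) × gain × calibration_error ×
drift(t), clipped to [0, max_flow]; drift declines linearly with operating
hours to emulate tubing degradation.  Reported RPM is proportional to the
command only — the pump display knows nothing of calibration or wear,
which is precisely why gravimetric feedback is required.  P-3's full scale
maps to 4 mL/min, encoding the hardware rule that the largest possible
command is still a safe flow into the exothermic quench.  Optional
zero-mean pulsation noise on delivered flow is off by default.

**Balances.** Readings are `round(mass + tare, 0.1 g)` at 20 Hz; tare
shifts are scripted scenario events (equipment disturbances), not errors.
Quantization error is bounded by half a quantum, which the property tests
assert.

**Faults.** Overfill (volume > capacity) and dry-run (commanded withdrawal
from an empty vessel) raise distinct named faults in strict mode.  A
"clamp" mode instead delivers what is physically there — a peristaltic
pump on an emptying flask just moves less and then air.  The manual-mode
campaign fixtures use clamp because those historical runs really did run
pumps against drifting inventories; the automated fixture keeps strict
faults since its supervisor is supposed to prevent both conditions.

**Not modelled** (out of scope by design): precipitation/nucleation and
filtration physics (the ISO-CSTR is mixing plus duty-cycled outflow),
gas evolution, thermal dynamics beyond the on/off threshold, and hardware
I/O layers.

## Control stack

**Loss-in-weight estimator.**  Differentiating a 0.1 g-quantized stream
message-by-message yields zeros punctuated by spikes, so the estimator
(i) rate-limits input to 3 msg/s, (ii) passes only *changed* masses,
(iii) fills a five-message window and differences its first and fifth
entries, dividing by density (a declining feed bottle reads as positive
delivery).  At very low pump speed changes become rare, so an RPM-based
estimate (nominal rpm-to-flow constant × reported RPM) substitutes, but is
admitted only below 1 mL/min.  At the nominal operating point each window
spans ≥ 4 quanta over ~5.5 s, so per-estimate error is set by the ±1/3 s
message-grid jitter of the window endpoints (~6%), and the time average is
accurate to a few tenths of a percent.  This quantization floor is an
honest property of the scheme: the closed loop regulates delivered flow to
within ~0.5% of setpoint with the real 0.1 g balance, and to three
significant figures when quantization is made negligible.  Tests assert
both regimes separately.

**PID loops.**  Positional PID on the *normalized* error (divided by the
setpoint), so one set of gains transfers across 50 mL and 500 mL
scenarios.  Outputs are fractions of full scale in [0, 1], mapped linearly
to 0–10 V; a bias equal to the nominal steady command gives bumpless entry
into closed loop.  Anti-windup is conditional integration: while the
output is clamped, integration is suspended unless the error drives the
output back inside the limits.  Loop 1 (feed flow → P-1) is updated
event-driven, whenever the estimator emits — the behaviour of the original
dashboard controller node.  Loops 2 and 3 (vessel mass → P-2/P-3) are
reverse acting (heavy vessel ⇒ pump out faster) and run at 1 Hz, only
during steady state; during startup and shutdown the supervisor's constant
commands rule.

**Gains.**  The historical controllers' gains were tuned empirically and
never reported, and were essentially PI.  Defaults here: kp = 0.6,
ki = 0.05 s⁻¹, kd = 0 on the level loops.  The flow loop needs softer
action: the pump responds instantly, so the per-update proportional loop
gain is kp × (pump span)/(setpoint) ≈ kp × 4 at the nominal point, and
kp = 0.6 would give a gain-2.4 oscillator against the ~3 s estimator
delay.  The scenario configs therefore set loop 1 to kp = 0.1,
ki = 0.01 s⁻¹ (loop gain 0.4, well damped).  All gains are per-loop
config; the gain-scan used for this tuning is reproducible by editing
`[control]` in a scenario TOML.

**Supervisor.**  Phases IDLE → FILL_CSTR1 → FILL_CSTR2 → TOPOFF_CSTR1 →
BATCH_HOLD → STEADY → SHUTDOWN → DONE, with shutdown reachable from any
running phase on user command.  Startup mimics a batch run: P-1 fast-fills
CSTR-1 (default 80% of range — "rapid" was never quantified); when WS-2
reaches target P-1 backs off by exactly 10% (overfill protection against
unequal pump performance) and P-2 fast-fills CSTR-2 from CSTR-1; when WS-3
reaches target P-2 stops and P-1 tops CSTR-1 off; both full, everything
holds for 2 h (configurable) before the PID loops engage.  Shutdown drains
both reactors into the quench at the steady setpoint flow until the
balances read empty (default threshold 1 g, with a 0.5 g hysteresis band
against quantization chatter).  Whether the feed loop should keep running
open-loop during the batch-hold top-off was ambiguous; here P-1 is simply
off during the hold, and the constant P-2/P-3 startup/shutdown outputs are
config keys.

**ISO-CSTR outlet.**  The isolation vessel's outlet pump is duty-cycled:
bursts at `target/duty` for a `duty` fraction of each period, giving an
exact time-averaged outflow (checked by numeric integration) while staying
compatible with intermittent filtration.  Defaults: duty 0.25, period
600 s, average matched to the feed setpoint.

## Campaign scenario fixtures

`make_scenario(1..4)` encodes the four historical runs (feed setpoint /
CSTR target / control mode): 0.5 mL/min / 30 mL / manual;
2.5 / 150 / manual with a 0.60 feed-pump calibration factor, 4%/h tubing
drift on P-2/P-3 and scripted tare shifts; 0.67 / 40 / manual with PTFE
head miscalibrations (0.863 / 1.10 / 1.20); and 2.5 / 150 / PID with small
(±4%) miscalibrations.  The manual calibration factors were chosen once to
reproduce the runs' reported actual-vs-target feed flows (0.502, 1.499,
0.578 mL/min) and are fixed properties of the fixtures, not seed-driven.
Volumes in the metrics are balance masses divided by the stream density —
the same reduction used on the real data — so the scripted tare shifts
corrupt the recorded volumes exactly the way moved equipment corrupted the
originals.  Reported per-run standard deviations of the historical record
are single noise realizations; the tests therefore assert qualitative
structure (PID beats manual on both bias and spread on matched seeds;
drifting manual runs under-deliver feed by > 10%) rather than those
numbers.

Run 4's anecdotal equipment failures (a melted fitting, a hotplate error)
are not part of the default fixture — the fixture represents nominal
automated operation — but the event schema (tare shift, pump stall, heater
fault) can script them.

**Unreported physical parameters** are config defaults, chosen once:
densities 1.75 g/mL for the ClSO₃H-rich stream and 1.0 for aqueous quench
make-up (1.1 for the mixed isolation fluid); 50/500 mL nominal flask
capacities with overfill at nominal volume; feed-stock solute (starting
material) mass fraction 0.17 and product/starting-material mass ratio 1.5
for product accounting (chlorosulfonation adds ~98.5 g/mol to a
confidential substrate; 1.5 is a round representative value).  Spacetime
yield divides recovered product mass by run duration × combined heated
reactor volume; the paper-arithmetic path (supplied product mass) is exact,
while the simulation path depends on the two accounting ratios above and
is therefore indicative, not predictive.

## Response-surface module

Factor coding follows the screen's nominal design: A = (T − 140)/10,
B = (eq − 7.5)/2.5.  The *executed* 11-run list is shipped as a fixture
and deviates from the textbook rotatable design: axial points at coded
±1.5 (A) and ±1.4 (B) rather than ±√2, and center replicates at 8 eq
(coded B = +0.2).  `build_rotatable_ccd` constructs the textbook design;
the fixture preserves the campaign as run.  Both are supported everywhere.

Fitting is OLS (statsmodels) on coded monomials up to the requested order
with backward elimination of terms at p ≥ 0.05, preserving hierarchy (a
term is not removable while a retained higher-order term contains it).
On a two-factor CCD the pure cubes are exactly aliased
(A³ = α²A + (1−α²)AB² on the design points), so candidate terms are
admitted mixed-monomials-first within each degree and aliased candidates
dropped before fitting — which is why a cubic fit returns the A²B/AB² form
and recovers noise-free synthetic coefficients exactly (tested to 1e−8).
Published model coefficients are shipped verbatim as fixtures, decoupling
prediction (and its tests) from refitting; the impurity model is quadratic
in 1/R3 and predictions invert the transform last.

Desirability uses Derringer–Suich linear ramps with weight 1 (the standard
choice; the original functional form was unstated), combined by weighted
geometric mean.  Anchors default to the min/max of the printed-model
predictions over the 11 executed conditions, since the raw batch responses
are not published; the impurity in-range anchors are overridable.  The
optimizer is a coarse grid scan over the coded design region
(A ∈ [−1.5, 1.5], B ∈ [−1.4, 1.4]) with Nelder–Mead polish from the best
cells — gradient-free because the surface is piecewise linear with
plateaus — and returns all ties.  The unit-desirability set is a plateau;
tests verify a desirability-1.0 solution exists, that the published
operating point lies on the same plateau, and that the optimizer is at
least as good as an exhaustive 201×201 grid oracle.

Two percent-rounding artifacts are surfaced rather than hidden: the
two-tank design conversion is exactly 96.83% (quoted as 97%), so
`conversion_percent` makes the rounding explicit and `solve_n` at an
un-rounded 0.97 target returns 3 tanks; and the three independently
modelled responses at the selected optimum sum to ~104.9 LCAP, an artifact
of per-response modelling, not a mass-balance statement.

## Numerical and testing choices

Telemetry CSVs carry a schema-version header; floats are written shortest-
repr and read back with exact round-trip parsing.  Closed-loop runs are
bit-deterministic per (config, seed); the only stochastic elements are
optional pump pulsation and synthetic response noise, both drawn from a
seeded generator.  The balance sub-stream feeding the estimator inside the
closed loop is sampled at the 3 Hz rate limit with linear mass
interpolation inside each 1 s plant step — equivalent to rate-limiting the
20 Hz stream, at a fifth of the cost.  Closed-loop tests run shortened
horizons (10 min hold, 4 h runs); the full 12 h automated campaign at
dt = 1 s runs once in the acceptance tests and takes a few seconds.

**What passing tests do and do not show.**  The synthetic plant has
linear, well-behaved pumps, ideal mixing, a composition-independent
density and no measurement dynamics beyond quantization and tare shifts.
Passing therefore demonstrates the *logic* of the control stack (sequencing,
estimator filtering, anti-windup, setpoint rejection of calibration error
and drift) and the arithmetic of the design computations — not chemical
accuracy of the impurity profile, precipitation behaviour, or performance
under unmodelled disturbances (pulsation spectra, thermal transients,
balance drift).  Known limitations, besides the out-of-scope physics:
the event-driven flow loop's ~0.5% quantization floor; product accounting
through two configurable ratios; and manual-mode fixtures that emulate
operator *absence* (constant commands) rather than the occasional manual
corrections of the historical runs.
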