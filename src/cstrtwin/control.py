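"""Automation stack: gravimetric flow estimator, PID loops, pump supervisor.

The plant is controlled from three balance streams alone:

* loop 1 holds the feed flowrate by differentiating the feed-stock balance
  (WS-1) and driving P-1;
* loops 2 and 3 hold the CSTR-1 / CSTR-2 fill masses (WS-2 / WS-3) by
  driving the downstream pumps P-2 / P-3 (reverse acting: a heavy vessel
  pumps out faster).

Differentiating a 0.1 g-quantized stream naively yields zeros punctuated by
spikes, so the estimator passes only *changed* masses into a five-message
buffer and differences the first and fifth entries; at very low pump speeds
(where changes become rare) an RPM-based estimate takes over, admitted only
below a threshold flow.  A supervisor state machine sequences startup
(fill CSTR-1, fill CSTR-2 while CSTR-1 keeps topping, batch hold) into
steady-state PID operation and a drain-down shutdown.

All controller outputs are fractions of full scale in [0, 1], mapped
linearly onto the pumps' 0-10 V command range.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ControlConfig, RunConfig, build_plant, build_reaction
from .plant import (
    DryRunFault,
    OverfillFault,
    PlantFault,
    PlantState,
    ScaleReading,
    iso_outlet_schedule,
    step_plant,
)

__all__ = [
    "PIDParams",
    "PID",
    "FlowEstimator",
    "Phase",
    "Supervisor",
    "supervisor_step",
    "SimulationResult",
    "run_closed_loop",
]


# ---------------------------------------------------------------------------
# PID
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PIDParams:
    """Positional-PID parameters on the normalized loop error.

    The error is divided by ``norm`` (defaults to |setpoint|, or 1 for a
    zero setpoint) so the same gains work across 50 mL and 500 mL vessels.
    ``bias`` is the output at zero error — the nominal steady command —
    giving bumpless entry into closed loop.  ``reverse`` flips the error
    sign for loops where a high measurement must raise the output.
    """

    setpoint: float
    kp: float = 0.6
    ki: float = 0.0  # 1/s
    kd: float = 0.0  # s
    output_min: float = 0.0
    output_max: float = 1.0
    bias: float = 0.0
    reverse: bool = False
    norm: float | None = None

    def __post_init__(self) -> None:
        if self.output_min >= self.output_max:
            raise ValueError("output_min must be < output_max")
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("gains must be non-negative")

    @property
    def error_scale(self) -> float:
        if self.norm is not None:
            return self.norm
        return abs(self.setpoint) if self.setpoint != 0 else 1.0


class PID:
    """Positional PID with output clamping and conditional anti-windup.

    Integration is suspended whenever the unclamped output lies outside the
    limits and the current error would push it further out.
    """

    def __init__(self, params: PIDParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.integral = 0.0
        self.last_error: float | None = None
        self.last_time: float | None = None
        self.last_output = min(
            max(self.params.bias, self.params.output_min), self.params.output_max
        )

    def update(self, measurement: float, now: float) -> float:
        p = self.params
        error = (p.setpoint - measurement) / p.error_scale
        if p.reverse:
            error = -error
        if self.last_time is None:
            dt = 0.0
        else:
            dt = now - self.last_time
            if dt < 0:
                raise ValueError("time must not run backwards between PID calls")
            if dt == 0.0:
                return self.last_output
        derivative = 0.0
        if dt > 0 and self.last_error is not None and p.kd > 0:
            derivative = (error - self.last_error) / dt
        candidate_integral = self.integral + error * dt
        raw = p.bias + p.kp * error + p.ki * candidate_integral + p.kd * derivative
        if raw > p.output_max:
            output = p.output_max
            if error < 0:  # error drives back inside: let integral unwind
                self.integral = candidate_integral
        elif raw < p.output_min:
            output = p.output_min
            if error > 0:
                self.integral = candidate_integral
        else:
            output = raw
            self.integral = candidate_integral
        self.last_error = error
        self.last_time = now
        self.last_output = output
        return output


# ---------------------------------------------------------------------------
# flowrate estimation from the quantized balance stream
# ---------------------------------------------------------------------------


class FlowEstimator:
    """Loss-in-weight flow estimate from a quantized balance stream.

    Incoming messages are rate-limited, then filtered to *changed* masses
    only; once five changed messages are buffered, the estimate is
    ``(m_first - m_last) / (t_last - t_first) / density`` in mL/min (a
    declining source reads as positive delivery), recomputed on every
    subsequent accepted change over the sliding five-message window.  When
    no buffered estimate is available on an update, an RPM-based estimate
    ``rpm_constant * reported_rpm`` is emitted instead, but only while it
    is below ``fallback_threshold`` (slow-pump regime).  Returns ``None``
    when there is nothing to emit.
    """

    BUFFER = 5

    def __init__(
        self,
        density_gml: float,
        rpm_constant_mlmin_per_rpm: float,
        rate_limit_hz: float = 3.0,
        fallback_threshold_mlmin: float = 1.0,
    ):
        if density_gml <= 0:
            raise ValueError("density must be positive")
        self.density = density_gml
        self.rpm_constant = rpm_constant_mlmin_per_rpm
        self.rate_limit_hz = rate_limit_hz
        self.fallback_threshold = fallback_threshold_mlmin
        self.buffer: list[ScaleReading] = []
        self.last_input_time: float | None = None
        self.last_mass: float | None = None
        self.last_estimate: float | None = None
        self.n_accepted = 0  # messages past the rate limiter (diagnostics)

    def update(
        self, reading: ScaleReading, reported_rpm: float | None = None
    ) -> float | None:
        if self.last_input_time is not None:
            if reading.time_s < self.last_input_time:
                raise ValueError("non-monotonic scale timestamps")
            if (reading.time_s - self.last_input_time) < 1.0 / self.rate_limit_hz - 1e-12:
                return None  # rate limited, message dropped
        self.last_input_time = reading.time_s
        self.n_accepted += 1

        emitted: float | None = None
        if self.last_mass is None or reading.mass_g != self.last_mass:
            self.last_mass = reading.mass_g
            self.buffer.append(reading)
            if len(self.buffer) > self.BUFFER:
                self.buffer.pop(0)
            if len(self.buffer) == self.BUFFER:
                first, last = self.buffer[0], self.buffer[-1]
                dt_s = last.time_s - first.time_s
                if dt_s > 0:
                    g_per_s = (first.mass_g - last.mass_g) / dt_s
                    emitted = g_per_s * 60.0 / self.density
                    self.last_estimate = emitted
        if emitted is None and reported_rpm is not None:
            rpm_est = self.rpm_constant * reported_rpm
            if rpm_est < self.fallback_threshold:
                emitted = rpm_est
        return emitted


# ---------------------------------------------------------------------------
# supervisor state machine
# ---------------------------------------------------------------------------


class Phase(enum.Enum):
    IDLE = "IDLE"
    FILL_CSTR1 = "FILL_CSTR1"
    FILL_CSTR2 = "FILL_CSTR2"
    TOPOFF_CSTR1 = "TOPOFF_CSTR1"
    BATCH_HOLD = "BATCH_HOLD"
    STEADY = "STEADY"
    SHUTDOWN = "SHUTDOWN"
    DONE = "DONE"


_RUNNING = {
    Phase.FILL_CSTR1,
    Phase.FILL_CSTR2,
    Phase.TOPOFF_CSTR1,
    Phase.BATCH_HOLD,
    Phase.STEADY,
}


@dataclass
class SupervisorTargets:
    """Mass targets and nominal commands the supervisor sequences against."""

    cstr1_target_g: float
    cstr2_target_g: float
    fastfill_fraction: float = 0.8
    #: nominal steady-state output fractions for P-1..P-3 (setpoint / span)
    steady_fractions: dict[str, float] = field(default_factory=dict)
    hold_duration_s: float = 7200.0
    hysteresis_g: float = 0.5
    empty_threshold_g: float = 1.0


@dataclass
class Supervisor:
    """Startup / steady-state / shutdown sequencing of P-1..P-3.

    ``step`` consumes the current balance readings and an optional user
    command (``"start"``, ``"stop"``, ``"shutdown"``) and returns the base
    output fractions for the three transfer pumps.  During STEADY the PID
    loops override these (``pid_active`` flags it); in every other phase
    the supervisor's constants rule, matching a control room where level
    loops are only closed at steady state.
    """

    targets: SupervisorTargets
    phase: Phase = Phase.IDLE
    phase_entry_time_s: float = 0.0
    _p1_fraction: float = 0.0
    _log: list[tuple[float, str, str]] = field(default_factory=list)

    @property
    def pid_active(self) -> bool:
        return self.phase is Phase.STEADY

    @property
    def transitions(self) -> list[tuple[float, str, str]]:
        """(time, phase, trigger) records of every transition taken."""
        return list(self._log)

    def _enter(self, phase: Phase, now: float, trigger: str) -> None:
        self.phase = phase
        self.phase_entry_time_s = now
        self._log.append((now, phase.value, trigger))

    def step(
        self,
        now: float,
        ws2_g: float,
        ws3_g: float,
        user_cmd: str | None = None,
    ) -> dict[str, float]:
        t = self.targets
        if user_cmd is not None:
            if user_cmd == "start" and self.phase is Phase.IDLE:
                self._p1_fraction = t.fastfill_fraction
                self._enter(Phase.FILL_CSTR1, now, "user start")
            elif user_cmd in ("shutdown", "stop") and self.phase in _RUNNING:
                self._enter(Phase.SHUTDOWN, now, f"user {user_cmd}")
            elif user_cmd not in ("start", "stop", "shutdown"):
                raise ValueError(f"unknown user command {user_cmd!r}")

        if self.phase is Phase.FILL_CSTR1:
            if ws2_g >= t.cstr1_target_g:
                self._p1_fraction *= 0.90  # back off to protect CSTR-1
                self._enter(Phase.FILL_CSTR2, now, "WS-2 reached target")
        elif self.phase is Phase.FILL_CSTR2:
            if ws3_g >= t.cstr2_target_g:
                self._enter(Phase.TOPOFF_CSTR1, now, "WS-3 reached target")
        elif self.phase is Phase.TOPOFF_CSTR1:
            if ws2_g >= t.cstr1_target_g:
                self._enter(Phase.BATCH_HOLD, now, "WS-2 topped off")
        elif self.phase is Phase.BATCH_HOLD:
            if now - self.phase_entry_time_s >= t.hold_duration_s:
                self._enter(Phase.STEADY, now, "hold elapsed")
        elif self.phase is Phase.SHUTDOWN:
            if (
                ws2_g <= t.empty_threshold_g + t.hysteresis_g
                and ws3_g <= t.empty_threshold_g + t.hysteresis_g
            ):
                self._enter(Phase.DONE, now, "both CSTRs drained")

        return self._commands(ws2_g, ws3_g)

    def _commands(self, ws2_g: float, ws3_g: float) -> dict[str, float]:
        t = self.targets
        sf = t.steady_fractions
        phase = self.phase
        if phase is Phase.FILL_CSTR1:
            return {"P1": self._p1_fraction, "P2": 0.0, "P3": 0.0}
        if phase is Phase.FILL_CSTR2:
            return {"P1": self._p1_fraction, "P2": t.fastfill_fraction, "P3": 0.0}
        if phase is Phase.TOPOFF_CSTR1:
            return {"P1": self._p1_fraction, "P2": 0.0, "P3": 0.0}
        if phase is Phase.BATCH_HOLD:
            return {"P1": 0.0, "P2": 0.0, "P3": 0.0}
        if phase is Phase.STEADY:
            return {
                "P1": sf.get("P1", 0.0),
                "P2": sf.get("P2", 0.0),
                "P3": sf.get("P3", 0.0),
            }
        if phase is Phase.SHUTDOWN:
            # drain both reactors into the quench at the steady setpoint
            p2 = sf.get("P2", 0.0) if ws2_g > t.empty_threshold_g else 0.0
            p3 = sf.get("P3", 0.0) if ws3_g > t.empty_threshold_g else 0.0
            return {"P1": 0.0, "P2": p2, "P3": p3}
        return {"P1": 0.0, "P2": 0.0, "P3": 0.0}


def supervisor_step(
    sup: Supervisor,
    now: float,
    ws2_g: float,
    ws3_g: float,
    user_cmd: str | None = None,
) -> tuple[Supervisor, dict[str, float]]:
    """Functional wrapper over :meth:`Supervisor.step`."""
    commands = sup.step(now, ws2_g, ws3_g, user_cmd)
    return sup, commands


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

TELEMETRY_COLUMNS = [
    "time_s",
    "state",
    "ws1_g",
    "ws2_g",
    "ws3_g",
    "p1_V",
    "p2_V",
    "p3_V",
    "p4_V",
    "p5_V",
    "p1_rpm",
    "p2_rpm",
    "p3_rpm",
    "p4_rpm",
    "p5_rpm",
    "est_flow_mLmin",
    "cstr1_vol_mL",
    "cstr2_vol_mL",
]


@dataclass
class SimulationResult:
    """Telemetry plus final plant state and product accounting for one run."""

    telemetry: pd.DataFrame
    final_state: PlantState
    config: RunConfig
    seed: int | None
    supervisor_log: list[tuple[float, str, str]]

    @property
    def product_mass_g(self) -> float:
        """Product mass recovered: filtered out plus ISO-CSTR holdup."""
        sc = self.config.scenario
        iso = self.final_state.tanks["iso"]
        solute = (
            self.final_state.collected_product_solute_g
            + iso.solute_g * iso.species.product
        )
        return solute * sc.product_to_sm_mass_ratio


def run_closed_loop(
    config: RunConfig,
    seed: int | None = None,
    out_csv=None,
) -> SimulationResult:
    """Simulate one full startup -> steady -> shutdown trajectory.

    Deterministic for a given config and seed.  Telemetry is logged once per
    ``log_every_s`` and optionally written to ``out_csv`` (see
    :mod:`cstrtwin.telemetry` for the schema).  Plant faults propagate with
    the supervisor phase attached for context.
    """
    sc = config.scenario
    ctl = config.control
    plant = build_plant(config)
    reaction = build_reaction(config)
    rng = np.random.default_rng(seed)

    cstr1 = config.tanks["cstr1"]
    cstr2 = config.tanks["cstr2"]
    target1_g = sc.target_volume_ml * cstr1.density_gml
    target2_g = sc.target_volume_ml * cstr2.density_gml

    steady_fractions = {
        name: min(
            1.0,
            sc.feed_setpoint_mlmin
            / (config.pumps[name].gain_mlmin_per_v * 10.0),
        )
        for name in ("P1", "P2", "P3")
    }
    sup = Supervisor(
        SupervisorTargets(
            cstr1_target_g=target1_g,
            cstr2_target_g=target2_g,
            fastfill_fraction=ctl.fastfill_fraction,
            steady_fractions=steady_fractions,
            hold_duration_s=ctl.hold_duration_s,
            hysteresis_g=ctl.hysteresis_g,
            empty_threshold_g=ctl.empty_threshold_g,
        )
    )

    feed_density = config.tanks["feed"].density_gml
    estimator = FlowEstimator(
        density_gml=feed_density,
        rpm_constant_mlmin_per_rpm=plant.pumps["P1"].nominal_rpm_constant,
        rate_limit_hz=ctl.rate_limit_hz,
        fallback_threshold_mlmin=ctl.fallback_mlmin,
    )
    pid1 = PID(
        PIDParams(
            setpoint=sc.feed_setpoint_mlmin,
            kp=ctl.loop1.kp,
            ki=ctl.loop1.ki,
            kd=ctl.loop1.kd,
            bias=steady_fractions["P1"],
        )
    )
    pid2 = PID(
        PIDParams(
            setpoint=target1_g,
            kp=ctl.loop2.kp,
            ki=ctl.loop2.ki,
            kd=ctl.loop2.kd,
            bias=steady_fractions["P2"],
            reverse=True,
        )
    )
    pid3 = PID(
        PIDParams(
            setpoint=target2_g,
            kp=ctl.loop3.kp,
            ki=ctl.loop3.ki,
            kd=ctl.loop3.kd,
            bias=steady_fractions["P3"],
            reverse=True,
        )
    )

    p4_profile = iso_outlet_schedule(
        sc.feed_setpoint_mlmin,
        sc.iso_outlet_duty,
        sc.iso_outlet_period_s,
        max_flow_mlmin=config.pumps["P4"].max_flow_mlmin,
    )

    dt = sc.dt_s
    n_sub = max(1, int(round(ctl.rate_limit_hz * dt)))
    log_stride = max(1, int(round(sc.log_every_s / dt)))
    stalls: dict[str, float] = {}  # pump -> stall end time
    heater: dict[str, tuple[float, float]] = {}  # tank -> (end time, original T)
    pending = sorted(sc.events, key=lambda e: e.time_s)
    rows: list[tuple] = []
    u1 = steady_fractions["P1"]
    est_flow = float("nan")
    prev_feed_mass = plant.tanks["feed"].mass_g
    started_shutdown = False
    step_index = 0

    while plant.time_s < sc.duration_s and sup.phase is not Phase.DONE:
        now = plant.time_s

        while pending and pending[0].time_s <= now:
            ev = pending.pop(0)
            if ev.kind == "tare_shift":
                plant.scales[ev.target].tare_g += ev.delta_g
            elif ev.kind == "pump_stall":
                stalls[ev.target] = ev.time_s + ev.duration_s
            elif ev.kind == "heater_fault":
                tank = plant.tanks[ev.target]
                heater[ev.target] = (ev.time_s + ev.duration_s, tank.temperature_c)
                tank.temperature_c = 25.0
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
        for name, (end, original) in list(heater.items()):
            if now >= end:
                plant.tanks[name].temperature_c = original
                del heater[name]

        ws1 = plant.scales["WS1"].quantize(plant.tanks["feed"].mass_g)
        ws2 = plant.scales["WS2"].quantize(plant.tanks["cstr1"].mass_g)
        ws3 = plant.scales["WS3"].quantize(plant.tanks["cstr2"].mass_g)

        cmd = None
        if now == 0.0:
            cmd = "start"
        elif (
            sc.shutdown_at_s is not None
            and not started_shutdown
            and now >= sc.shutdown_at_s
        ):
            cmd = "shutdown"
            started_shutdown = True
        fractions = sup.step(now, ws2, ws3, cmd)

        if sup.pid_active and ctl.mode == "pid":
            fractions["P1"] = u1
            fractions["P2"] = pid2.update(ws2, now)
            fractions["P3"] = pid3.update(ws3, now)

        for pump_name, end in list(stalls.items()):
            if now < end:
                fractions[pump_name] = 0.0
            else:
                del stalls[pump_name]

        for name in ("P1", "P2", "P3"):
            plant.pumps[name].set_fraction(fractions[name])
        if sup.phase in (Phase.STEADY, Phase.SHUTDOWN):
            p4_flow = p4_profile.flow_at(now)
            plant.pumps["P4"].set_command(
                p4_flow / config.pumps["P4"].gain_mlmin_per_v
            )
        else:
            plant.pumps["P4"].set_command(0.0)

        if step_index % log_stride == 0:
            pumps = [plant.pumps[p] for p in ("P1", "P2", "P3", "P4", "P5")]
            rows.append(
                (
                    now,
                    sup.phase.value,
                    ws1,
                    ws2,
                    ws3,
                    *(p.command_v for p in pumps),
                    *(p.reported_rpm for p in pumps),
                    est_flow,
                    plant.tanks["cstr1"].volume_ml,
                    plant.tanks["cstr2"].volume_ml,
                )
            )

        try:
            step_plant(
                plant,
                dt,
                reaction,
                rng=rng,
                faults=sc.faults,
                pulsation_sd=sc.pulsation_sd,
            )
        except PlantFault as exc:
            raise type(exc)(f"[phase {sup.phase.value}, t={now:.0f} s] {exc}") from exc

        # Feed the loss-in-weight estimator with the rate-limited WS-1
        # sub-stream for the step just taken (linear mass interpolation
        # emulates the balance's fast message rate between control ticks).
        if sup.pid_active and ctl.mode == "pid":
            new_mass = plant.tanks["feed"].mass_g
            rpm = plant.pumps["P1"].reported_rpm
            for i in range(1, n_sub + 1):
                frac = i / n_sub
                tt = now + frac * dt
                mm = prev_feed_mass + (new_mass - prev_feed_mass) * frac
                out = estimator.update(
                    plant.scales["WS1"].reading(tt, mm), reported_rpm=rpm
                )
                if out is not None:
                    est_flow = out
                    u1 = pid1.update(out, tt)
        prev_feed_mass = plant.tanks["feed"].mass_g
        step_index += 1

    telemetry = pd.DataFrame(rows, columns=TELEMETRY_COLUMNS)
    result = SimulationResult(telemetry, plant, config, seed, sup.transitions)
    if out_csv is not None:
        from .telemetry import write_telemetry

        write_telemetry(telemetry, out_csv)
    return result
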