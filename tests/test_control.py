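"""Control stack: estimator, PID, supervisor sequencing, closed loop."""

import numpy as np
import pytest

from cstrtwin import (
    FlowEstimator,
    PID,
    PIDParams,
    Phase,
    ScaleModel,
    ScaleReading,
    Supervisor,
    compute_metrics,
    run_closed_loop,
    scale_stream,
    supervisor_step,
)
from cstrtwin.control import SupervisorTargets


# --- flow estimator ---------------------------------------------------------


def constant_flow_estimates(flow_mlmin=2.5, density=1.0, duration_s=300.0):
    scale = ScaleModel("WS1", precision_g=0.1, rate_hz=20.0)
    est = FlowEstimator(density, rpm_constant_mlmin_per_rpm=0.1)
    rate_gs = flow_mlmin * density / 60.0
    out = []
    for r in scale_stream(lambda t: 800.0 - rate_gs * t, 0.0, duration_s, scale):
        v = est.update(r)
        if v is not None:
            out.append(v)
    return out


def test_estimator_tracks_constant_flow_within_five_percent():
    estimates = constant_flow_estimates()
    assert estimates, "buffer never filled"
    assert np.mean(estimates) == pytest.approx(2.5, rel=0.05)
    assert max(abs(e - 2.5) for e in estimates) / 2.5 < 0.15


def test_estimator_time_average_meets_quantization_bound():
    """Each estimate differences >= 4 quanta, so its error is bounded by the
    sampling-grid jitter of the 5-message window; the time average is tighter."""
    estimates = constant_flow_estimates(duration_s=1200.0)
    assert np.mean(estimates) == pytest.approx(2.5, rel=0.02)


def test_buffer_of_five_contract():
    est = FlowEstimator(1.0, rpm_constant_mlmin_per_rpm=0.1)
    # four changed masses: no output yet
    for i, mass in enumerate([100.0, 99.9, 99.8, 99.7]):
        assert est.update(ScaleReading(i * 1.0, mass)) is None
    # fifth change completes the window
    v = est.update(ScaleReading(4.0, 99.6))
    assert v == pytest.approx((100.0 - 99.6) / 4.0 * 60.0)


def test_rpm_fallback_only_below_threshold():
    est = FlowEstimator(1.0, rpm_constant_mlmin_per_rpm=0.1, fallback_threshold_mlmin=1.0)
    # constant mass -> no buffered update; rpm estimate admitted when < 1
    assert est.update(ScaleReading(0.0, 50.0), reported_rpm=5.0) == pytest.approx(0.5)
    assert est.update(ScaleReading(1.0, 50.0), reported_rpm=20.0) is None  # 2.0 >= 1


def test_rate_limit_drops_fast_messages():
    est = FlowEstimator(1.0, rpm_constant_mlmin_per_rpm=0.1, rate_limit_hz=3.0)
    for i in range(40):  # 2 s of 20 Hz, every message a change
        est.update(ScaleReading(i * 0.05, 100.0 - i))
    assert est.n_accepted <= 7  # ~3 messages per second pass the limiter
    assert len(est.buffer) <= 5


def test_non_monotone_timestamps_rejected():
    est = FlowEstimator(1.0, rpm_constant_mlmin_per_rpm=0.1)
    est.update(ScaleReading(1.0, 10.0))
    with pytest.raises(ValueError, match="monotonic"):
        est.update(ScaleReading(0.5, 9.9))


# --- PID --------------------------------------------------------------------


def test_proportional_only_algebra():
    pid = PID(PIDParams(setpoint=1.0, kp=0.5, ki=0.0))
    assert pid.update(0.8, 0.0) == pytest.approx(0.1)  # e_norm = 0.2


def test_zero_error_returns_bias():
    pid = PID(PIDParams(setpoint=10.0, kp=0.6, ki=0.05, bias=0.25))
    assert pid.update(10.0, 0.0) == pytest.approx(0.25)


def test_clamp_freezes_integral():
    pid = PID(PIDParams(setpoint=1.0, kp=0.5, ki=0.1))
    pid.update(-100.0, 0.0)
    out = pid.update(-100.0, 10.0)  # huge positive error for 10 s
    assert out == 1.0
    frozen = pid.integral
    pid.update(-100.0, 20.0)
    assert pid.integral == frozen == 0.0  # anti-windup: integration suspended
    # once the output re-enters the limits, integration resumes
    out = pid.update(0.9, 30.0)
    assert 0.0 < out < 1.0
    assert pid.integral > frozen


def test_degenerate_dt_returns_previous_output():
    pid = PID(PIDParams(setpoint=1.0, kp=0.5))
    first = pid.update(0.5, 5.0)
    assert pid.update(0.9, 5.0) == first
    with pytest.raises(ValueError):
        pid.update(0.9, 4.0)


# --- supervisor -------------------------------------------------------------


def fresh_supervisor():
    return Supervisor(
        SupervisorTargets(
            cstr1_target_g=262.5,
            cstr2_target_g=262.5,
            fastfill_fraction=0.8,
            steady_fractions={"P1": 0.25, "P2": 0.25, "P3": 0.625},
            hold_duration_s=7200.0,
        )
    )


def test_startup_sequence_and_ten_percent_backoff():
    sup = fresh_supervisor()
    cmds = sup.step(0.0, 0.0, 0.0, "start")
    assert sup.phase is Phase.FILL_CSTR1
    assert cmds == {"P1": 0.8, "P2": 0.0, "P3": 0.0}
    cmds = sup.step(60.0, 263.0, 0.0)  # WS-2 crosses target
    assert sup.phase is Phase.FILL_CSTR2
    assert cmds["P1"] == pytest.approx(0.8 * 0.9)  # speed reduced by exactly 10%
    assert cmds["P2"] == 0.8
    cmds = sup.step(120.0, 240.0, 263.0)  # WS-3 crosses target
    assert sup.phase is Phase.TOPOFF_CSTR1
    assert cmds["P2"] == 0.0 and cmds["P1"] == pytest.approx(0.72)
    sup.step(150.0, 263.0, 262.0)  # WS-2 topped off again
    assert sup.phase is Phase.BATCH_HOLD
    sup.step(150.0 + 7199.0, 262.5, 262.5)
    assert sup.phase is Phase.BATCH_HOLD
    cmds = sup.step(150.0 + 7200.0, 262.5, 262.5)  # two-hour hold elapsed
    assert sup.phase is Phase.STEADY
    assert sup.pid_active
    assert cmds == {"P1": 0.25, "P2": 0.25, "P3": 0.625}


def test_shutdown_drains_at_setpoint_until_empty():
    sup = fresh_supervisor()
    sup.step(0.0, 0.0, 0.0, "start")
    sup.step(1.0, 263.0, 0.0)
    sup.step(2.0, 240.0, 263.0)
    sup.step(3.0, 263.0, 262.0)
    sup.step(7300.0, 262.5, 262.5)
    assert sup.phase is Phase.STEADY
    sup, cmds = supervisor_step(sup, 8000.0, 262.5, 262.5, "shutdown")
    assert sup.phase is Phase.SHUTDOWN
    assert cmds == {"P1": 0.0, "P2": 0.25, "P3": 0.625}
    _, cmds = supervisor_step(sup, 9000.0, 0.5, 100.0)  # CSTR-1 drained first
    assert cmds["P2"] == 0.0 and cmds["P3"] == 0.625
    supervisor_step(sup, 9500.0, 0.5, 0.5)
    assert sup.phase is Phase.DONE


def test_unknown_user_command_rejected():
    sup = fresh_supervisor()
    with pytest.raises(ValueError, match="unknown user command"):
        sup.step(0.0, 0.0, 0.0, "reverse")


def test_transition_log_records_triggers():
    sup = fresh_supervisor()
    sup.step(0.0, 0.0, 0.0, "start")
    sup.step(60.0, 263.0, 0.0)
    phases = [p for _, p, _ in sup.transitions]
    assert phases == ["FILL_CSTR1", "FILL_CSTR2"]


# --- closed loop ------------------------------------------------------------


def test_integral_action_rejects_calibration_error(short_run4):
    """A 15% miscalibrated level pump still holds the mass setpoint."""
    short_run4.pumps["P2"].calibration_error = 0.85
    result = run_closed_loop(short_run4, seed=3)
    tel = result.telemetry
    last2h = tel[(tel["state"] == "STEADY") & (tel["time_s"] >= tel["time_s"].max() - 7200)]
    mean_vol = last2h["ws2_g"].mean() / 1.75
    assert abs(mean_vol - 150.0) / 150.0 < 0.01


def test_perfect_calibration_hits_setpoint_to_three_figures(short_run4):
    """In the disturbance-free limit (ideal pumps, negligible balance
    quantization) the delivered feed flow equals the setpoint to three
    significant figures; with the real 0.1 g balance the event-driven
    loss-in-weight loop keeps a sub-percent quantization floor."""
    for p in ("P1", "P2", "P3"):
        short_run4.pumps[p].calibration_error = 1.0
    coarse = compute_metrics(run_closed_loop(short_run4, seed=3).telemetry)
    assert abs(coarse.feed_flow_mlmin - 2.5) / 2.5 < 0.01
    short_run4.scales["WS1"].precision_g = 1e-6
    fine = compute_metrics(run_closed_loop(short_run4, seed=3).telemetry)
    assert abs(fine.feed_flow_mlmin - 2.5) < 0.005


def test_supervisor_never_exceeds_p3_cap(short_run4):
    result = run_closed_loop(short_run4, seed=3)
    tel = result.telemetry
    assert (tel["p3_V"] <= 10.0 + 1e-12).all()
    # 10 V full scale on P-3 corresponds to the 4 mL/min safety cap
    assert short_run4.pumps["P3"].gain_mlmin_per_v * 10.0 <= 4.0


def test_closed_loop_is_reproducible(short_run4):
    short_run4.scenario.pulsation_sd = 0.01  # exercise the stochastic path
    a = run_closed_loop(short_run4, seed=11).telemetry
    b = run_closed_loop(short_run4, seed=11).telemetry
    assert a.equals(b)
    c = run_closed_loop(short_run4, seed=12).telemetry
    assert not a.equals(c)


def test_phase_context_attached_to_faults(short_run4):
    from cstrtwin import OverfillFault

    short_run4.tanks["cstr2"].capacity_ml = 100.0  # below the 150 mL target
    with pytest.raises(OverfillFault, match="phase FILL_CSTR2"):
        run_closed_loop(short_run4, seed=3)
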