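"""Study-run fixtures and run-level monitoring metrics.

Four continuous-manufacturing runs are shipped as scenario fixtures,
mirroring the campaign that motivated the control stack:

====  ==========  ==========  =======  ==============================
run   feed        CSTR target control  pathology emulated
====  ==========  ==========  =======  ==============================
1     0.5 mL/min  30 mL       manual   none (small scale, well behaved)
2     2.5 mL/min  150 mL      manual   P-1 miscalibration (0.60), tubing
                                       degradation drift on P-2/P-3, tare
                                       shifts from equipment disturbances
3     0.67 mL/min 40 mL       manual   PTFE-head miscalibration on all
                                       transfer pumps
4     2.5 mL/min  150 mL      PID      nominal small miscalibrations,
                                       corrected by the closed loops
====  ==========  ==========  =======  ==============================

Manual runs hold the nominal setpoint commands open-loop, so pump
miscalibration lands directly on the delivered flows — which is exactly
what the gravimetric record of those runs showed and what motivated
feedback control.  The manual fixtures run with fault clamping (a pump on
an emptying vessel delivers what is there), because that is what a
peristaltic pump physically does; the PID fixture keeps strict faults.

Metrics mirror the campaign's monitoring table: per-CSTR mean/std volume
over the steady window (volumes derived from the balance masses, so
scripted tare shifts corrupt them the way they corrupted the real record),
the actual feed flowrate and its linear-fit R^2, and spacetime yield.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import Event, RunConfig, default_run_config

__all__ = [
    "make_scenario",
    "RunMetrics",
    "compute_metrics",
    "spacetime_yield",
    "metrics_from_result",
]


def make_scenario(run_id: int, seed: int | None = None) -> RunConfig:
    """Configuration fixture for one of the four campaign runs.

    ``seed`` is recorded in the scenario (it seeds any stochastic plant
    effects such as pump pulsation; the fixtures themselves are
    deterministic functions of ``run_id``).
    """
    if run_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown run_id {run_id!r}; expected 1-4")
    cfg = default_run_config()
    cfg.scenario.seed = seed

    if run_id == 1:
        _size_tanks(cfg, flask_ml=50.0, feed_ml=400.0, feed_cap_ml=1000.0,
                    iso_ml=400.0, iso_cap_ml=1000.0)
        cfg.pumps["P1"].calibration_error = 1.004
        cfg.control.mode = "manual"
        cfg.scenario = replace(
            cfg.scenario,
            name="run1",
            feed_setpoint_mlmin=0.5,
            target_volume_ml=30.0,
            duration_s=11 * 3600.0,
            shutdown_at_s=10 * 3600.0,
            faults="clamp",
        )
    elif run_id == 2:
        _size_tanks(cfg, flask_ml=500.0, feed_ml=2400.0, feed_cap_ml=3000.0,
                    iso_ml=2000.0, iso_cap_ml=20000.0)
        cfg.pumps["P1"].calibration_error = 0.60  # gross miscalibration
        cfg.pumps["P2"].drift_rate_per_h = 0.04  # C-Flex tubing degradation
        cfg.pumps["P3"].drift_rate_per_h = 0.04
        cfg.control.mode = "manual"
        cfg.scenario = replace(
            cfg.scenario,
            name="run2",
            feed_setpoint_mlmin=2.5,
            target_volume_ml=150.0,
            duration_s=18 * 3600.0,
            shutdown_at_s=17 * 3600.0,
            faults="clamp",
            events=[
                # tubing replacements shifted equipment on the scales
                Event(6 * 3600.0, "tare_shift", "WS2", delta_g=45.0),
                Event(8 * 3600.0, "tare_shift", "WS3", delta_g=60.0),
                Event(12 * 3600.0, "tare_shift", "WS2", delta_g=30.0),
            ],
        )
    elif run_id == 3:
        _size_tanks(cfg, flask_ml=50.0, feed_ml=400.0, feed_cap_ml=1000.0,
                    iso_ml=400.0, iso_cap_ml=1000.0)
        cfg.pumps["P1"].calibration_error = 0.863  # PTFE heads read wrong
        cfg.pumps["P2"].calibration_error = 1.10
        cfg.pumps["P3"].calibration_error = 1.20
        cfg.control.mode = "manual"
        cfg.scenario = replace(
            cfg.scenario,
            name="run3",
            feed_setpoint_mlmin=0.67,
            target_volume_ml=40.0,
            duration_s=8 * 3600.0,
            shutdown_at_s=7 * 3600.0,
            faults="clamp",
        )
    else:  # run 4: full-scale, PID
        _size_tanks(cfg, flask_ml=500.0, feed_ml=1800.0, feed_cap_ml=3000.0,
                    iso_ml=2000.0, iso_cap_ml=20000.0)
        cfg.pumps["P1"].calibration_error = 0.96
        cfg.pumps["P2"].calibration_error = 0.97
        cfg.pumps["P3"].calibration_error = 1.02
        cfg.control.mode = "pid"
        cfg.scenario = replace(
            cfg.scenario,
            name="run4",
            feed_setpoint_mlmin=2.5,
            target_volume_ml=150.0,
            duration_s=12 * 3600.0,
            shutdown_at_s=11 * 3600.0,
            faults="raise",
        )
    return cfg


def _size_tanks(cfg: RunConfig, flask_ml, feed_ml, feed_cap_ml, iso_ml, iso_cap_ml):
    cfg.tanks["cstr1"].capacity_ml = flask_ml
    cfg.tanks["cstr2"].capacity_ml = flask_ml
    cfg.tanks["feed"].initial_volume_ml = feed_ml
    cfg.tanks["feed"].capacity_ml = feed_cap_ml
    cfg.tanks["iso"].initial_volume_ml = iso_ml
    cfg.tanks["iso"].capacity_ml = iso_cap_ml


@dataclass(frozen=True)
class RunMetrics:
    """Run-level monitoring summary over the steady-state window."""

    cstr1_mean_ml: float
    cstr1_std_ml: float
    cstr2_mean_ml: float
    cstr2_std_ml: float
    feed_flow_mlmin: float
    feed_r2: float
    window_s: tuple[float, float]
    spacetime_yield_g_ml_h: float | None = None


def compute_metrics(
    telemetry: pd.DataFrame,
    density_gml: float = 1.75,
    window: str | tuple[float, float] = "steady",
    product_mass_g: float | None = None,
    heated_volume_ml: float | None = None,
    elapsed_h: float | None = None,
) -> RunMetrics:
    """Monitoring metrics from a telemetry record.

    ``window`` is ``"steady"`` (rows logged during the STEADY phase — from
    steady-state entry to shutdown) or an explicit ``(t0, t1)`` span in
    seconds.  Vessel volumes are the balance masses divided by the stream
    density, as in the gravimetric record (so tare disturbances bias them,
    deliberately).  The feed flowrate is the magnitude of the slope of an
    ordinary least-squares line through (time, WS-1 mass), converted to
    mL/min, with its coefficient of determination.  Spacetime yield is
    attached when product mass, heated volume and elapsed time are given.
    """
    if isinstance(window, str):
        if window != "steady":
            raise ValueError("window must be 'steady' or a (t0, t1) pair")
        sel = telemetry[telemetry["state"] == "STEADY"]
    else:
        t0, t1 = window
        sel = telemetry[(telemetry["time_s"] >= t0) & (telemetry["time_s"] < t1)]
    if len(sel) < 2:
        raise ValueError("steady-state window is empty")

    t = sel["time_s"].to_numpy(dtype=float)
    vol1 = sel["ws2_g"].to_numpy(dtype=float) / density_gml
    vol2 = sel["ws3_g"].to_numpy(dtype=float) / density_gml
    ws1 = sel["ws1_g"].to_numpy(dtype=float)

    slope, intercept = np.polyfit(t, ws1, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((ws1 - fitted) ** 2))
    ss_tot = float(np.sum((ws1 - ws1.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flow = abs(slope) * 60.0 / density_gml

    sty = None
    if product_mass_g is not None:
        if heated_volume_ml is None or elapsed_h is None:
            raise ValueError(
                "spacetime yield needs heated_volume_ml and elapsed_h too"
            )
        sty = spacetime_yield(product_mass_g, elapsed_h, heated_volume_ml)

    return RunMetrics(
        cstr1_mean_ml=float(vol1.mean()),
        cstr1_std_ml=float(vol1.std(ddof=0)),
        cstr2_mean_ml=float(vol2.mean()),
        cstr2_std_ml=float(vol2.std(ddof=0)),
        feed_flow_mlmin=float(flow),
        feed_r2=float(r2),
        window_s=(float(t[0]), float(t[-1])),
        spacetime_yield_g_ml_h=sty,
    )


def spacetime_yield(product_mass_g: float, elapsed_h: float, heated_volume_ml: float) -> float:
    """Product mass per heated reactor volume per time, g mL^-1 h^-1."""
    if elapsed_h <= 0 or heated_volume_ml <= 0:
        raise ValueError("elapsed time and heated volume must be positive")
    return product_mass_g / (elapsed_h * heated_volume_ml)


def metrics_from_result(result, window: str | tuple[float, float] = "steady") -> RunMetrics:
    """Convenience: metrics for a :class:`~cstrtwin.control.SimulationResult`.

    Spacetime yield uses the run's recovered product mass, the combined
    heated CSTR target volume, and the full scenario duration.
    """
    sc = result.config.scenario
    return compute_metrics(
        result.telemetry,
        density_gml=result.config.tanks["cstr1"].density_gml,
        window=window,
        product_mass_g=result.product_mass_g,
        heated_volume_ml=2.0 * sc.target_volume_ml,
        elapsed_h=sc.duration_s / 3600.0,
    )
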