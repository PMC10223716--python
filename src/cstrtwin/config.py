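"""Scenario configuration: dataclasses plus plain-text (TOML) round-trip.

A run of the twin is fully described by one config object: vessel geometry
and densities, pump characteristics, balance characteristics, kinetics,
control-stack parameters, and the scenario script (setpoints, durations,
scripted disturbance events).  Configs serialize to TOML with sections
``[plant]``, ``[plant.tanks.*]``, ``[pumps.*]``, ``[scales.*]``,
``[kinetics]``, ``[control]``, ``[scenario]`` and ``[[scenario.events]]``.

All defaults are stated here once; the scenario factory in
:mod:`cstrtwin.scenarios` derives the four study fixtures from them.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .kinetics import KineticsSpec
from .plant import (
    PlantState,
    PumpModel,
    ReactionSpec,
    ScaleModel,
    SpeciesState,
    TankState,
)

__all__ = [
    "TankConfig",
    "PumpConfig",
    "ScaleConfig",
    "KineticsConfig",
    "ControlConfig",
    "LoopGains",
    "Event",
    "ScenarioConfig",
    "RunConfig",
    "build_plant",
    "build_reaction",
    "load_config",
    "save_config",
]


@dataclass
class TankConfig:
    capacity_ml: float
    density_gml: float = 1.75  # ClSO3H-rich reaction stream
    temperature_c: float = 25.0
    initial_volume_ml: float = 0.0
    solute_fraction: float = 0.0  # reactive solute mass fraction of contents
    initial_sm_fraction: float = 0.0  # starting-material share of that solute


@dataclass
class PumpConfig:
    gain_mlmin_per_v: float = 1.0
    calibration_error: float = 1.0
    drift_rate_per_h: float = 0.0
    max_flow_mlmin: float | None = None
    rpm_per_volt: float = 10.0


@dataclass
class ScaleConfig:
    precision_g: float = 0.1
    rate_hz: float = 20.0
    tare_g: float = 0.0


@dataclass
class KineticsConfig:
    k_per_min: float = 0.077
    reference_temperature_c: float = 155.0
    threshold_c: float = 150.0
    series_channel: bool = False
    k_second_per_min: float = 0.0


@dataclass
class LoopGains:
    """Gains on the normalized (setpoint-relative) loop error."""

    kp: float = 0.6
    ki: float = 0.05  # 1/s
    kd: float = 0.0


@dataclass
class ControlConfig:
    mode: str = "pid"  # "pid" | "manual"
    # loop 1: feed flowrate (WS-1 derivative) -> P-1.  Tuned softer than the
    # level loops: the pump responds instantly, so the per-update loop gain
    # kp * pump_max / setpoint must stay below 1 for the estimator-delayed
    # discrete loop to be well damped.
    loop1: LoopGains = field(default_factory=lambda: LoopGains(kp=0.1, ki=0.01))
    # loops 2-3: vessel mass (WS-2 / WS-3) -> P-2 / P-3
    loop2: LoopGains = field(default_factory=LoopGains)
    loop3: LoopGains = field(default_factory=LoopGains)
    hold_duration_s: float = 7200.0  # batch hold before steady state
    fastfill_fraction: float = 0.8  # startup fill command, fraction of range
    hysteresis_g: float = 0.5  # target-detection band at the quantized scale
    rate_limit_hz: float = 3.0  # estimator input message cap
    fallback_mlmin: float = 1.0  # RPM-estimate admission threshold
    empty_threshold_g: float = 1.0  # "vessel drained" detection at shutdown


@dataclass
class Event:
    """A scripted disturbance: tare shift, pump stall, or heater fault."""

    time_s: float
    kind: str  # "tare_shift" | "pump_stall" | "heater_fault"
    target: str  # scale, pump, or tank name
    delta_g: float = 0.0  # tare_shift only
    duration_s: float = 0.0  # pump_stall / heater_fault


@dataclass
class ScenarioConfig:
    name: str = "custom"
    feed_setpoint_mlmin: float = 2.5
    target_volume_ml: float = 150.0
    duration_s: float = 43200.0
    shutdown_at_s: float | None = None  # None: run to duration, no shutdown cmd
    dt_s: float = 1.0
    log_every_s: float = 1.0
    faults: str = "raise"
    pulsation_sd: float = 0.0  # zero-mean relative flow noise, off by default
    iso_outlet_duty: float = 0.25
    iso_outlet_period_s: float = 600.0
    product_to_sm_mass_ratio: float = 1.5  # MW growth on chlorosulfonation
    seed: int | None = None
    events: list[Event] = field(default_factory=list)


@dataclass
class RunConfig:
    """Everything needed to run the twin once."""

    tanks: dict[str, TankConfig]
    pumps: dict[str, PumpConfig]
    scales: dict[str, ScaleConfig]
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)


def default_run_config() -> RunConfig:
    """A nominal 500 mL-flask, 150 mL-target, 2.5 mL/min configuration."""
    return RunConfig(
        tanks={
            "feed": TankConfig(
                capacity_ml=3000.0,
                initial_volume_ml=1800.0,
                temperature_c=25.0,
                solute_fraction=0.17,
                initial_sm_fraction=1.0,
            ),
            "cstr1": TankConfig(capacity_ml=500.0, temperature_c=155.0),
            "cstr2": TankConfig(capacity_ml=500.0, temperature_c=155.0),
            "iso": TankConfig(
                capacity_ml=20000.0,
                density_gml=1.1,
                temperature_c=-5.0,
                initial_volume_ml=1000.0,
            ),
        },
        pumps={
            "P1": PumpConfig(gain_mlmin_per_v=1.0, max_flow_mlmin=10.0),
            "P2": PumpConfig(gain_mlmin_per_v=1.0, max_flow_mlmin=10.0),
            # P-3 wired so full scale is a safe ~4 mL/min into the quench
            "P3": PumpConfig(gain_mlmin_per_v=0.4, max_flow_mlmin=4.0),
            "P4": PumpConfig(gain_mlmin_per_v=1.0, max_flow_mlmin=10.0),
            "P5": PumpConfig(gain_mlmin_per_v=1.0, max_flow_mlmin=10.0),
        },
        scales={"WS1": ScaleConfig(), "WS2": ScaleConfig(), "WS3": ScaleConfig()},
    )


def build_plant(config: RunConfig) -> PlantState:
    """Instantiate a :class:`PlantState` from a config."""
    tanks: dict[str, TankState] = {}
    for name, tc in config.tanks.items():
        species = SpeciesState(starting_material=tc.initial_sm_fraction)
        tanks[name] = TankState.from_volume(
            name,
            tc.initial_volume_ml,
            tc.density_gml,
            tc.capacity_ml,
            tc.temperature_c,
            species,
            solute_fraction=tc.solute_fraction,
        )
    pumps = {
        name: PumpModel(
            name,
            pc.gain_mlmin_per_v,
            pc.calibration_error,
            pc.drift_rate_per_h,
            pc.max_flow_mlmin,
            pc.rpm_per_volt,
        )
        for name, pc in config.pumps.items()
    }
    scales = {
        name: ScaleModel(name, sc.precision_g, sc.rate_hz, sc.tare_g)
        for name, sc in config.scales.items()
    }
    return PlantState(0.0, tanks, pumps, scales)


def build_reaction(config: RunConfig) -> ReactionSpec:
    kc = config.kinetics
    return ReactionSpec(
        KineticsSpec(kc.k_per_min, kc.reference_temperature_c),
        threshold_c=kc.threshold_c,
        series_channel=kc.series_channel,
        k_second_per_min=kc.k_second_per_min,
    )


# ---------------------------------------------------------------------------
# TOML round-trip
# ---------------------------------------------------------------------------


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if v is None:
                continue  # TOML has no null; absent key means default None
            out[f.name] = _to_dict(v)
        return out
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_to_dict(v) for v in obj]
    return obj


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def _dump_section(lines: list[str], name: str, data: dict) -> None:
    scalars = {k: v for k, v in data.items() if not isinstance(v, (dict, list))}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    arrays = {k: v for k, v in data.items() if isinstance(v, list)}
    if scalars or not (tables or arrays):
        lines.append(f"[{name}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_format_value(v)}")
        lines.append("")
    for k, v in tables.items():
        _dump_section(lines, f"{name}.{k}", v)
    for k, items in arrays.items():
        for item in items:
            lines.append(f"[[{name}.{k}]]")
            for ik, iv in item.items():
                lines.append(f"{ik} = {_format_value(iv)}")
            lines.append("")


def save_config(config: RunConfig, path) -> None:
    """Write a config as a sectioned TOML file."""
    data = _to_dict(config)
    lines: list[str] = []
    _dump_section(lines, "plant", {"tanks": data["tanks"]})
    for pump, pdata in data["pumps"].items():
        _dump_section(lines, f"pumps.{pump}", pdata)
    for scale, sdata in data["scales"].items():
        _dump_section(lines, f"scales.{scale}", sdata)
    _dump_section(lines, "kinetics", data["kinetics"])
    _dump_section(lines, "control", data["control"])
    _dump_section(lines, "scenario", data["scenario"])
    with open(path, "w") as fh:
        fh.write("\n".join(lines).rstrip() + "\n")


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} key {k!r}")
        ftype = fields[k].type
        if ftype in ("LoopGains",) or k in ("loop1", "loop2", "loop3"):
            v = _build(LoopGains, v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Read a config written by :func:`save_config`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    tanks = {k: _build(TankConfig, v) for k, v in raw["plant"]["tanks"].items()}
    pumps = {k: _build(PumpConfig, v) for k, v in raw.get("pumps", {}).items()}
    scales = {k: _build(ScaleConfig, v) for k, v in raw.get("scales", {}).items()}
    kinetics = _build(KineticsConfig, raw.get("kinetics", {}))
    control = _build(ControlConfig, raw.get("control", {}))
    sdata = dict(raw.get("scenario", {}))
    events = [_build(Event, e) for e in sdata.pop("events", [])]
    scenario = _build(ScenarioConfig, sdata)
    scenario.events = events
    return RunConfig(tanks, pumps, scales, kinetics, control, scenario)
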