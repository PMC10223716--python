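"""Digital twin of the continuous chlorosulfonation train.

Topology (fixed): feed stock -> P-1 -> CSTR-1 -> P-2 -> CSTR-2 -> P-3 ->
ISO-CSTR -> P-4/P-5 -> filter.  Peristaltic pumps move a chlorosulfonic-
acid-rich reaction stream between stirred round-bottom flasks; gravimetric
balances sit under the feed stock (WS-1), CSTR-1 (WS-2) and CSTR-2 (WS-3).
The twin advances on a fixed explicit-Euler time step (1 s by default;
residence times are of order an hour, so stiffness is not a concern) and
tracks, per vessel: total mass, the mass of reactive solute (starting-
material basis) it carries, and the composition of that solute between
starting material, sulfonyl-chloride product and sulfonic-acid impurity.

The reaction is pseudo-first order in the starting material and is switched
on only at or above a temperature threshold; heat transfer is instantaneous
(vessel temperatures are configuration, not state).  The ISO-CSTR is a
mixing vessel with duty-cycled outflow only: no precipitation or filtration
physics.

Mass is conserved exactly by construction: every transfer is computed once
and debited/credited on both sides, and cumulative per-pump transfers are
kept for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, NamedTuple

import numpy as np

from .kinetics import KineticsSpec

__all__ = [
    "PlantFault",
    "OverfillFault",
    "DryRunFault",
    "SpeciesState",
    "TankState",
    "PumpModel",
    "ScaleModel",
    "ScaleReading",
    "ReactionSpec",
    "PlantState",
    "step_plant",
    "read_scale",
    "scale_stream",
    "FlowProfile",
    "iso_outlet_schedule",
]

_EMPTY_VOLUME_ML = 1e-9


class PlantFault(RuntimeError):
    """Base class for plant faults raised during stepping."""


class OverfillFault(PlantFault):
    """A vessel's volume exceeded its capacity."""


class DryRunFault(PlantFault):
    """A commanded pump attempted to withdraw from an empty vessel."""


@dataclass
class SpeciesState:
    """Composition of the reactive solute, as fractions of the solute basis.

    Fractions are on the starting-material basis the feed carries: the feed
    enters with ``starting_material = 1`` and the reaction converts it in
    place, so the three fractions sum to at most 1 (solvent excluded).
    """

    starting_material: float = 0.0
    product: float = 0.0
    sulfonic_acid: float = 0.0

    def validate(self, tol: float = 1e-9) -> None:
        for name, v in (
            ("starting_material", self.starting_material),
            ("product", self.product),
            ("sulfonic_acid", self.sulfonic_acid),
        ):
            if not -tol <= v <= 1.0 + tol:
                raise ValueError(f"species fraction {name}={v} outside [0, 1]")
        total = self.starting_material + self.product + self.sulfonic_acid
        if total > 1.0 + tol:
            raise ValueError(f"species fractions sum to {total} > 1")

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.starting_material, self.product, self.sulfonic_acid)


@dataclass
class TankState:
    """One stirred vessel: mass is primary, volume derived via density."""

    name: str
    mass_g: float
    density_gml: float
    capacity_ml: float
    temperature_c: float = 25.0
    species: SpeciesState = field(default_factory=SpeciesState)
    solute_g: float = 0.0  # reactive solute (starting-material basis) carried

    @property
    def volume_ml(self) -> float:
        return self.mass_g / self.density_gml

    @classmethod
    def from_volume(
        cls,
        name: str,
        volume_ml: float,
        density_gml: float,
        capacity_ml: float,
        temperature_c: float = 25.0,
        species: SpeciesState | None = None,
        solute_fraction: float = 0.0,
    ) -> "TankState":
        mass = volume_ml * density_gml
        return cls(
            name,
            mass,
            density_gml,
            capacity_ml,
            temperature_c,
            species if species is not None else SpeciesState(),
            solute_g=mass * solute_fraction,
        )

    def validate(self) -> None:
        if self.mass_g < -1e-9:
            raise ValueError(f"{self.name}: negative mass {self.mass_g}")
        if self.volume_ml > self.capacity_ml * (1 + 1e-12):
            raise OverfillFault(
                f"{self.name}: volume {self.volume_ml:.3f} mL exceeds "
                f"capacity {self.capacity_ml} mL"
            )
        self.species.validate()


@dataclass
class PumpModel:
    """Command-voltage -> RPM -> flow model of a peristaltic pump.

    Delivered flow is ``command * gain * calibration_error * drift(t)``
    clipped to ``[0, max_flow]``; ``calibration_error`` is the unknown
    multiplicative miscalibration of the head, and ``drift`` a linear loss
    of delivery with operating time emulating tubing degradation.  The
    reported RPM is the pump's own (nominal) display and knows nothing of
    either effect, which is exactly why gravimetric feedback is needed.
    """

    name: str
    gain_mlmin_per_v: float
    calibration_error: float = 1.0
    drift_rate_per_h: float = 0.0
    max_flow_mlmin: float | None = None
    rpm_per_volt: float = 10.0
    command_v: float = 0.0

    def set_command(self, volts: float) -> None:
        self.command_v = min(10.0, max(0.0, volts))

    def set_fraction(self, fraction: float) -> None:
        """Set the command as a 0-1 fraction of the 0-10 V range."""
        self.set_command(10.0 * fraction)

    @property
    def reported_rpm(self) -> float:
        return self.command_v * self.rpm_per_volt

    @property
    def nominal_rpm_constant(self) -> float:
        """(mL/min)/RPM implied by the nominal gain; estimator fallback."""
        return self.gain_mlmin_per_v / self.rpm_per_volt

    def drift_factor(self, t_hours: float) -> float:
        return max(0.0, 1.0 - self.drift_rate_per_h * t_hours)

    def delivered_flow_mlmin(self, t_hours: float, noise: float = 0.0) -> float:
        q = (
            self.command_v
            * self.gain_mlmin_per_v
            * self.calibration_error
            * self.drift_factor(t_hours)
        )
        q *= 1.0 + noise
        if self.max_flow_mlmin is not None:
            q = min(q, self.max_flow_mlmin)
        return max(0.0, q)


class ScaleReading(NamedTuple):
    """One timestamped, quantized balance message."""

    time_s: float
    mass_g: float


@dataclass
class ScaleModel:
    """Gravimetric balance: quantized readings at a fixed message rate."""

    name: str
    precision_g: float = 0.1
    rate_hz: float = 20.0
    tare_g: float = 0.0

    def quantize(self, true_mass_g: float) -> float:
        q = self.precision_g
        return float(np.round((true_mass_g + self.tare_g) / q) * q)

    def reading(self, time_s: float, true_mass_g: float) -> ScaleReading:
        return ScaleReading(time_s, self.quantize(true_mass_g))


@dataclass(frozen=True)
class ReactionSpec:
    """Reaction model for the twin: on/off by temperature threshold.

    Default: a single pseudo-first-order channel SM -> product at
    ``kinetics.k_per_min``.  ``series_channel`` switches to the two-step
    SM -> sulfonic acid -> product path with the second step at
    ``k_second_per_min`` (no published rate exists for it, hence off by
    default).
    """

    kinetics: KineticsSpec
    threshold_c: float = 150.0
    series_channel: bool = False
    k_second_per_min: float = 0.0

    @property
    def k_per_min(self) -> float:
        return self.kinetics.k_per_min


# scale -> tank placement per the process flow diagram
SCALE_TANKS = {"WS1": "feed", "WS2": "cstr1", "WS3": "cstr2"}
# pump -> (source tank, destination tank); None destination leaves the system
PUMP_ROUTES = {
    "P1": ("feed", "cstr1"),
    "P2": ("cstr1", "cstr2"),
    "P3": ("cstr2", "iso"),
    "P4": ("iso", None),
    "P5": ("iso", None),
}


@dataclass
class PlantState:
    """Full state of the train at one instant, plus conservation ledgers."""

    time_s: float
    tanks: dict[str, TankState]
    pumps: dict[str, PumpModel]
    scales: dict[str, ScaleModel]
    pump_totals_g: dict[str, float] = field(default_factory=dict)
    collected_mass_g: float = 0.0  # mass pumped out of the system (to filter)
    collected_product_solute_g: float = 0.0  # product share of solute pumped out

    def __post_init__(self) -> None:
        for name in self.pumps:
            self.pump_totals_g.setdefault(name, 0.0)

    def total_mass_g(self) -> float:
        return sum(t.mass_g for t in self.tanks.values())

    def validate(self) -> None:
        for tank in self.tanks.values():
            tank.validate()


def _react(tank: TankState, spec: ReactionSpec, dt_min: float) -> None:
    if tank.temperature_c < spec.threshold_c or spec.k_per_min <= 0:
        return
    sp = tank.species
    if not spec.series_channel:
        decay = math.exp(-spec.k_per_min * dt_min)
        converted = sp.starting_material * (1.0 - decay)
        sp.starting_material -= converted
        sp.product += converted
    else:
        # SM -> sulfonic acid -> product, explicit Euler on the intermediate
        d_sm = sp.starting_material * (1.0 - math.exp(-spec.k_per_min * dt_min))
        d_sa = min(sp.sulfonic_acid, sp.sulfonic_acid * spec.k_second_per_min * dt_min)
        sp.starting_material -= d_sm
        sp.sulfonic_acid += d_sm - d_sa
        sp.product += d_sa


def step_plant(
    state: PlantState,
    dt_s: float,
    reaction: ReactionSpec,
    rng: np.random.Generator | None = None,
    faults: str = "raise",
    pulsation_sd: float = 0.0,
) -> PlantState:
    """Advance the plant by one explicit-Euler step of ``dt_s`` seconds.

    Transfers use start-of-step availabilities and compositions; each
    transfer debits the source and credits the destination with the same
    mass (and proportional solute), so global mass balance holds to float
    round-off.  ``faults`` selects strict behaviour (``"raise"``: named
    :class:`OverfillFault` / :class:`DryRunFault`) or the physical clamp
    (``"clamp"``: a pump on an empty vessel delivers nothing, an overdrawn
    one delivers what is there).  Mutates and returns ``state``.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if faults not in ("raise", "clamp"):
        raise ValueError("faults must be 'raise' or 'clamp'")
    t_hours = state.time_s / 3600.0
    dt_min = dt_s / 60.0

    # start-of-step snapshots
    avail = {name: tank.mass_g for name, tank in state.tanks.items()}
    comp = {name: tank.species.copy() for name, tank in state.tanks.items()}
    solute_frac = {
        name: (tank.solute_g / tank.mass_g if tank.mass_g > 0 else 0.0)
        for name, tank in state.tanks.items()
    }

    for pump_name, (src_name, dst_name) in PUMP_ROUTES.items():
        pump = state.pumps[pump_name]
        noise = 0.0
        if pulsation_sd > 0.0 and rng is not None:
            noise = float(rng.normal(0.0, pulsation_sd))
        q = pump.delivered_flow_mlmin(t_hours, noise)
        if q <= 0.0:
            continue
        src = state.tanks[src_name]
        if avail[src_name] / src.density_gml <= _EMPTY_VOLUME_ML:
            if faults == "raise":
                raise DryRunFault(
                    f"{pump_name} commanded at {pump.command_v:.2f} V but "
                    f"source vessel {src_name} is empty"
                )
            continue  # clamp: empty source delivers nothing
        want_g = q * dt_min * src.density_gml
        moved_g = min(want_g, avail[src_name])
        if moved_g < want_g and faults == "raise" and moved_g <= 0.0:
            raise DryRunFault(f"{pump_name}: source vessel {src_name} ran dry")
        moved_solute = moved_g * solute_frac[src_name]
        avail[src_name] -= moved_g
        src.mass_g -= moved_g
        src.solute_g -= moved_solute
        state.pump_totals_g[pump_name] += moved_g
        if dst_name is None:
            state.collected_mass_g += moved_g
            state.collected_product_solute_g += moved_solute * comp[src_name].product
        else:
            dst = state.tanks[dst_name]
            _blend_in(dst, moved_g, moved_solute, comp[src_name])

    for tank in state.tanks.values():
        _react(tank, reaction, dt_min)
        if tank.mass_g < 0.0:
            tank.mass_g = max(tank.mass_g, 0.0)  # guard float dust
        if tank.volume_ml > tank.capacity_ml * (1 + 1e-12):
            if faults == "raise":
                raise OverfillFault(
                    f"{tank.name}: volume {tank.volume_ml:.2f} mL exceeds "
                    f"capacity {tank.capacity_ml} mL"
                )

    state.time_s += dt_s
    return state


def _blend_in(
    tank: TankState, mass_g: float, solute_g: float, species: SpeciesState
) -> None:
    """Mix an incoming parcel into a perfectly stirred vessel.

    Solute composition blends weighted by solute mass; the vessel's bulk
    density is a stream property and is not re-estimated on mixing.
    """
    old_solute = tank.solute_g
    new_solute = old_solute + solute_g
    if new_solute > 0:
        sp = tank.species
        w_old = old_solute / new_solute
        w_new = solute_g / new_solute
        sp.starting_material = (
            w_old * sp.starting_material + w_new * species.starting_material
        )
        sp.product = w_old * sp.product + w_new * species.product
        sp.sulfonic_acid = w_old * sp.sulfonic_acid + w_new * species.sulfonic_acid
    tank.mass_g += mass_g
    tank.solute_g = new_solute


def read_scale(state: PlantState, ws_id: str) -> ScaleReading:
    """Current quantized reading of one balance (tare offset applied)."""
    if ws_id not in state.scales:
        raise KeyError(f"unknown scale {ws_id!r}")
    tank = state.tanks[SCALE_TANKS[ws_id]]
    return state.scales[ws_id].reading(state.time_s, tank.mass_g)


def scale_stream(
    mass_fn: Callable[[float], float],
    t_start_s: float,
    t_end_s: float,
    scale: ScaleModel,
) -> Iterator[ScaleReading]:
    """Emit quantized readings of a mass trajectory at the scale's rate.

    ``mass_fn`` maps time (s) to true mass (g); messages are emitted at
    ``scale.rate_hz`` from ``t_start_s`` (inclusive) to ``t_end_s``
    (exclusive), time-ordered.  This is the raw balance stream a scale
    produces before any rate limiting in the control stack.
    """
    if t_end_s <= t_start_s:
        raise ValueError("empty stream interval")
    period = 1.0 / scale.rate_hz
    n = int(math.floor((t_end_s - t_start_s) / period))
    for i in range(n):
        t = t_start_s + i * period
        yield scale.reading(t, mass_fn(t))


@dataclass(frozen=True)
class FlowProfile:
    """Duty-cycled outlet profile: bursts of high flow, zero in between."""

    high_flow_mlmin: float
    duty: float
    period_s: float

    @property
    def average_mlmin(self) -> float:
        return self.high_flow_mlmin * self.duty

    def flow_at(self, t_s: float) -> float:
        return self.high_flow_mlmin if (t_s % self.period_s) < self.duty * self.period_s else 0.0


def iso_outlet_schedule(
    target_avg_mlmin: float,
    duty: float,
    period_s: float,
    max_flow_mlmin: float | None = None,
) -> FlowProfile:
    """Piecewise-constant ISO-CSTR outlet profile with exact time average.

    Intermittent high-flow bursts give a time-averaged outlet equal to
    ``target_avg_mlmin``; with ``duty`` the burst fraction of each period
    the burst flow is ``target/duty``, which must not exceed the pump cap.
    """
    if not 0.0 < duty <= 1.0:
        raise ValueError("duty must lie in (0, 1]")
    if period_s <= 0:
        raise ValueError("period must be positive")
    if target_avg_mlmin < 0:
        raise ValueError("target average flow must be non-negative")
    high = target_avg_mlmin / duty
    if max_flow_mlmin is not None and high > max_flow_mlmin * (1 + 1e-12):
        raise ValueError(
            f"infeasible schedule: burst flow {high:.3f} mL/min exceeds "
            f"pump cap {max_flow_mlmin} mL/min at duty {duty}"
        )
    return FlowProfile(high, duty, period_s)
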