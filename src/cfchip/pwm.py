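"""PWM reagent formulation: duty-cycle schedules and valve pulse trains.

Intermediate reagent concentrations are generated by alternating timed
pulses of stock solutions: within every cycle of period ``T`` each input
flows for ``t = D * T`` where ``D`` is its duty fraction.  The delivered
composition under ideal plug mixing is exactly linear in the duties.

Duties are held as exact :class:`fractions.Fraction` values so that the
structural invariants (duties sum to exactly 1, the energy solution holds
exactly half of every cycle when the 1:1 lysate:energy constraint is
active) are bit-exact, not approximate.

Three-input formulation follows the device's operating constraint: the
energy solution keeps a fixed 50% duty to maintain the 1:1 lysate:energy
ratio, and the remaining half cycle is split between a plain lysate and a
lysate carrying the dosed biomolecule.  The minimum usable duty (default
5%) is set by valve actuation time; on a 5% grid this yields the ten-level
dilution series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .device import DeviceLayout

__all__ = [
    "InputSolution",
    "PWMSchedule",
    "MixTarget",
    "MuxPlan",
    "ValveEvent",
    "InfeasibleTargetError",
    "pulse_time",
    "duties_for_target",
    "enumerate_dilution_series",
    "build_flush_train",
    "delivered_composition",
    "insert_wash_steps",
    "mixing_fidelity",
    "is_mixed",
    "assign_mux",
]

MIN_DUTY_DEFAULT = Fraction(1, 20)    # 5%: valve open/close time floor
RESOLUTION_DEFAULT = Fraction(1, 20)  # 5% duty grid
ENERGY_DUTY = Fraction(1, 2)          # 1:1 lysate:energy constraint

DEFAULT_CYCLE_PERIOD_MS = 600.0
DEFAULT_N_CYCLES = 100
THREE_INPUT_CYCLE_PERIOD_MS = 1000.0
THREE_INPUT_N_CYCLES = 60

#: residual plug amplitude below which the stream counts as fully mixed
MIX_THRESHOLD = 0.05

LYSATE = "lysate"
ENERGY = "energy"
BUFFER = "buffer"


class InfeasibleTargetError(ValueError):
    """Requested composition cannot be realized on the duty grid."""


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(10_000)


@dataclass(frozen=True)
class InputSolution:
    """One inlet stock: identity, inlet position, class, and contents.

    ``contents`` maps species name -> stock concentration (nM unless the
    caller adopts another unit consistently).
    """

    id: str
    inlet_index: int
    solution_class: str = LYSATE
    contents: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.solution_class not in (LYSATE, ENERGY, BUFFER):
            raise ValueError(f"unknown solution class {self.solution_class!r}")
        for sp, conc in self.contents.items():
            if conc < 0:
                raise ValueError(f"negative stock concentration for {sp!r}")


@dataclass(frozen=True)
class PWMSchedule:
    """Duty assignment realizing one composition.

    Invariants: duties sum to exactly 1; every nonzero duty is at least
    ``min_duty``; total flow time is ``n_cycles * T``.
    """

    cycle_period_ms: float
    duties: Mapping[str, Fraction]
    n_cycles: int = DEFAULT_N_CYCLES
    min_duty: Fraction = MIN_DUTY_DEFAULT

    def __post_init__(self) -> None:
        duties = {k: _as_fraction(v) for k, v in self.duties.items()}
        object.__setattr__(self, "duties", duties)
        object.__setattr__(self, "min_duty", _as_fraction(self.min_duty))
        if self.cycle_period_ms <= 0:
            raise ValueError("cycle period must be > 0")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be > 0")
        total = sum(duties.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"duties sum to {total}, expected exactly 1")
        for k, d in duties.items():
            if d < 0 or d > 1:
                raise ValueError(f"duty for {k!r} outside [0, 1]")
            if d != 0 and d < self.min_duty:
                raise ValueError(
                    f"nonzero duty {d} for {k!r} below minimum {self.min_duty}")

    @property
    def total_flow_time_s(self) -> float:
        return self.n_cycles * self.cycle_period_ms / 1000.0

    def pulse_time_ms(self, input_id: str) -> float:
        return pulse_time(self.duties[input_id], self.cycle_period_ms)

    def same_duties(self, other: "PWMSchedule") -> bool:
        a = {k: v for k, v in self.duties.items() if v != 0}
        b = {k: v for k, v in other.duties.items() if v != 0}
        return a == b

    def to_dict(self) -> dict:
        return {
            "cycle_period_ms": self.cycle_period_ms,
            "duties": {k: float(v) for k, v in self.duties.items()},
            "n_cycles": self.n_cycles,
            "total_flow_time_s": self.total_flow_time_s,
        }


@dataclass(frozen=True)
class MixTarget:
    """Requested dose of one variable input, as a fraction of its maximum
    feasible share (the lysate half-cycle)."""

    variable_input: str
    target_fraction: float
    energy_input: str = ENERGY
    plain_input: str = "plain_lysate"
    energy_duty: Fraction = ENERGY_DUTY

    def __post_init__(self) -> None:
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ValveEvent:
    t_ms: float
    valve: str
    action: str  # "open" | "close"

    def to_dict(self) -> dict:
        return {"t_ms": self.t_ms, "valve": self.valve, "action": self.action}


@dataclass(frozen=True)
class MuxPlan:
    """Mapping composition id -> tuple of row clusters it feeds."""

    assignments: Mapping[str, tuple[tuple[int, ...], ...]]

    def rows_for(self, composition_id: str) -> list[int]:
        return sorted(r for cluster in self.assignments[composition_id]
                      for r in cluster)


# -- operations -------------------------------------------------------------


def pulse_time(duty, cycle_period_ms: float) -> float:
    """Pulse duration t = D * T (ms) for one input within one cycle."""
    d = float(duty)
    if not 0 <= d <= 1:
        raise ValueError("duty must lie in [0, 1]")
    if cycle_period_ms <= 0:
        raise ValueError("cycle period must be > 0")
    return d * cycle_period_ms


def duties_for_target(target: MixTarget,
                      min_duty=MIN_DUTY_DEFAULT,
                      resolution=RESOLUTION_DEFAULT,
                      cycle_period_ms: float = THREE_INPUT_CYCLE_PERIOD_MS,
                      n_cycles: int = THREE_INPUT_N_CYCLES) -> PWMSchedule:
    """Three-input schedule delivering a fraction of the variable stock.

    The energy solution keeps exactly half the cycle; the requested share
    of the other half goes to the variable lysate, rounded to the duty
    grid, and the remainder to plain lysate.  Raises
    :class:`InfeasibleTargetError` when the rounded duty falls strictly
    between zero and the minimum actuation duty.
    """
    min_duty = _as_fraction(min_duty)
    resolution = _as_fraction(resolution)
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    half = target.energy_duty
    ideal = Fraction(target.target_fraction).limit_denominator(10_000) * half
    # nearest grid multiple; exact ties break toward the lower duty
    q = ideal / resolution
    k_lo = q.numerator // q.denominator
    k = k_lo if q - k_lo <= Fraction(1, 2) else k_lo + 1
    variable = k * resolution
    plain = half - variable
    for name, d in ((target.variable_input, variable),
                    (target.plain_input, plain)):
        if 0 < d < min_duty:
            smallest = min_duty / half
            raise InfeasibleTargetError(
                f"duty {float(d):.4f} for {name!r} is below the minimum "
                f"actuation duty {float(min_duty):.4f}; smallest achievable "
                f"nonzero fraction is {float(smallest):.4f}")
    duties = {target.energy_input: half,
              target.plain_input: plain,
              target.variable_input: variable}
    return PWMSchedule(cycle_period_ms=cycle_period_ms, duties=duties,
                       n_cycles=n_cycles, min_duty=min(min_duty, resolution))


def enumerate_dilution_series(min_duty=MIN_DUTY_DEFAULT,
                              resolution=RESOLUTION_DEFAULT,
                              cycle_period_ms: float = THREE_INPUT_CYCLE_PERIOD_MS,
                              n_cycles: int = THREE_INPUT_N_CYCLES,
                              variable_input: str = "variable_lysate",
                              plain_input: str = "plain_lysate",
                              energy_input: str = ENERGY) -> list[PWMSchedule]:
    """All distinct nonzero doses achievable for one stock, in ascending
    order of variable duty.  With the 5% minimum duty and 5% grid this is
    the ten-level dilution series."""
    min_duty = _as_fraction(min_duty)
    resolution = _as_fraction(resolution)
    if not 0 < min_duty <= ENERGY_DUTY or not 0 < resolution <= ENERGY_DUTY:
        raise ValueError("min_duty and resolution must lie in (0, 0.5]")
    n_steps = ENERGY_DUTY / resolution
    if n_steps.denominator != 1:
        raise ValueError(
            f"resolution {float(resolution)} does not evenly divide the "
            f"0.5 lysate half-cycle")
    schedules = []
    for k in range(1, int(n_steps) + 1):
        variable = k * resolution
        if variable < min_duty:
            continue
        plain = ENERGY_DUTY - variable
        if 0 < plain < min_duty:
            continue
        duties = {energy_input: ENERGY_DUTY, plain_input: plain,
                  variable_input: variable}
        schedules.append(PWMSchedule(
            cycle_period_ms=cycle_period_ms, duties=duties,
            n_cycles=n_cycles, min_duty=min(min_duty, resolution)))
    return schedules


def build_flush_train(schedule: PWMSchedule,
                      inlet_order: Sequence[str] | None = None) -> list[ValveEvent]:
    """Timed open/close events realizing the schedule.

    Within each cycle inputs fire sequentially in inlet order (ascending
    inlet index when :class:`InputSolution` objects are supplied via
    ``inlet_order``), each for its pulse time t = D*T.  Zero-duty inputs
    emit no events.  Total duration is n_cycles * T.
    """
    if inlet_order is None:
        inlet_order = list(schedule.duties)
    events: list[ValveEvent] = []
    T = schedule.cycle_period_ms
    for cycle in range(schedule.n_cycles):
        t = cycle * T
        for input_id in inlet_order:
            d = schedule.duties.get(input_id, Fraction(0))
            if d == 0:
                continue
            dt = pulse_time(d, T)
            events.append(ValveEvent(t, input_id, "open"))
            events.append(ValveEvent(t + dt, input_id, "close"))
            t += dt
    return events


def inlet_order_of(inputs: Iterable[InputSolution]) -> list[str]:
    """Input ids sorted by ascending inlet index (the firing order)."""
    return [s.id for s in sorted(inputs, key=lambda s: s.inlet_index)]


def delivered_composition(schedule: PWMSchedule,
                          inputs: Mapping[str, InputSolution]) -> dict[str, float]:
    """Ideal-mixing delivered concentrations: sum over inputs of duty x stock.

    Exactly linear and additive in the duties."""
    out: dict[str, float] = {}
    for input_id, duty in schedule.duties.items():
        if input_id not in inputs:
            raise KeyError(f"schedule references undefined input {input_id!r}")
        for sp, conc in inputs[input_id].contents.items():
            out[sp] = out.get(sp, 0.0) + float(duty) * conc
    return out


def wash_schedule(cycle_period_ms: float = DEFAULT_CYCLE_PERIOD_MS,
                  n_cycles: int = DEFAULT_N_CYCLES,
                  buffer_input: str = "pbs") -> PWMSchedule:
    """Buffer-only schedule used to purge serpentine dead volume."""
    return PWMSchedule(cycle_period_ms=cycle_period_ms,
                       duties={buffer_input: Fraction(1)},
                       n_cycles=n_cycles)


def insert_wash_steps(phases: Sequence[PWMSchedule],
                      wash: PWMSchedule | None = None) -> list[PWMSchedule]:
    """Insert a buffer wash between consecutive phases whose duty
    assignments differ; identical consecutive phases get no wash."""
    if len(phases) == 0:
        raise ValueError("at least one phase is required")
    if wash is None:
        wash = wash_schedule()
    out = [phases[0]]
    for prev, nxt in zip(phases, phases[1:]):
        if not prev.same_duties(nxt):
            out.append(wash)
        out.append(nxt)
    return out


# -- plug-mixing fidelity ---------------------------------------------------

#: tracer diffusivity used by the mixing model (um^2/s, GFP class)
MIXING_D_MOL = 90.0
#: effective mean advection speed in the mixing path (um/s)
MIXING_SPEED_UM_S = 4000.0


def _calibrated_residence(threshold_period_s: float) -> float:
    # back-solve t_res so residual(threshold_period) == MIX_THRESHOLD exactly
    return (math.log(1.0 / MIX_THRESHOLD) * (MIXING_SPEED_UM_S * threshold_period_s) ** 2
            / (4.0 * math.pi ** 2 * MIXING_D_MOL))


#: checkpoint -> residence time (s); calibrated so the serpentine end is
#: fully mixed exactly up to 800 ms periods and the exchange-channel entry
#: up to 1200 ms
CHECKPOINT_RESIDENCE_S = {
    "serpentine_end": _calibrated_residence(0.8),
    "exchange_entry": _calibrated_residence(1.2),
}


def mixing_fidelity(cycle_period_ms: float, checkpoint: str) -> float:
    """Residual plug amplitude fraction at a downstream checkpoint.

    An advected square wave of wavelength u*T decays diffusively; the
    fundamental Fourier mode leaves residual
    ``exp(-4 pi^2 D t_res / (u T)^2)`` after the checkpoint's residence
    time.  Residuals below 0.05 count as fully mixed.  The residence
    times are effective, calibrated constants (not measured transport
    parameters): they place the mixed/unmixed boundary at 800 ms for the
    serpentine end and 1200 ms for the exchange-channel entry.
    """
    if cycle_period_ms <= 0:
        raise ValueError("cycle period must be > 0")
    try:
        t_res = CHECKPOINT_RESIDENCE_S[checkpoint]
    except KeyError:
        raise KeyError(
            f"unknown checkpoint {checkpoint!r}; expected one of "
            f"{sorted(CHECKPOINT_RESIDENCE_S)}") from None
    T_s = cycle_period_ms / 1000.0
    wavelength = MIXING_SPEED_UM_S * T_s
    return math.exp(-4.0 * math.pi ** 2 * MIXING_D_MOL * t_res / wavelength ** 2)


def is_mixed(cycle_period_ms: float, checkpoint: str) -> bool:
    """True when the residual plug amplitude is at/below the 5% threshold."""
    return mixing_fidelity(cycle_period_ms, checkpoint) <= MIX_THRESHOLD * (1 + 1e-9)


def assign_mux(composition_ids: Sequence[str], layout: DeviceLayout) -> MuxPlan:
    """Partition rows into contiguous equal clusters, one per composition.

    Remainder rows go to the last cluster; compositions are assigned top
    row downward in input order.
    """
    n = len(composition_ids)
    if n == 0:
        raise ValueError("at least one composition is required")
    if n > layout.n_rows:
        raise ValueError(
            f"{n} compositions exceed the {layout.n_rows} addressable rows")
    base = layout.n_rows // n
    assignments: dict[str, tuple[tuple[int, ...], ...]] = {}
    start = 0
    for i, comp in enumerate(composition_ids):
        size = base if i < n - 1 else layout.n_rows - start
        rows = tuple(range(start, start + size))
        assignments[comp] = (rows,)
        start += size
    return MuxPlan(assignments=assignments)
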