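"""Event-driven execution of the flush/incubate chemostat protocol.

The protocol alternates two postures:

* **flush** — the cell-inlet valve (2) seals every unit cell, the
  exchange-pair valves (1) open, and after a 10 s wait the PWM-formulated
  mixture replaces the exchange channel.  The sealed cells are untouched;
  the flush is modeled as an instantaneous replacement of each cell's
  reservoir segment with the delivered composition at the flush timestamp.
* **incubate** — valves (1) close, isolating each cell with its reservoir
  segment; valve (2) opens and reagents exchange by diffusion while the
  circuit kinetics run.  Incubation windows are integrated jointly with
  the two-compartment exchange terms by a stiff-capable ODE solver.

A run is a sequence of phases (compositions), each flushed every
``flush_period`` (default 15 min), with buffer washes inserted whenever
the duty assignment changes, optional inducer pulses, and reporter
sampling at the imaging cadence (default every 30 min).  Everything is
deterministic given the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import TS_COLUMNS, TimeSeriesTable
from .device import DeviceLayout
from .kinetics import RESOURCE, CircuitModel, CircuitSpec, KineticParams
from .pwm import InputSolution, MuxPlan, PWMSchedule, delivered_composition
from .spotting import PlateMap

__all__ = [
    "ValveID",
    "ProtocolPhase",
    "PulseSpec",
    "ExperimentState",
    "ActuationRecord",
    "ProtocolViolationError",
    "ConfigurationError",
    "flush",
    "incubate",
    "run_protocol",
    "reagent_consumption",
    "DEFAULT_FLUSH_FLOW_RATE_UL_MIN",
]


class ValveID(IntEnum):
    """Pneumatic valve roles within one unit cell."""

    EXCHANGE_PAIR = 1  # separates each cell's exchange-channel segment
    CELL_INLET = 2     # seals the cell while the channel is replaced
    BUTTON = 3         # surface-patterning button
    SANDWICH = 4       # separates neighboring reaction chambers
    NECK = 5           # isolates the DNA spot until patterning is done


#: valve posture during incubation (True = open)
_INCUBATION_STATE = {
    ValveID.EXCHANGE_PAIR: False,
    ValveID.CELL_INLET: True,
    ValveID.BUTTON: False,
    ValveID.SANDWICH: False,
    ValveID.NECK: True,
}

DEFAULT_FLUSH_FLOW_RATE_UL_MIN = 0.75
DEFAULT_PREFLUSH_WAIT_S = 10.0
DEFAULT_FLUSH_PERIOD_MIN = 15.0


class ProtocolViolationError(RuntimeError):
    """A valve sequencing rule was broken."""


class ConfigurationError(ValueError):
    """The protocol configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class ActuationRecord:
    t_s: float
    valve: str
    cell_scope: str
    action: str

    def to_json(self) -> str:
        return json.dumps({"t_s": self.t_s, "valve": self.valve,
                           "cell_scope": self.cell_scope,
                           "action": self.action})


@dataclass(frozen=True)
class PulseSpec:
    """Transient delivery of a species via the flush composition."""

    species: str
    concentration_nm: float
    start_h: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.start_h < 0:
            raise ValueError("pulse start must be >= 0")
        if self.duration_h <= 0:
            raise ValueError("pulse duration must be > 0")

    def active(self, t_h: float) -> bool:
        return self.start_h <= t_h < self.start_h + self.duration_h


@dataclass
class ProtocolPhase:
    """One composition phase of the protocol.

    ``schedule`` is either a single :class:`PWMSchedule` feeding the whole
    chip, or a mapping composition-id -> schedule together with a
    ``mux_plan`` routing each composition to its row clusters.
    """

    name: str
    duration_h: float
    schedule: PWMSchedule | Mapping[str, PWMSchedule]
    inputs: Mapping[str, InputSolution]
    mux_plan: MuxPlan | None = None
    flush_period_min: float = DEFAULT_FLUSH_PERIOD_MIN
    preflush_wait_s: float = DEFAULT_PREFLUSH_WAIT_S

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("phase duration must be > 0")
        if isinstance(self.schedule, Mapping) and self.mux_plan is None:
            raise ConfigurationError(
                "per-composition schedules require a mux plan")
        flush_s = self._any_schedule().total_flow_time_s
        if self.flush_period_min * 60.0 <= flush_s:
            raise ValueError(
                f"flush period {self.flush_period_min} min must exceed the "
                f"{flush_s:.0f} s flush duration")
        for sched in self._schedules():
            for input_id in sched.duties:
                if input_id not in self.inputs:
                    raise ConfigurationError(
                        f"phase {self.name!r} schedule references undefined "
                        f"input {input_id!r}")

    def _schedules(self) -> list[PWMSchedule]:
        if isinstance(self.schedule, Mapping):
            return list(self.schedule.values())
        return [self.schedule]

    def _any_schedule(self) -> PWMSchedule:
        return self._schedules()[0]

    def row_schedule(self, row: int, layout: DeviceLayout) -> PWMSchedule:
        if not isinstance(self.schedule, Mapping):
            return self.schedule
        for comp_id, clusters in self.mux_plan.assignments.items():
            for cluster in clusters:
                if row in cluster:
                    return self.schedule[comp_id]
        raise ConfigurationError(f"row {row} is not addressed by the mux plan")

    def row_composition(self, row: int, layout: DeviceLayout) -> dict[str, float]:
        return delivered_composition(self.row_schedule(row, layout), self.inputs)

    def duty_signature(self, row: int, layout: DeviceLayout):
        sched = self.row_schedule(row, layout)
        return tuple(sorted((k, v) for k, v in sched.duties.items() if v != 0))


@dataclass
class _CellGroup:
    """Cells sharing one circuit: a compiled model plus live state."""

    circuit_name: str
    model: CircuitModel
    rows: np.ndarray
    cols: np.ndarray
    lengths_um: np.ndarray
    y: np.ndarray

    @property
    def cell_ids(self) -> list[str]:
        return [f"r{r}c{c}" for r, c in zip(self.rows, self.cols)]


@dataclass
class ExperimentState:
    """Full chip state: per-group concentrations, valves, actuation log."""

    groups: dict[str, _CellGroup]
    layout: DeviceLayout
    time_s: float = 0.0
    valves: dict[ValveID, bool] = field(
        default_factory=lambda: dict(_INCUBATION_STATE))
    log: list[ActuationRecord] = field(default_factory=list)

    def actuate(self, valve: ValveID, open_: bool, t_s: float | None = None,
                scope: str = "chip") -> None:
        t = self.time_s if t_s is None else t_s
        if self.log and t < self.log[-1].t_s - 1e-9:
            raise ProtocolViolationError("actuation log must be time-ordered")
        self.valves[valve] = open_
        self.log.append(ActuationRecord(
            t_s=t, valve=valve.name, cell_scope=scope,
            action="open" if open_ else "close"))

    def note(self, action: str, t_s: float, valve: str = "INLET_PWM",
             scope: str = "chip") -> None:
        self.log.append(ActuationRecord(t_s=t_s, valve=valve,
                                        cell_scope=scope, action=action))

    def concentrations(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.groups[group]
        return g.model.split(g.y)


def flush(state: ExperimentState,
          compositions: Mapping[int, Mapping[str, float]] | Mapping[str, float],
          flow_duration_s: float = 60.0,
          preflush_wait_s: float = DEFAULT_PREFLUSH_WAIT_S,
          wash_first: bool = False) -> ExperimentState:
    """Replace every reservoir segment with the delivered composition.

    ``compositions`` maps row -> composition (species -> nM), or is a
    single composition for the whole chip.  The cell compartments are
    untouched: they are sealed behind the closed cell-inlet valve, and
    attempting to flush with that valve open is a protocol violation.
    Logs: open(1), a 10 s wait, the flow window, close(1), open(2).
    """
    if state.valves[ValveID.CELL_INLET]:
        raise ProtocolViolationError(
            "flush attempted with the cell-inlet valve open; the unit cells "
            "must be sealed while the exchange channel is replaced")
    t0 = state.time_s
    state.actuate(ValveID.EXCHANGE_PAIR, True, t0)
    state.note("wait", t0, valve="-")
    t_flow = t0 + preflush_wait_s
    if wash_first:
        state.note("wash_flow_start", t_flow, valve="PBS")
        state.note("wash_flow_end", t_flow + flow_duration_s, valve="PBS")
        t_flow += flow_duration_s
    state.note("flow_start", t_flow)
    state.note("flow_end", t_flow + flow_duration_s)

    per_row = bool(compositions) and all(
        isinstance(k, (int, np.integer)) for k in compositions)
    for g in state.groups.values():
        n = g.model.n_cells * g.model.n_sp
        res = g.y[n:].reshape(g.model.n_cells, g.model.n_sp)
        res[:] = 0.0
        for c in range(g.model.n_cells):
            comp = compositions[int(g.rows[c])] if per_row else compositions
            for sp, conc in comp.items():
                if sp in g.model.index:
                    res[c, g.model.index[sp]] = conc
    t_end = t_flow + flow_duration_s
    state.actuate(ValveID.EXCHANGE_PAIR, False, t_end)
    state.actuate(ValveID.CELL_INLET, True, t_end)
    return state


def incubate(state: ExperimentState, duration_s: float,
             rtol: float = 1e-8, atol: float = 1e-10) -> ExperimentState:
    """Integrate circuit kinetics plus two-compartment exchange.

    Requires the incubation posture: cell-inlet open, exchange pair
    closed.  A zero-duration incubation is the identity.
    """
    if not state.valves[ValveID.CELL_INLET]:
        raise ProtocolViolationError("incubation requires the cell inlet open")
    if state.valves[ValveID.EXCHANGE_PAIR]:
        raise ProtocolViolationError(
            "incubation requires the exchange-pair valves closed")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if duration_s == 0:
        return state
    for g in state.groups.values():
        sol = g.model.integrate(g.y, duration_s, rtol=rtol, atol=atol)
        y = sol.y[:, -1]
        # the integrator may leave tiny negative excursions; clip within
        # tolerance, fail loudly beyond it
        floor = y.min()
        if floor < -1e-6:
            raise RuntimeError(
                f"negative concentration {floor:.3g} beyond numerical "
                f"tolerance in group {g.circuit_name!r}")
        g.y = np.clip(y, 0.0, None)
    state.time_s += duration_s
    return state


def build_state(layout: DeviceLayout, plate: PlateMap,
                circuits: Mapping[str, CircuitSpec],
                params: KineticParams) -> ExperimentState:
    """Compile plate-programmed cells into per-circuit model groups.

    Each spot's ``template_id`` names a circuit (a spotted DNA mix); the
    spot's dsDNA surface fraction scales every template in that circuit.
    """
    by_circuit: dict[str, list] = {}
    for rec in plate:
        if rec.template_id not in circuits:
            raise ConfigurationError(
                f"plate references undefined circuit {rec.template_id!r}")
        by_circuit.setdefault(rec.template_id, []).append(rec)

    groups: dict[str, _CellGroup] = {}
    for name, recs in by_circuit.items():
        circuit = circuits[name]
        geoms = [layout.geometry(r.row, r.col) for r in recs]
        scale = np.array([[r.surface_fraction] * len(circuit.templates)
                          for r in recs])
        model = CircuitModel(circuit, params, geoms, g_scale=scale)
        y0 = model.initial_state()
        groups[name] = _CellGroup(
            circuit_name=name, model=model,
            rows=np.array([r.row for r in recs]),
            cols=np.array([r.col for r in recs]),
            lengths_um=np.array([layout.lengths_um[r.row, r.col] for r in recs]),
            y=y0,
        )
    return ExperimentState(groups=groups, layout=layout)


def run_protocol(layout: DeviceLayout, plate: PlateMap,
                 circuits: Mapping[str, CircuitSpec],
                 phases: Sequence[ProtocolPhase],
                 params: KineticParams | None = None,
                 sample_interval_min: float = 30.0,
                 pulses: Sequence[PulseSpec] = (),
                 record_species: Sequence[str] | None = None,
                 rtol: float = 1e-8) -> tuple[TimeSeriesTable, ExperimentState]:
    """Execute the full flush/incubate protocol over the programmed chip.

    Alternates reservoir flushes (every ``flush_period`` of the active
    phase, including one at t = 0 that first fills the exchange channel)
    with incubation integration; switches compositions at phase
    boundaries, inserting a buffer wash whenever the duty assignment
    changes; layers pulse deliveries onto flush compositions; and samples
    reporter species in every programmed cell on the exact
    ``sample_interval`` grid.  Returns the time-series table and the final
    state (which carries the actuation log).
    """
    if params is None:
        params = KineticParams()
    if not phases:
        raise ConfigurationError("at least one phase is required")
    state = build_state(layout, plate, circuits, params)

    total_h = sum(p.duration_h for p in phases)
    total_s = total_h * 3600.0

    # flush schedule: per phase, every flush_period starting at phase start
    flush_times: list[tuple[float, ProtocolPhase, bool]] = []
    t0 = 0.0
    prev_phase: ProtocolPhase | None = None
    for phase in phases:
        period_s = phase.flush_period_min * 60.0
        t = t0
        first = True
        while t < t0 + phase.duration_h * 3600.0 - 1e-9:
            needs_wash = False
            if first and prev_phase is not None:
                needs_wash = any(
                    phase.duty_signature(r, layout)
                    != prev_phase.duty_signature(r, layout)
                    for r in range(layout.n_rows))
            flush_times.append((t, phase, needs_wash))
            t += period_s
            first = False
        prev_phase = phase
        t0 += phase.duration_h * 3600.0

    sample_s = sample_interval_min * 60.0
    n_samples = int(round(total_s / sample_s))
    sample_times = [k * sample_s for k in range(n_samples + 1)
                    if k * sample_s <= total_s + 1e-9]

    events: dict[float, dict] = {}
    for t, phase, wash in flush_times:
        events.setdefault(round(t, 6), {})["flush"] = (phase, wash)
    for t in sample_times:
        events.setdefault(round(t, 6), {})["sample"] = True
    event_times = sorted(events)

    if record_species is None:
        wanted: list[str] = []
        for c in circuits.values():
            wanted.extend(c.reporters or [t.product for t in c.templates])
        record_species = list(dict.fromkeys(wanted))

    records: list[tuple] = []

    def take_sample(t_s: float) -> None:
        t_h = t_s / 3600.0
        for g in state.groups.values():
            cell, _ = g.model.split(g.y)
            for sp in record_species:
                if sp not in g.model.index:
                    continue
                vals = cell[:, g.model.index[sp]]
                for i, cid in enumerate(g.cell_ids):
                    records.append((cid, int(g.rows[i]), int(g.cols[i]),
                                    float(g.lengths_um[i]), t_h, sp,
                                    float(max(vals[i], 0.0))))

    for t_event in event_times:
        dt = t_event - state.time_s
        if dt > 1e-9:
            incubate(state, dt, rtol=rtol)
        ev = events[t_event]
        if ev.get("sample"):
            take_sample(t_event)
        if "flush" in ev:
            phase, wash = ev["flush"]
            t_h = t_event / 3600.0
            comps: dict[int, dict[str, float]] = {}
            for row in range(layout.n_rows):
                comp = dict(phase.row_composition(row, layout))
                for p in pulses:
                    if p.active(t_h):
                        comp[p.species] = comp.get(p.species, 0.0) \
                            + p.concentration_nm
                comps[row] = comp
            state.actuate(ValveID.CELL_INLET, False, t_event)
            flush(state, comps,
                  flow_duration_s=phase._any_schedule().total_flow_time_s,
                  preflush_wait_s=phase.preflush_wait_s, wash_first=wash)

    df = pd.DataFrame(records, columns=TS_COLUMNS)
    return TimeSeriesTable(df), state


def reagent_consumption(phases: Sequence[ProtocolPhase] | None = None,
                        flow_params: Mapping[str, float] | None = None) -> float:
    """Reagent consumption in uL/h: flushes/hour x flush duration x rate.

    ``flow_params`` must contain ``flow_rate_ul_min`` (the default flush
    flow rate of 0.75 uL/min is exported separately, calibrated so the
    default protocol consumes ~3 uL/h) and may override
    ``flush_period_min`` / ``flush_duration_s``.
    """
    if flow_params is None or "flow_rate_ul_min" not in flow_params:
        raise ConfigurationError("flow_params must provide 'flow_rate_ul_min'")
    rate = flow_params["flow_rate_ul_min"]
    if rate < 0:
        raise ValueError("flow rate must be >= 0")
    if phases:
        period = phases[0].flush_period_min
        duration_s = phases[0]._any_schedule().total_flow_time_s
    else:
        period = flow_params.get("flush_period_min", DEFAULT_FLUSH_PERIOD_MIN)
        duration_s = flow_params.get("flush_duration_s", 60.0)
    flushes_per_h = 60.0 / period
    return flushes_per_h * (duration_s / 60.0) * rate


def write_actuation_log(log: Sequence[ActuationRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in log:
            fh.write(rec.to_json() + "\n")


def read_actuation_log(path) -> list[ActuationRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(ActuationRecord(**d))
    return out
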