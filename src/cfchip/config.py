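"""Experiment configuration, deterministic seeding, and run manifests.

Configs are YAML documents with a strict schema: unknown keys are
rejected, defaults are resolved at load time, and the canonicalized form
round-trips byte-identically.  Every run emits a manifest recording the
config hash, package version and output inventory, so a config + seed
pair always reproduces identical data files.

A single global seed fans out to per-module streams via
``derive_seed(seed, module_name)`` (SHA-256 of ``"{seed}:{module}"``,
reduced below 2**31), making module-level randomness independent of call
order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import experiments
from .device import DeviceLayout, default_layout
from .kinetics import KineticParams, PARAM_PRESETS
from .protocol import ProtocolPhase, PulseSpec, run_protocol, write_actuation_log
from .spotting import PlateMap

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "ConfigError",
    "load_config",
    "save_config",
    "derive_seed",
    "run_experiment",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


def derive_seed(seed: int, module: str) -> int:
    digest = hashlib.sha256(f"{seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


_PHASE_KEYS = {"name", "kind", "duration_h", "flush_period_min", "zf_duties"}
_PULSE_KEYS = {"species", "concentration_nm", "start_h", "duration_h"}
_TOP_KEYS = {"layout", "plate", "circuits", "phases", "pulses",
             "kinetics", "sample_interval_min", "seed", "output_dir"}
_CIRCUIT_BUILDERS = {
    "constitutive_gfp": experiments.constitutive_gfp,
    "zf_target": experiments.zf_target_circuit,
    "tetr_repression": experiments.tetr_repression_circuit,
    "toggle": experiments.toggle_circuit,
}


@dataclass
class ExperimentConfig:
    """A fully-resolved experiment description.

    ``circuits`` maps a circuit id to ``{"kind": <builder>, **kwargs}``
    using the canned circuit builders; ``plate`` is a path to a plate-map
    CSV (resolved relative to the config file).  Phases are either the
    standard two-input expression phase or the three-input ZF titration.
    """

    plate: str
    circuits: dict[str, dict]
    phases: list[dict]
    layout: dict | None = None
    pulses: list[dict] = field(default_factory=list)
    kinetics: str | dict = "default"
    sample_interval_min: float = 30.0
    seed: int = 0
    output_dir: str = "results"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("plate", "circuits", "phases"):
            if key not in d:
                raise ConfigError(f"missing required key {key!r}")
        cfg = cls(
            plate=d["plate"],
            circuits=d["circuits"],
            phases=[dict(p) for p in d["phases"]],
            layout=d.get("layout"),
            pulses=[dict(p) for p in d.get("pulses", [])],
            kinetics=d.get("kinetics", "default"),
            sample_interval_min=d.get("sample_interval_min", 30.0),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "results"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("key 'seed' must be an integer")
        if not isinstance(self.sample_interval_min, (int, float)) \
                or self.sample_interval_min <= 0:
            raise ConfigError("key 'sample_interval_min' must be a positive number")
        for i, ph in enumerate(self.phases):
            unknown = set(ph) - _PHASE_KEYS
            if unknown:
                raise ConfigError(f"phase {i}: unknown keys {sorted(unknown)}")
            if "duration_h" not in ph:
                raise ConfigError(f"phase {i}: missing 'duration_h' (hours, > 0)")
            if not isinstance(ph["duration_h"], (int, float)) or ph["duration_h"] <= 0:
                raise ConfigError(f"phase {i}: 'duration_h' must be a positive number")
            kind = ph.get("kind", "standard")
            if kind not in ("standard", "zf_titration"):
                raise ConfigError(
                    f"phase {i}: 'kind' must be 'standard' or 'zf_titration'")
            fp = ph.get("flush_period_min", 15.0)
            if not isinstance(fp, (int, float)) or fp <= 0:
                raise ConfigError(
                    f"phase {i}: 'flush_period_min' must be a positive number")
        for i, pu in enumerate(self.pulses):
            unknown = set(pu) - _PULSE_KEYS
            if unknown:
                raise ConfigError(f"pulse {i}: unknown keys {sorted(unknown)}")
            for k in _PULSE_KEYS:
                if k != "species" and (k not in pu
                                       or not isinstance(pu[k], (int, float))):
                    raise ConfigError(f"pulse {i}: {k!r} must be a number")
        for name, spec in self.circuits.items():
            if "kind" not in spec:
                raise ConfigError(f"circuit {name!r}: missing 'kind'")
            if spec["kind"] not in _CIRCUIT_BUILDERS:
                raise ConfigError(
                    f"circuit {name!r}: unknown kind {spec['kind']!r}; "
                    f"expected one of {sorted(_CIRCUIT_BUILDERS)}")
        if isinstance(self.kinetics, str) and self.kinetics not in PARAM_PRESETS:
            raise ConfigError(
                f"unknown kinetic preset {self.kinetics!r}; "
                f"expected one of {sorted(PARAM_PRESETS)}")

    # -- canonical form ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["layout"] is None:
            del d["layout"]
        if not d["pulses"]:
            del d["pulses"]
        return d

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()

    # -- realization -------------------------------------------------------

    def build_layout(self) -> DeviceLayout:
        if self.layout is None:
            return default_layout()
        return DeviceLayout.from_dict(self.layout)

    def build_params(self) -> KineticParams:
        if isinstance(self.kinetics, str):
            return PARAM_PRESETS[self.kinetics]
        return KineticParams(**self.kinetics)

    def build_circuits(self) -> dict:
        out = {}
        for name, spec in self.circuits.items():
            kwargs = {k: v for k, v in spec.items() if k != "kind"}
            out[name] = _CIRCUIT_BUILDERS[spec["kind"]](**kwargs)
        return out

    def build_phases(self, layout: DeviceLayout) -> list[ProtocolPhase]:
        phases = []
        for ph in self.phases:
            kind = ph.get("kind", "standard")
            if kind == "standard":
                phases.append(experiments.standard_phase(
                    ph["duration_h"], name=ph.get("name", "expression"),
                    flush_period_min=ph.get("flush_period_min", 15.0)))
            else:
                duties = ph.get("zf_duties")
                duties = experiments.ZF_DUTIES if duties is None else duties
                phases.append(experiments.zf_phase(
                    ph["duration_h"], layout, zf_duties=duties))
        return phases

    def build_pulses(self) -> list[PulseSpec]:
        return [PulseSpec(p["species"], p["concentration_nm"],
                          p["start_h"], p["duration_h"]) for p in self.pulses]


def load_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    return ExperimentConfig.from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.canonical_yaml())


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    package_version: str
    started_utc: str
    finished_utc: str
    seed: int
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_experiment(cfg: ExperimentConfig, base_dir: str | Path = ".") -> RunManifest:
    """Execute a configured run and write time series, log and manifest."""
    from . import __version__

    base = Path(base_dir)
    started = datetime.now(timezone.utc).isoformat()
    layout = cfg.build_layout()
    plate = PlateMap.from_csv(base / cfg.plate, layout=layout)
    table, state = run_protocol(
        layout, plate, cfg.build_circuits(), cfg.build_phases(layout),
        params=cfg.build_params(),
        sample_interval_min=cfg.sample_interval_min,
        pulses=cfg.build_pulses())

    out_dir = base / cfg.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_path = out_dir / "timeseries.csv"
    log_path = out_dir / "actuation_log.jsonl"
    table.to_csv(ts_path)
    write_actuation_log(state.log, log_path)
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        package_version=__version__,
        started_utc=started,
        finished_utc=datetime.now(timezone.utc).isoformat(),
        seed=cfg.seed,
        outputs=[ts_path.name, log_path.name],
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
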