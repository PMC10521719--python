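"""Device geometry and diffusive exchange rates.

The chip is an array of unit-cell chemostats (default 8 rows x 35 cells =
280 chemostats).  Each unit cell communicates with an isolated segment of
the exchange channel (its "reservoir") through a connecting channel of
length ``l`` (50-450 um, fixed 25 um width, 15 um flow height).  Reagent
turnover in a cell is therefore set purely by geometry: long connecting
channels exchange slowly, short ones quickly.

Exchange is modeled as quasi-steady 1D diffusion through the connecting
channel: the molar flux between the two well-mixed compartments is
``D * A * (C_res - C_cell) / l`` with ``A`` the channel cross-section, so
each species relaxes with first-order rates

    k_cell = D * A / (l * V_cell)      (seen by the unit cell)
    k_res  = D * A / (l * V_res)       (seen by the reservoir segment)

Surface-immobilized species (biotin-anchored DNA templates) never exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "UnitCellGeometry",
    "Species",
    "DeviceLayout",
    "default_layout",
    "diffusivity_from_mw",
    "exchange_rate",
    "reservoir_exchange_rate",
    "exchange_rate_pair",
]

# -- geometry defaults (um / pL) --------------------------------------------

CHANNEL_WIDTH_UM = 25.0
CHANNEL_HEIGHT_UM = 15.0
L_MIN_UM = 50.0
L_MAX_UM = 450.0
#: the five connecting-channel lengths used on the default array
DEFAULT_LENGTHS_UM = (50.0, 150.0, 250.0, 350.0, 450.0)
DEFAULT_CELL_VOLUME_PL = 500.0
DEFAULT_RESERVOIR_VOLUME_PL = 250.0

#: reference diffusivity for the ~27 kDa fluorescent-protein class, um^2/s
D_ANCHOR_UM2_S = 90.0
ANCHOR_MW_KDA = 27.0

UM3_PER_PL = 1.0e3  # 1 pL = 1e-12 L = 1e3 um^3

DIFFUSIBLE = "diffusible"
SURFACE_BOUND = "surface_bound"


@dataclass(frozen=True)
class UnitCellGeometry:
    """Geometry of one chemostat and its exchange-channel segment."""

    connecting_length_um: float
    channel_width_um: float = CHANNEL_WIDTH_UM
    channel_height_um: float = CHANNEL_HEIGHT_UM
    cell_volume_pl: float = DEFAULT_CELL_VOLUME_PL
    reservoir_volume_pl: float = DEFAULT_RESERVOIR_VOLUME_PL

    def __post_init__(self) -> None:
        l = self.connecting_length_um
        if not (L_MIN_UM <= l <= L_MAX_UM):
            raise ValueError(
                f"connecting length {l} um outside the fabricated range "
                f"[{L_MIN_UM}, {L_MAX_UM}] um"
            )
        for name in ("channel_width_um", "channel_height_um",
                     "cell_volume_pl", "reservoir_volume_pl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def cross_section_um2(self) -> float:
        return self.channel_width_um * self.channel_height_um


@dataclass(frozen=True)
class Species:
    """A molecular species carried by the simulation.

    ``diffusivity_um2_s`` is derived from the molecular weight by cube-root
    Stokes-Einstein scaling when not given explicitly.  Surface-bound
    species (anchored DNA templates) have zero exchange regardless of any
    nominal diffusivity.
    """

    name: str
    molecular_weight_kda: float = ANCHOR_MW_KDA
    diffusivity_um2_s: float | None = None
    mobility_class: str = DIFFUSIBLE

    def __post_init__(self) -> None:
        if self.mobility_class not in (DIFFUSIBLE, SURFACE_BOUND):
            raise ValueError(f"unknown mobility class {self.mobility_class!r}")
        if self.diffusivity_um2_s is None:
            object.__setattr__(
                self, "diffusivity_um2_s",
                diffusivity_from_mw(self.molecular_weight_kda))
        if self.diffusivity_um2_s < 0:
            raise ValueError("diffusivity must be >= 0")


def diffusivity_from_mw(mw_kda: float, d_anchor: float = D_ANCHOR_UM2_S) -> float:
    """Diffusivity (um^2/s) from molecular weight by cube-root scaling.

    D(mw) = D_anchor * (27 / mw)^(1/3), anchored to the ~27 kDa
    fluorescent-protein tracer class.
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be > 0")
    return d_anchor * (ANCHOR_MW_KDA / mw_kda) ** (1.0 / 3.0)


def exchange_rate(geometry: UnitCellGeometry, species: Species) -> float:
    """First-order exchange rate (1/s) seen by the unit cell.

    k_cell = D * A / (l * V_cell); zero for surface-bound species.
    """
    return exchange_rate_pair(geometry, species)[0]


def reservoir_exchange_rate(geometry: UnitCellGeometry, species: Species) -> float:
    """Conjugate rate (1/s) seen by the reservoir segment: D*A/(l*V_res)."""
    return exchange_rate_pair(geometry, species)[1]


def exchange_rate_pair(geometry: UnitCellGeometry,
                       species: Species) -> tuple[float, float]:
    """(k_cell, k_res) in 1/s for one species through one connecting channel."""
    if species.mobility_class == SURFACE_BOUND:
        return 0.0, 0.0
    l = geometry.connecting_length_um
    if l <= 0:
        raise ValueError("connecting length must be > 0")
    d_a = species.diffusivity_um2_s * geometry.cross_section_um2
    k_cell = d_a / (l * geometry.cell_volume_pl * UM3_PER_PL)
    k_res = d_a / (l * geometry.reservoir_volume_pl * UM3_PER_PL)
    return k_cell, k_res


@dataclass
class DeviceLayout:
    """The chemostat array: per-cell geometry plus multiplexer row clusters.

    ``lengths_um`` has shape (n_rows, cells_per_row).  ``mux_clusters``
    partitions row indices into addressable groups; by default every row is
    its own cluster.
    """

    n_rows: int = 8
    cells_per_row: int = 35
    lengths_um: np.ndarray | None = None
    channel_width_um: float = CHANNEL_WIDTH_UM
    channel_height_um: float = CHANNEL_HEIGHT_UM
    cell_volume_pl: float = DEFAULT_CELL_VOLUME_PL
    reservoir_volume_pl: float = DEFAULT_RESERVOIR_VOLUME_PL
    mux_clusters: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.cells_per_row <= 0:
            raise ValueError("layout dimensions must be positive")
        if self.lengths_um is None:
            row = [DEFAULT_LENGTHS_UM[j % len(DEFAULT_LENGTHS_UM)]
                   for j in range(self.cells_per_row)]
            self.lengths_um = np.array([row] * self.n_rows, dtype=float)
        else:
            self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.lengths_um.shape != (self.n_rows, self.cells_per_row):
            raise ValueError(
                f"lengths_um shape {self.lengths_um.shape} != "
                f"({self.n_rows}, {self.cells_per_row})")
        if not self.mux_clusters:
            self.mux_clusters = [[r] for r in range(self.n_rows)]
        self.validate()

    # -- derived -----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.cells_per_row

    def geometry(self, row: int, col: int) -> UnitCellGeometry:
        return UnitCellGeometry(
            connecting_length_um=float(self.lengths_um[row, col]),
            channel_width_um=self.channel_width_um,
            channel_height_um=self.channel_height_um,
            cell_volume_pl=self.cell_volume_pl,
            reservoir_volume_pl=self.reservoir_volume_pl,
        )

    def validate(self) -> None:
        """Check geometric and multiplexer invariants; raise on violation."""
        lo, hi = self.lengths_um.min(), self.lengths_um.max()
        if lo < L_MIN_UM or hi > L_MAX_UM:
            raise ValueError(
                f"connecting lengths [{lo}, {hi}] outside [{L_MIN_UM}, {L_MAX_UM}] um")
        for name in ("channel_width_um", "channel_height_um",
                     "cell_volume_pl", "reservoir_volume_pl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        seen: set[int] = set()
        for cluster in self.mux_clusters:
            for r in cluster:
                if not 0 <= r < self.n_rows:
                    raise ValueError(f"mux cluster references missing row {r}")
                if r in seen:
                    raise ValueError(f"row {r} assigned to more than one cluster")
                seen.add(r)
        if seen != set(range(self.n_rows)):
            missing = sorted(set(range(self.n_rows)) - seen)
            raise ValueError(f"rows {missing} belong to no mux cluster")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "cells_per_row": self.cells_per_row,
            "lengths_um": self.lengths_um.tolist(),
            "widths_um": self.channel_width_um,
            "height_um": self.channel_height_um,
            "volumes_pl": {"cell": self.cell_volume_pl,
                           "reservoir": self.reservoir_volume_pl},
            "mux_clusters": [list(c) for c in self.mux_clusters],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceLayout":
        vols = d.get("volumes_pl", {})
        return cls(
            n_rows=d["rows"],
            cells_per_row=d["cells_per_row"],
            lengths_um=np.asarray(d["lengths_um"], dtype=float),
            channel_width_um=d.get("widths_um", CHANNEL_WIDTH_UM),
            channel_height_um=d.get("height_um", CHANNEL_HEIGHT_UM),
            cell_volume_pl=vols.get("cell", DEFAULT_CELL_VOLUME_PL),
            reservoir_volume_pl=vols.get("reservoir", DEFAULT_RESERVOIR_VOLUME_PL),
            mux_clusters=[list(c) for c in d.get("mux_clusters", [])],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DeviceLayout":
        return cls.from_dict(yaml.safe_load(text))

    def with_volumes(self, cell_volume_pl: float,
                     reservoir_volume_pl: float) -> "DeviceLayout":
        return replace(self, cell_volume_pl=cell_volume_pl,
                       reservoir_volume_pl=reservoir_volume_pl,
                       lengths_um=self.lengths_um.copy(),
                       mux_clusters=[list(c) for c in self.mux_clusters])


def default_layout(lengths_um: Sequence[float] = DEFAULT_LENGTHS_UM,
                   n_rows: int = 8, cells_per_row: int = 35) -> DeviceLayout:
    """The default array: 8 rows x 35 chemostats, connecting lengths cycling
    over five values spanning 50-450 um, one mux cluster per row."""
    row = [float(lengths_um[j % len(lengths_um)]) for j in range(cells_per_row)]
    return DeviceLayout(
        n_rows=n_rows,
        cells_per_row=cells_per_row,
        lengths_um=np.array([row] * n_rows, dtype=float),
    )
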