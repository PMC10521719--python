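"""DNA programming of unit cells by microarray spotting.

Each unit cell is programmed by a spotted mixture of biotinylated dsDNA
template and short biotinylated ssDNA oligo.  Both compete with equal
per-molecule affinity for a saturating pool of biotin-binding surface
sites, so the fraction of sites carrying expressible template is simply
``ds / (ds + ss)`` — the spotting ratio, not the absolute amount, sets the
surface template density.  Plate maps are CSV files with header
``row,col,template_id,ds_nM,ss_nM``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .device import DeviceLayout

__all__ = [
    "SpotRecord",
    "PlateMap",
    "dsdna_surface_fraction",
    "effective_template_density",
    "validate_ratio",
    "dilution_series_plate",
]

#: spotting ratios above this (ds:ss above 1:5) risk template overloading
MAX_DS_SS_RATIO = 1.0 / 5.0

#: default surface-chemistry constants used to convert a bound-template
#: surface density into an effective solution-phase concentration
DEFAULT_SITE_DENSITY_UM2 = 6000.0   # biotin-binding sites / um^2
DEFAULT_PATTERNED_AREA_UM2 = 500.0  # neutrAvidin-coated circle / unit cell
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class SpotRecord:
    """One spotted position: template identity plus ds/ss concentrations (nM)."""

    row: int
    col: int
    template_id: str
    ds_conc_nm: float
    ss_conc_nm: float

    def __post_init__(self) -> None:
        if self.ds_conc_nm < 0 or self.ss_conc_nm < 0:
            raise ValueError("spotted concentrations must be >= 0")

    @property
    def surface_fraction(self) -> float:
        return dsdna_surface_fraction(self.ds_conc_nm, self.ss_conc_nm)


@dataclass
class PlateMap:
    """Ordered collection of spot records aligned to a device layout."""

    records: list[SpotRecord] = field(default_factory=list)
    layout: DeviceLayout | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for rec in self.records:
            key = (rec.row, rec.col)
            if key in seen:
                raise ValueError(f"duplicate spot at (row={rec.row}, col={rec.col})")
            seen.add(key)
            if self.layout is not None:
                if not (0 <= rec.row < self.layout.n_rows
                        and 0 <= rec.col < self.layout.cells_per_row):
                    raise ValueError(
                        f"spot (row={rec.row}, col={rec.col}) outside the "
                        f"{self.layout.n_rows}x{self.layout.cells_per_row} layout")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.row, r.col, r.template_id, r.ds_conc_nm, r.ss_conc_nm)
             for r in self.records],
            columns=["row", "col", "template_id", "ds_nM", "ss_nM"],
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   layout: DeviceLayout | None = None) -> "PlateMap":
        records = [
            SpotRecord(int(r.row), int(r.col), str(r.template_id),
                       float(r.ds_nM), float(r.ss_nM))
            for r in df.itertuples(index=False)
        ]
        return cls(records=records, layout=layout)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase,
                 layout: DeviceLayout | None = None) -> "PlateMap":
        return cls.from_frame(pd.read_csv(path), layout=layout)


def dsdna_surface_fraction(ds_nm: float, ss_nm: float,
                           relative_affinity: float = 1.0) -> float:
    """Fraction of surface sites carrying dsDNA template.

    Equal-affinity competition for saturating biotin-binding sites gives
    ``a*ds / (a*ds + ss)`` with the relative per-molecule affinity ``a`` of
    template versus oligo (default 1: both carry a single biotin).
    """
    if ds_nm < 0 or ss_nm < 0:
        raise ValueError("concentrations must be >= 0")
    if relative_affinity <= 0:
        raise ValueError("relative affinity must be > 0")
    denom = relative_affinity * ds_nm + ss_nm
    if denom == 0:
        raise ValueError("ds + ss must be > 0 (empty spot has no occupancy)")
    return relative_affinity * ds_nm / denom


def effective_template_density(
    fraction: float,
    site_density_um2: float = DEFAULT_SITE_DENSITY_UM2,
    patterned_area_um2: float = DEFAULT_PATTERNED_AREA_UM2,
    cell_volume_pl: float = 500.0,
) -> float:
    """Effective solution-phase template concentration G (nM).

    Converts the bound template count (fraction of occupied sites times
    site density times patterned area) into the concentration the reaction
    volume experiences: ``count / (N_A * V)``.
    """
    if fraction < 0 or site_density_um2 < 0 or patterned_area_um2 < 0:
        raise ValueError("all inputs must be >= 0")
    if cell_volume_pl <= 0:
        raise ValueError("cell volume must be > 0")
    count = fraction * site_density_um2 * patterned_area_um2
    volume_l = cell_volume_pl * 1e-12
    return count / (AVOGADRO * volume_l) * 1e9


def validate_ratio(plate: PlateMap,
                   max_ratio: float = MAX_DS_SS_RATIO) -> list[str]:
    """Warn for every spot whose ds:ss ratio exceeds the recommended bound.

    High-ratio spots produce template densities at which reagent exchange
    cannot sustain peak expression (early overshoot).  Returns warning
    strings; never mutates the plate.
    """
    warnings = []
    for rec in plate:
        if rec.ss_conc_nm == 0:
            ratio = float("inf") if rec.ds_conc_nm > 0 else 0.0
        else:
            ratio = rec.ds_conc_nm / rec.ss_conc_nm
        if ratio > max_ratio:
            warnings.append(
                f"spot (row={rec.row}, col={rec.col}, template={rec.template_id}): "
                f"ds:ss ratio {rec.ds_conc_nm:g}:{rec.ss_conc_nm:g} exceeds "
                f"the recommended 1:{1 / max_ratio:g} upper bound")
    return warnings


def dilution_series_plate(layout: DeviceLayout, template_id: str,
                          fractions: list[float], total_nm: float = 100.0,
                          row: int = 0) -> PlateMap:
    """Plate map spotting a template dilution series along one row.

    Each fraction f becomes a spot with ds = f*total and ss = (1-f)*total,
    so the surface fraction equals f exactly under equal-affinity binding.
    """
    if len(fractions) > layout.cells_per_row:
        raise ValueError("more dilutions than cells in a row")
    records = [
        SpotRecord(row, col, template_id,
                   ds_conc_nm=f * total_nm, ss_conc_nm=(1.0 - f) * total_nm)
        for col, f in enumerate(fractions)
    ]
    return PlateMap(records=records, layout=layout)
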