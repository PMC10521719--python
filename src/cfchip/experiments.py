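"""Canned circuits and experiment builders for the three standard assays.

* constitutive characterization: one unregulated GFP template per cell,
  across template dilutions and connecting-channel lengths;
* the zinc-finger (ZF) repression screen: four PWM-formulated ZF doses x
  twelve promoter variants x five geometries (240 conditions), the ZF
  delivered as a purified mScarlet-tagged protein through the lysate
  half-cycle;
* small-molecule circuits: the TetR/aTc derepression assay and the
  TetR-LacI toggle switch flipped by IPTG pulses.

The twelve-variant Kd ladder is SYNTHETIC: the real operator-site
affinities are not published alongside the device, so the panel uses
placeholder dissociation constants spanning the dynamic range from
consensus (2 nM) to nonspecific binding (1 uM), plus two variants with
the operator deleted (fully ablated repression).
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .device import DeviceLayout, default_layout, DEFAULT_LENGTHS_UM
from .kinetics import (
    CircuitSpec,
    GeneTemplate,
    InducerBinding,
    OperatorSite,
    K_ATC_NM,
    K_IPTG_NM,
    MW_ATC_KDA,
    MW_IPTG_KDA,
    MW_ZF_MSCARLET_KDA,
)
from .protocol import ProtocolPhase, PulseSpec
from .pwm import (
    ENERGY_DUTY,
    InputSolution,
    MuxPlan,
    PWMSchedule,
    assign_mux,
    DEFAULT_CYCLE_PERIOD_MS,
    DEFAULT_N_CYCLES,
    THREE_INPUT_CYCLE_PERIOD_MS,
    THREE_INPUT_N_CYCLES,
)
from .spotting import PlateMap, SpotRecord, effective_template_density

__all__ = [
    "G_MAX_NM",
    "LOW_DENSITY_FRACTION",
    "HIGH_DENSITY_FRACTION",
    "ZF_PANEL_KDS_NM",
    "ZF_STOCK_NM",
    "constitutive_gfp",
    "zf_target_circuit",
    "zf_panel_circuits",
    "tetr_repression_circuit",
    "toggle_circuit",
    "standard_inputs",
    "standard_phase",
    "zf_inputs",
    "zf_phase",
    "zf_screen_plan",
    "characterization_plate",
    "zf_screen_plate",
    "ZF_DUTIES",
]

#: effective template concentration of an undiluted spot (all binding
#: sites carry template), from the default surface-chemistry constants
G_MAX_NM = effective_template_density(1.0)

#: spotting fractions bracketing the recommended ds:ss operating range
LOW_DENSITY_FRACTION = 1.0 / 11.0   # ds:ss = 1:10, the routine density
HIGH_DENSITY_FRACTION = 1.0 / 2.0   # ds:ss = 1:1, overshoot regime

#: ZF-mScarlet stock in the dosed lysate solution (nM; 5 uM)
ZF_STOCK_NM = 5000.0
#: the four PWM-formulated ZF duty levels (negative control first)
ZF_DUTIES = (Fraction(0), Fraction(1, 10), Fraction(1, 4), Fraction(1, 2))

#: synthetic operator-variant dissociation constants (nM); None = operator
#: deleted, repression fully ablated
ZF_PANEL_KDS_NM: dict[str, float | None] = {
    "wt": 2.0,
    "m1": 4.0, "m2": 8.0, "m3": 16.0, "m4": 32.0, "m5": 64.0,
    "m6": 125.0, "m7": 250.0, "m8": 500.0, "m9": 1000.0,
    "abl_d9a": None, "abl_5t": None,
}

#: operator affinities of the small-molecule circuits (nM, effective)
KD_TET_OPERATOR_NM = 10.0
KD_LAC_OPERATOR_NM = 5.0
KD_TET_TOGGLE_NM = 10.0
#: inducer binding is cooperative (TetR and LacI each carry two
#: inducer-binding subunits)
HILL_ATC = 2.0
HILL_IPTG = 2.0

MW_TETR_KDA = 46.0
MW_LACI_KDA = 150.0


# -- circuits ----------------------------------------------------------------


def constitutive_gfp(g_nm: float = G_MAX_NM) -> CircuitSpec:
    """A single unregulated GFP template."""
    return CircuitSpec(
        name="constitutive_gfp",
        templates=[GeneTemplate(id="gfp", product="GFP", g_nm=g_nm)],
        reporters=["GFP"],
    )


def zf_target_circuit(variant: str, kd_nm: float | None,
                      g_nm: float = G_MAX_NM, n_sites: int = 1) -> CircuitSpec:
    """GFP reporter whose promoter carries ZF operator site(s).

    ``kd_nm=None`` models an ablated binding site (no repression).  The ZF
    itself is a supplied, PWM-formulated protein, not expressed on-chip.
    """
    operators = () if kd_nm is None else tuple(
        OperatorSite(tf_id="ZF", kd_nm=kd_nm) for _ in range(n_sites))
    return CircuitSpec(
        name=f"zf_{variant}",
        templates=[GeneTemplate(id=f"zf_{variant}", product="GFP",
                                operators=operators, g_nm=g_nm)],
        supplied={"ZF": MW_ZF_MSCARLET_KDA},
        reporters=["GFP"],
    )


def zf_panel_circuits(g_nm: float | None = None,
                      n_sites: int = 1) -> dict[str, CircuitSpec]:
    """The twelve-variant promoter panel (synthetic Kd ladder)."""
    g = G_MAX_NM * LOW_DENSITY_FRACTION if g_nm is None else g_nm
    return {f"zf_{v}": zf_target_circuit(v, kd, g_nm=g, n_sites=n_sites)
            for v, kd in ZF_PANEL_KDS_NM.items()}


def tetr_repression_circuit(g_gfp_nm: float, g_tetr_nm: float) -> CircuitSpec:
    """aTc-controllable repression: constitutive TetR represses a GFP
    template carrying the Tet operator unless aTc sequesters TetR."""
    return CircuitSpec(
        name="tetr_repression",
        templates=[
            GeneTemplate(id="tetr", product="TetR", g_nm=g_tetr_nm,
                         product_mw_kda=MW_TETR_KDA),
            GeneTemplate(id="gfp_teto", product="GFP",
                         operators=(OperatorSite("TetR", KD_TET_OPERATOR_NM),),
                         g_nm=g_gfp_nm),
        ],
        supplied={"aTc": MW_ATC_KDA},
        inducer_bindings=[InducerBinding("TetR", "aTc", K_ATC_NM, HILL_ATC)],
        reporters=["GFP"],
    )


def toggle_circuit(g_reporter_nm: float = 8.0, g_tetr_nm: float = 20.0,
                   g_laci_nm: float = 20.0,
                   symmetric: bool = False) -> CircuitSpec:
    """The TetR-LacI toggle switch with a Lac-repressible GFP reporter.

    TetR is expressed from a LacI-repressible promoter and LacI from a
    TetR-repressible one; each promoter carries two operator sites.  LacI
    binds its operator more tightly than TetR does (5 vs 30 nM), so from a
    cold start the circuit settles into the LacI-high / GFP-low state; an
    IPTG pulse sequesters LacI and flips it to the TetR-high / GFP-high
    state, which persists.  ``symmetric=True`` equalizes the operator
    affinities and repressor sizes exactly (used to probe the
    indeterminate symmetric configuration).
    """
    kd_lac = KD_LAC_OPERATOR_NM
    kd_tet = kd_lac if symmetric else KD_TET_TOGGLE_NM
    mw_laci = MW_TETR_KDA if symmetric else MW_LACI_KDA
    lac_sites = tuple(OperatorSite("LacI", kd_lac) for _ in range(2))
    tet_sites = tuple(OperatorSite("TetR", kd_tet) for _ in range(2))
    return CircuitSpec(
        name="toggle",
        templates=[
            GeneTemplate(id="placo_tetr", product="TetR", operators=lac_sites,
                         g_nm=g_tetr_nm, product_mw_kda=MW_TETR_KDA),
            GeneTemplate(id="pteto_laci", product="LacI", operators=tet_sites,
                         g_nm=g_laci_nm, product_mw_kda=mw_laci),
            GeneTemplate(id="placo_gfp", product="GFP", operators=lac_sites,
                         g_nm=g_reporter_nm),
        ],
        supplied={"IPTG": MW_IPTG_KDA, "aTc": MW_ATC_KDA},
        inducer_bindings=[
            InducerBinding("LacI", "IPTG", K_IPTG_NM, HILL_IPTG),
            InducerBinding("TetR", "aTc", K_ATC_NM, HILL_ATC),
        ],
        reporters=["GFP"],
    )


# -- input solutions and phases ----------------------------------------------

#: resource units carried by each stock so that any 1:1 lysate:energy mix
#: delivers exactly the standard supply level
_E_STOCK = 200.0


def standard_inputs() -> dict[str, InputSolution]:
    """Two-input operation: lysate + energy at 1:1."""
    return {
        "lysate": InputSolution("lysate", 0, "lysate", {"E": _E_STOCK / 2}),
        "energy": InputSolution("energy", 1, "energy", {"E": _E_STOCK / 2}),
    }


def standard_phase(duration_h: float, name: str = "expression",
                   flush_period_min: float = 15.0) -> ProtocolPhase:
    """The basic two-input flush phase: 600 ms cycles, 50% duty, 100 cycles."""
    schedule = PWMSchedule(
        cycle_period_ms=DEFAULT_CYCLE_PERIOD_MS,
        duties={"lysate": ENERGY_DUTY, "energy": ENERGY_DUTY},
        n_cycles=DEFAULT_N_CYCLES)
    return ProtocolPhase(name=name, duration_h=duration_h, schedule=schedule,
                         inputs=standard_inputs(),
                         flush_period_min=flush_period_min)


def zf_inputs() -> dict[str, InputSolution]:
    """Three-input operation: plain lysate, ZF-dosed lysate, energy."""
    return {
        "plain_lysate": InputSolution("plain_lysate", 0, "lysate",
                                      {"E": _E_STOCK / 2}),
        "zf_lysate": InputSolution("zf_lysate", 1, "lysate",
                                   {"E": _E_STOCK / 2, "ZF": ZF_STOCK_NM}),
        "energy": InputSolution("energy", 2, "energy", {"E": _E_STOCK / 2}),
    }


def _zf_schedule(zf_duty: Fraction) -> PWMSchedule:
    duties = {"energy": ENERGY_DUTY,
              "plain_lysate": ENERGY_DUTY - zf_duty,
              "zf_lysate": zf_duty}
    return PWMSchedule(cycle_period_ms=THREE_INPUT_CYCLE_PERIOD_MS,
                       duties=duties, n_cycles=THREE_INPUT_N_CYCLES)


def zf_phase(duration_h: float, layout: DeviceLayout,
             zf_duties=ZF_DUTIES) -> ProtocolPhase:
    """ZF titration phase: one formulated ZF dose per mux row cluster."""
    comp_ids = [f"zf_duty_{float(d):g}" for d in zf_duties]
    plan: MuxPlan = assign_mux(comp_ids, layout)
    schedules = {cid: _zf_schedule(d) for cid, d in zip(comp_ids, zf_duties)}
    return ProtocolPhase(name="zf_titration", duration_h=duration_h,
                         schedule=schedules, inputs=zf_inputs(),
                         mux_plan=plan)


# -- plates and plans ---------------------------------------------------------


def characterization_plate(layout: DeviceLayout,
                           fraction: float = LOW_DENSITY_FRACTION,
                           lengths_um=DEFAULT_LENGTHS_UM,
                           row: int = 0) -> PlateMap:
    """One constitutive spot per connecting-channel length at one density.

    The default layout cycles the five lengths along each row, so columns
    0..4 cover all five geometries.
    """
    total = 110.0
    records = [
        SpotRecord(row, col, "constitutive_gfp",
                   ds_conc_nm=fraction * total,
                   ss_conc_nm=(1.0 - fraction) * total)
        for col in range(len(lengths_um))
    ]
    return PlateMap(records=records, layout=layout)


def zf_screen_plan(zf_duties=ZF_DUTIES,
                   variants=tuple(ZF_PANEL_KDS_NM),
                   lengths_um=DEFAULT_LENGTHS_UM) -> pd.DataFrame:
    """Enumerate the full repression screen: every (ZF dose x promoter
    variant x geometry) combination; 4 x 12 x 5 = 240 conditions."""
    rows = []
    for duty in zf_duties:
        for v in variants:
            for l in lengths_um:
                rows.append({
                    "zf_duty": float(duty),
                    "delivered_zf_nm": float(duty) * ZF_STOCK_NM,
                    "template_id": f"zf_{v}",
                    "kd_nm": ZF_PANEL_KDS_NM[v],
                    "length_um": float(l),
                })
    return pd.DataFrame(rows)


def zf_screen_plate(layout: DeviceLayout,
                    fraction: float = LOW_DENSITY_FRACTION,
                    variants=tuple(ZF_PANEL_KDS_NM),
                    n_lengths: int = len(DEFAULT_LENGTHS_UM)) -> PlateMap:
    """Spot the variant panel into every mux cluster.

    Within each cluster the 60 (variant x length) spots are laid out
    row-major; because the default layout cycles five lengths along each
    row, spot index ``5*t + k`` automatically lands on length ``k``.
    """
    total = 110.0
    n_clusters = 4
    rows_per_cluster = layout.n_rows // n_clusters
    records = []
    for cluster in range(n_clusters):
        base_row = cluster * rows_per_cluster
        idx = 0
        for v in variants:
            for _ in range(n_lengths):
                r = base_row + idx // layout.cells_per_row
                c = idx % layout.cells_per_row
                records.append(SpotRecord(
                    r, c, f"zf_{v}",
                    ds_conc_nm=fraction * total,
                    ss_conc_nm=(1.0 - fraction) * total))
                idx += 1
    return PlateMap(records=records, layout=layout)


def atc_pulse(start_h: float = 7.0, duration_h: float = 3.0,
              delivered_nm: float = 2500.0) -> PulseSpec:
    """An aTc pulse: 5 uM stock in the energy solution at 50% duty."""
    return PulseSpec("aTc", delivered_nm, start_h, duration_h)


def iptg_pulse(start_h: float = 7.0, duration_h: float = 3.0,
               delivered_nm: float = 125_000.0) -> PulseSpec:
    """An IPTG pulse: 250 uM stock in the energy solution at 50% duty."""
    return PulseSpec("IPTG", delivered_nm, start_h, duration_h)
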