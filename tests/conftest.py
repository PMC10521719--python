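"""Shared fixtures: the expensive pipeline simulations run once per session."""

import numpy as np
import pytest

from cfchip.device import default_layout
from cfchip.kinetics import KineticParams
from cfchip.protocol import run_protocol
from cfchip.spotting import PlateMap, SpotRecord
from cfchip import experiments as exp


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def params():
    return KineticParams()


def _characterization(layout, fraction, hours=16.0):
    plate = exp.characterization_plate(layout, fraction=fraction)
    table, state = run_protocol(
        layout, plate, {"constitutive_gfp": exp.constitutive_gfp()},
        [exp.standard_phase(hours)])
    return table, state


@pytest.fixture(scope="session")
def char_low(layout):
    """Constitutive characterization at the routine 1:10 spotting density."""
    return _characterization(layout, exp.LOW_DENSITY_FRACTION)


@pytest.fixture(scope="session")
def char_high(layout):
    """Constitutive characterization at the overloaded 1:1 density."""
    return _characterization(layout, exp.HIGH_DENSITY_FRACTION)


@pytest.fixture(scope="session")
def zf_screen(layout):
    """The full 4 x 12 x 5 ZF repression screen (240 programmed cells)."""
    plate = exp.zf_screen_plate(layout)
    circuits = exp.zf_panel_circuits()
    phases = [exp.standard_phase(6.5), exp.zf_phase(13.5, layout)]
    table, state = run_protocol(layout, plate, circuits, phases)
    return table, state


def zf_cell_id(cluster: int, variant_index: int, length_index: int) -> str:
    """Cell holding (variant, length) inside a ZF dose cluster (2 rows)."""
    idx = 5 * variant_index + length_index
    return f"r{2 * cluster + idx // 35}c{idx % 35}"


@pytest.fixture(scope="session")
def toggle_series(layout):
    """Toggle switch at four reporter template concentrations, l = 50 um,
    with a 3 h IPTG pulse starting at 7 h."""
    reporter_nm = (2.0, 4.0, 8.0, 16.0)
    circuits = {}
    records = []
    for i, g in enumerate(reporter_nm):
        name = f"toggle_r{i}"
        circuits[name] = exp.toggle_circuit(g_reporter_nm=g)
        records.append(SpotRecord(0, i * 5, name, 10.0, 100.0))
    plate = PlateMap(records, layout)
    table, state = run_protocol(
        layout, plate, circuits, [exp.standard_phase(20.0)],
        pulses=[exp.iptg_pulse(7.0, 3.0)],
        record_species=["GFP", "TetR", "LacI"])
    return reporter_nm, table, state


@pytest.fixture(scope="session")
def atc_assay(layout):
    """TetR/aTc assay: TetR titration at l = 50 plus a length sweep at the
    highest TetR template concentration; 3 h aTc pulse from 7 h."""
    tetr_nm = (0.0, 5.0, 10.0, 20.0)
    circuits = {}
    records = []
    for i, g in enumerate(tetr_nm):
        name = f"tetr{i}"
        circuits[name] = exp.tetr_repression_circuit(8.0, g)
        records.append(SpotRecord(0, i * 5, name, 10.0, 100.0))
    for k in range(5):  # cols 20-24 cycle through the five lengths
        records.append(SpotRecord(1, 20 + k, "tetr3", 10.0, 100.0))
    plate = PlateMap(records, layout)
    table, state = run_protocol(
        layout, plate, circuits, [exp.standard_phase(16.0)],
        pulses=[exp.atc_pulse(7.0, 3.0)],
        record_species=["GFP", "aTc"])
    return tetr_nm, table, state
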