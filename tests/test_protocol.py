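"""Protocol engine: valve sequencing, flush/incubate, sampling, logs."""

import numpy as np
import pytest

from cfchip.device import Species, default_layout, exchange_rate_pair
from cfchip.kinetics import PARAM_PRESETS, KineticParams, steady_state_constitutive
from cfchip.protocol import (
    ConfigurationError,
    ProtocolViolationError,
    ValveID,
    build_state,
    flush,
    incubate,
    reagent_consumption,
    run_protocol,
)
from cfchip.spotting import PlateMap, SpotRecord
from cfchip import experiments as exp


def _single_cell_state(params=None, g_nm=1.0, col=0):
    layout = default_layout()
    plate = PlateMap([SpotRecord(0, col, "c", 110.0, 0.0)], layout)
    circuits = {"c": exp.constitutive_gfp(g_nm)}
    return build_state(layout, plate, circuits, params or KineticParams())


class TestFlush:
    def test_sealed_cell_is_untouched(self):
        state = _single_cell_state()
        g = state.groups["c"]
        cell, _ = g.model.split(g.y)
        cell[0, g.model.index["GFP"]] = 7.0
        state.actuate(ValveID.CELL_INLET, False)
        flush(state, {"E": 100.0})
        cell_after, res_after = state.concentrations("c")
        assert cell_after[0, g.model.index["GFP"]] == 7.0

    def test_reservoir_is_exactly_the_delivered_composition(self):
        state = _single_cell_state()
        state.actuate(ValveID.CELL_INLET, False)
        flush(state, {"E": 42.0, "aTc": 5.0})
        g = state.groups["c"]
        _, res = state.concentrations("c")
        assert res[0, g.model.index["E"]] == 42.0
        # species unknown to the circuit are simply not carried
        assert "aTc" not in g.model.index

    def test_flush_with_open_inlet_is_a_protocol_violation(self):
        state = _single_cell_state()  # initial posture: inlet open
        with pytest.raises(ProtocolViolationError, match="sealed"):
            flush(state, {"E": 100.0})

    def test_log_contains_wait_between_valve_open_and_flow(self):
        state = _single_cell_state()
        state.actuate(ValveID.CELL_INLET, False)
        flush(state, {"E": 100.0}, preflush_wait_s=10.0)
        actions = [(r.valve, r.action) for r in state.log]
        i_open = actions.index(("EXCHANGE_PAIR", "open"))
        i_flow = actions.index(("INLET_PWM", "flow_start"))
        assert ("-", "wait") in actions[i_open:i_flow]
        t_open = state.log[i_open].t_s
        t_flow = next(r.t_s for r in state.log if r.action == "flow_start")
        assert t_flow - t_open == pytest.approx(10.0)


class TestIncubate:
    def test_zero_duration_is_identity(self):
        state = _single_cell_state()
        y_before = state.groups["c"].y.copy()
        incubate(state, 0.0)
        assert np.array_equal(state.groups["c"].y, y_before)

    def test_incubation_with_exchange_pair_open_rejected(self):
        state = _single_cell_state()
        state.valves[ValveID.EXCHANGE_PAIR] = True
        with pytest.raises(ProtocolViolationError):
            incubate(state, 60.0)


def _tiny_run(hours=2.0, **kwargs):
    layout = default_layout()
    plate = PlateMap([SpotRecord(0, 0, "c", 10.0, 100.0)], layout)
    return run_protocol(layout, plate, {"c": exp.constitutive_gfp()},
                        [exp.standard_phase(hours)], **kwargs)


class TestRunProtocol:
    def test_twenty_hour_run_logs_eighty_flushes(self):
        # 20 h / 15 min, counting the flush that fills the channel at t=0
        table, state = _tiny_run(hours=20.0)
        n_flushes = sum(1 for r in state.log if r.action == "flow_start")
        assert n_flushes == 80

    def test_cell_without_template_stays_dark(self):
        layout = default_layout()
        plate = PlateMap([SpotRecord(0, 0, "c", 0.0, 110.0)], layout)
        table, _ = run_protocol(layout, plate, {"c": exp.constitutive_gfp()},
                                [exp.standard_phase(6.0)])
        _, v = table.trace("r0c0", "GFP")
        assert np.all(v < 1e-9)

    def test_sampling_grid_is_exact(self):
        table, _ = _tiny_run(hours=3.0)
        times_min = np.unique(table.frame["time_h"].to_numpy()) * 60.0
        assert np.allclose(times_min % 30.0, 0.0, atol=1e-9)
        assert len(times_min) == 7  # 0..180 min inclusive

    def test_identical_configs_reproduce_identical_outputs(self):
        t1, _ = _tiny_run(hours=4.0)
        t2, _ = _tiny_run(hours=4.0)
        assert t1.frame.to_csv(index=False) == t2.frame.to_csv(index=False)

    def test_phase_with_undefined_input_rejected(self):
        phase = exp.standard_phase(2.0)
        phase.inputs = {"lysate": phase.inputs["lysate"]}
        with pytest.raises(ConfigurationError, match="undefined input"):
            exp.ProtocolPhase(name="bad", duration_h=2.0,
                              schedule=phase.schedule, inputs=phase.inputs)


class TestValveSafety:
    def _replay(self, log):
        """Replay an actuation log; assert the sequencing invariants:
        inlet flow only with the cell inlet closed and exchange pair
        open, and never both transport valves open at once."""
        valves = {ValveID.EXCHANGE_PAIR.name: False, ValveID.CELL_INLET.name: True}
        for rec in log:
            if rec.action in ("open", "close") and rec.valve in valves:
                valves[rec.valve] = rec.action == "open"
            if rec.action in ("flow_start", "wash_flow_start"):
                assert not valves[ValveID.CELL_INLET.name], \
                    f"inlet flow at t={rec.t_s} with the cell inlet open"
                assert valves[ValveID.EXCHANGE_PAIR.name]
            assert not (valves[ValveID.CELL_INLET.name]
                        and valves[ValveID.EXCHANGE_PAIR.name]), \
                f"both transport valves open at t={rec.t_s}"

    def test_characterization_log_is_safe(self, char_low):
        self._replay(char_low[1].log)

    def test_pulse_log_is_safe(self, atc_assay):
        self._replay(atc_assay[2].log)

    def test_screen_log_is_safe_and_contains_washes(self, zf_screen):
        log = zf_screen[1].log
        self._replay(log)
        # the duty change at the 6.5 h phase boundary inserts a PBS wash
        assert any(r.action == "wash_flow_start" for r in log)

    def test_log_is_strictly_time_ordered(self, char_low):
        times = [r.t_s for r in char_low[1].log]
        assert all(b >= a for a, b in zip(times, times[1:]))


class TestPulseDelivery:
    def test_inducer_present_only_around_the_pulse_window(self, atc_assay):
        _, table, _ = atc_assay
        t, atc = table.trace("r0c0", "aTc")
        assert atc[t <= 6.5].max() == 0.0
        assert atc[(t > 7.4) & (t < 10.0)].min() > 100.0
        washout = atc[t >= 14.0]
        assert washout.max() < 0.01 * atc.max()


class TestReagentConsumption:
    def test_default_protocol_consumes_three_microliters_per_hour(self):
        # 4 flushes/h x 1 min x 0.75 uL/min
        c = reagent_consumption(flow_params={"flow_rate_ul_min": 0.75})
        assert c == pytest.approx(3.0)

    def test_zero_flow_rate(self):
        assert reagent_consumption(flow_params={"flow_rate_ul_min": 0.0}) == 0.0

    def test_doubling_flush_frequency_doubles_consumption(self):
        base = reagent_consumption(flow_params={"flow_rate_ul_min": 0.75})
        fast = reagent_consumption(flow_params={"flow_rate_ul_min": 0.75,
                                                "flush_period_min": 7.5})
        assert fast == pytest.approx(2 * base)

    def test_missing_flow_rate_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="flow_rate"):
            reagent_consumption(flow_params={})


class TestContinuousChemostatLimit:
    def test_discrete_flush_converges_to_closed_form(self):
        """As the flush period shrinks, the periodically-flushed
        two-compartment system approaches the continuous chemostat whose
        constitutive steady state has a closed form."""
        params = PARAM_PRESETS["unlimited_resource"]
        geom = default_layout().geometry(0, 0)  # l = 50 um
        k_p = exchange_rate_pair(geom, Species("p", 27.0))[0]
        k_m = exchange_rate_pair(geom, Species("m", params.mrna_mw_kda))[0]
        m_ss = params.k_tx * 1.0 * params.rho() / (params.delta_m + k_m)
        p_dark = params.k_tl * m_ss * params.rho() / (params.k_mat + k_p)
        p_exact = params.k_mat * p_dark / k_p

        errors = []
        for period_s in (300.0, 60.0, 20.0):
            state = _single_cell_state(params=params)
            t, t_end = 0.0, 8.0 * 3600.0
            while t < t_end:
                state.actuate(ValveID.CELL_INLET, False, t)
                state.time_s = t
                flush(state, {"E": params.E_supply},
                      flow_duration_s=min(5.0, period_s / 4),
                      preflush_wait_s=1.0)
                state.time_s = t
                incubate(state, period_s)
                t += period_s
            g = state.groups["c"]
            cell, _ = g.model.split(g.y)
            p_end = cell[0, g.model.index["GFP"]]
            errors.append(abs(p_end - p_exact) / p_exact)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.10
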