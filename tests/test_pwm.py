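"""PWM scheduling: duty arithmetic, trains, mixing model, mux routing."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfchip.device import default_layout
from cfchip.pwm import (
    ENERGY_DUTY,
    InfeasibleTargetError,
    InputSolution,
    MixTarget,
    PWMSchedule,
    assign_mux,
    build_flush_train,
    delivered_composition,
    duties_for_target,
    enumerate_dilution_series,
    insert_wash_steps,
    is_mixed,
    mixing_fidelity,
    pulse_time,
    wash_schedule,
)


class TestPulseTime:
    @pytest.mark.parametrize("d,T,expected", [
        (0.5, 600.0, 300.0),   # the standard flush setting
        (0.0, 1000.0, 0.0),
        (1.0, 1000.0, 1000.0),
    ])
    def test_t_equals_duty_times_period(self, d, T, expected):
        assert pulse_time(d, T) == pytest.approx(expected)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            pulse_time(0.5, 0.0)


class TestDutiesForTarget:
    def test_null_dose(self):
        s = duties_for_target(MixTarget("zf", 0.0))
        assert s.duties["energy"] == Fraction(1, 2)
        assert s.duties["plain_lysate"] == Fraction(1, 2)
        assert s.duties["zf"] == 0

    def test_full_dose_uses_whole_lysate_half(self):
        s = duties_for_target(MixTarget("zf", 1.0))
        assert s.duties["zf"] == Fraction(1, 2)
        assert s.duties["plain_lysate"] == 0

    def test_below_minimum_actuation_is_infeasible(self):
        with pytest.raises(InfeasibleTargetError, match="smallest achievable"):
            duties_for_target(MixTarget("zf", 0.05), min_duty=0.05,
                              resolution=0.025)

    def test_duties_sum_exactly_to_one(self):
        for frac in (0.0, 0.1, 0.37, 0.5, 0.85, 1.0):
            s = duties_for_target(MixTarget("zf", frac))
            assert sum(s.duties.values()) == Fraction(1)
            assert s.duties["energy"] == ENERGY_DUTY

    @given(target=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, target):
        """The grid allocation equals the exhaustive-search optimum, with
        ties broken toward the lower variable duty."""
        res = Fraction(1, 20)
        half = Fraction(1, 2)
        ideal = Fraction(target).limit_denominator(10_000) * half
        candidates = [k * res for k in range(0, 11)]
        best = min(candidates, key=lambda d: (abs(d - ideal), d))
        feasible = best == 0 or best >= Fraction(1, 20)
        if not feasible:
            with pytest.raises(InfeasibleTargetError):
                duties_for_target(MixTarget("v", target))
            return
        s = duties_for_target(MixTarget("v", target))
        assert s.duties["v"] == best


class TestDilutionSeries:
    def test_default_grid_yields_ten_dilutions(self):
        assert len(enumerate_dilution_series(0.05, 0.05)) == 10

    @pytest.mark.parametrize("md,res,expected", [
        (0.10, 0.10, 5),   # brute force: multiples of 0.10 in (0, 0.5]
        (0.25, 0.25, 2),   # {0.25, 0.50}
    ])
    def test_coarser_grids_against_enumeration(self, md, res, expected):
        series = enumerate_dilution_series(md, res)
        assert len(series) == expected
        duties = [s.duties["variable_lysate"] for s in series]
        assert duties == sorted(duties)

    def test_every_schedule_respects_min_duty_and_sums_to_one(self):
        for s in enumerate_dilution_series(0.05, 0.05):
            assert sum(s.duties.values()) == Fraction(1)
            assert all(d == 0 or d >= s.min_duty for d in s.duties.values())

    def test_resolution_not_dividing_half_cycle_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            enumerate_dilution_series(0.05, 0.15)


class TestFlushTrain:
    def test_standard_flush_is_sixty_seconds(self):
        s = PWMSchedule(600.0, {"lysate": Fraction(1, 2),
                                "energy": Fraction(1, 2)}, n_cycles=100)
        assert s.total_flow_time_s == pytest.approx(60.0)
        events = build_flush_train(s)
        assert events[-1].t_ms == pytest.approx(60_000.0)
        assert len(events) == 2 * 2 * 100

    def test_three_input_cycle_period_gives_same_flow_time(self):
        s = PWMSchedule(1000.0, {"a": Fraction(1, 2), "b": Fraction(1, 4),
                                 "c": Fraction(1, 4)}, n_cycles=60)
        assert s.total_flow_time_s == pytest.approx(60.0)

    def test_single_full_duty_input_has_no_gaps(self):
        s = PWMSchedule(1000.0, {"only": Fraction(1)}, n_cycles=3)
        events = build_flush_train(s)
        for i in range(0, len(events), 2):
            assert events[i].action == "open"
            assert events[i + 1].action == "close"
            assert events[i + 1].t_ms - events[i].t_ms == pytest.approx(1000.0)
        closes = [e.t_ms for e in events if e.action == "close"]
        opens = [e.t_ms for e in events if e.action == "open"]
        assert opens[1:] == closes[:-1]  # back-to-back cycles

    def test_inputs_fire_sequentially_within_cycle(self):
        s = PWMSchedule(1000.0, {"a": Fraction(1, 2), "b": Fraction(1, 2)},
                        n_cycles=1)
        events = build_flush_train(s, inlet_order=["a", "b"])
        assert [(e.valve, e.action) for e in events] == [
            ("a", "open"), ("a", "close"), ("b", "open"), ("b", "close")]
        assert events[2].t_ms == pytest.approx(500.0)


INPUTS = {
    "lysate": InputSolution("lysate", 0, "lysate", {"E": 100.0}),
    "zf_lysate": InputSolution("zf_lysate", 1, "lysate",
                               {"E": 100.0, "ZF": 5000.0}),
    "energy": InputSolution("energy", 2, "energy", {"E": 100.0}),
    "pbs": InputSolution("pbs", 3, "buffer", {}),
}


class TestDeliveredComposition:
    def test_half_duty_halves_stock(self):
        s = PWMSchedule(1000.0, {"zf_lysate": Fraction(1, 2),
                                 "energy": Fraction(1, 2)})
        comp = delivered_composition(s, INPUTS)
        assert comp["ZF"] == pytest.approx(2500.0)  # 5 uM stock at 50% duty

    def test_buffer_only_delivers_nothing(self):
        comp = delivered_composition(wash_schedule(), INPUTS)
        assert comp == {}

    def test_unknown_input_rejected(self):
        s = PWMSchedule(1000.0, {"mystery": Fraction(1)})
        with pytest.raises(KeyError):
            delivered_composition(s, INPUTS)

    def test_delivered_zf_exactly_proportional_to_duty(self):
        zf = []
        duties = [Fraction(k, 20) for k in range(1, 11)]
        for d in duties:
            s = PWMSchedule(1000.0, {"energy": Fraction(1, 2),
                                     "lysate": Fraction(1, 2) - d,
                                     "zf_lysate": d})
            zf.append(delivered_composition(s, INPUTS)["ZF"])
        assert np.all(np.diff(zf) > 0)
        ratios = np.array(zf) / np.array([float(d) for d in duties])
        assert np.allclose(ratios, 5000.0)

    @given(st.lists(st.floats(0, 1000), min_size=3, max_size=3),
           st.integers(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_superposition_in_duties(self, stocks, k):
        """Delivered concentration is additive over inputs with random
        stocks: moving duty between two inputs moves the output linearly."""
        d = Fraction(k, 20)
        inputs = {
            "a": InputSolution("a", 0, "lysate", {"x": stocks[0]}),
            "b": InputSolution("b", 1, "lysate", {"x": stocks[1]}),
            "c": InputSolution("c", 2, "energy", {"x": stocks[2]}),
        }
        s = PWMSchedule(1000.0, {"a": Fraction(1, 2) - d, "b": d,
                                 "c": Fraction(1, 2)})
        expected = (float(Fraction(1, 2) - d) * stocks[0]
                    + float(d) * stocks[1] + 0.5 * stocks[2])
        assert delivered_composition(s, inputs)["x"] == pytest.approx(expected)


class TestWashInsertion:
    def _sched(self, d):
        return PWMSchedule(1000.0, {"energy": Fraction(1, 2),
                                    "lysate": Fraction(1, 2) - d,
                                    "zf_lysate": d})

    def test_identical_phases_get_no_wash(self):
        a = self._sched(Fraction(1, 10))
        out = insert_wash_steps([a, a])
        assert len(out) == 2

    def test_changed_duty_inserts_wash(self):
        a, b = self._sched(Fraction(1, 10)), self._sched(Fraction(1, 4))
        out = insert_wash_steps([a, b])
        assert len(out) == 3
        assert set(out[1].duties) == {"pbs"}

    def test_adjacent_pair_oracle(self):
        a, b, c = (self._sched(Fraction(k, 20)) for k in (1, 2, 3))
        out = insert_wash_steps([a, b, b, c])
        kinds = ["wash" if set(s.duties) == {"pbs"} else "phase" for s in out]
        assert kinds == ["phase", "wash", "phase", "phase", "wash", "phase"]

    def test_empty_phase_list_rejected(self):
        with pytest.raises(ValueError):
            insert_wash_steps([])


class TestMixingFidelity:
    def test_standard_period_is_mixed_at_serpentine(self):
        assert is_mixed(600.0, "serpentine_end")
        assert mixing_fidelity(600.0, "serpentine_end") < 0.05

    def test_long_period_mixed_only_at_exchange_entry(self):
        assert is_mixed(1200.0, "exchange_entry")
        assert not is_mixed(1400.0, "serpentine_end")

    def test_thresholds_sit_at_the_calibrated_boundary(self):
        assert mixing_fidelity(800.0, "serpentine_end") == pytest.approx(0.05)
        assert mixing_fidelity(1200.0, "exchange_entry") == pytest.approx(0.05)

    def test_residual_vanishes_for_short_periods(self):
        assert mixing_fidelity(1.0, "serpentine_end") < 1e-10

    def test_strictly_increasing_in_period(self):
        periods = np.linspace(100, 2000, 25)
        residuals = [mixing_fidelity(T, "exchange_entry") for T in periods]
        assert np.all(np.diff(residuals) > 0)

    def test_unknown_checkpoint_rejected(self):
        with pytest.raises(KeyError, match="checkpoint"):
            mixing_fidelity(600.0, "nowhere")


class TestMuxAssignment:
    def test_four_compositions_on_eight_rows(self):
        plan = assign_mux(["a", "b", "c", "d"], default_layout())
        assert [plan.rows_for(c) for c in "abcd"] == [
            [0, 1], [2, 3], [4, 5], [6, 7]]

    def test_one_row_each(self):
        plan = assign_mux(list("abcdefgh"), default_layout())
        assert [plan.rows_for(c) for c in "abcdefgh"] == [[r] for r in range(8)]

    def test_remainder_rows_go_to_last_cluster(self):
        plan = assign_mux(["a", "b", "c"], default_layout())
        assert [len(plan.rows_for(c)) for c in "abc"] == [2, 2, 4]

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="addressable rows"):
            assign_mux([str(i) for i in range(9)], default_layout())
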