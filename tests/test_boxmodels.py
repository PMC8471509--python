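import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustbox import (
    ConcentrationSeries,
    DustinessRecord,
    EmissionSpec,
    Scenario,
    ach_from_flows,
    air_balance_report,
    flows_from_ach,
    one_box_steady_state,
    read_scenario_yaml,
    solve_one_box,
    solve_two_box,
    time_weighted_average,
    two_box_steady_state,
    write_scenario_yaml,
)


def const_spec(s: float, schedule=((0.0, math.inf),)) -> EmissionSpec:
    """Spec emitting exactly ``s`` mg/min while active."""
    rec = DustinessRecord("unit", "CD", w_inhalable=s, w_respirable=0.0)
    return EmissionSpec(rec, "inhalable", 1.0, 1.0, 1.0, 1.0, schedule=schedule)


def scenario(**kw) -> Scenario:
    base = dict(name="s", v=100.0, v_nf=4.0, q_gv=20.0, q_lev=5.0,
                q_lev_nf=2.0, beta=5.0, c0=0.0)
    base.update(kw)
    return Scenario(**base)


valid_scenarios = st.builds(
    scenario,
    v=st.floats(50.0, 5000.0),
    v_nf=st.floats(1.0, 40.0),
    q_gv=st.floats(1.0, 500.0),
    q_lev=st.floats(0.0, 300.0),
    q_lev_nf=st.floats(0.0, 20.0),
    beta=st.floats(0.25, 30.0),
    c0=st.floats(0.0, 1.0),
)


class TestAch:
    def test_hand_computed_example(self):
        assert ach_from_flows(0.0, 300.0, 2100.0) == pytest.approx(8.571, abs=1e-3)

    def test_zero_flows(self):
        assert ach_from_flows(0.0, 0.0, 77.0) == 0.0

    @given(q_gv=st.floats(0.0, 1e3), q_lev=st.floats(0.0, 1e3),
           v=st.floats(1.0, 1e4))
    def test_flow_round_trip(self, q_gv, q_lev, v):
        assert flows_from_ach(ach_from_flows(q_gv, q_lev, v), v) == pytest.approx(
            q_gv + q_lev, rel=1e-12, abs=1e-12
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            ach_from_flows(1.0, 1.0, 0.0)


class TestOneBoxSteadyState:
    def test_pure_ventilation_equilibrium(self):
        ss = one_box_steady_state(0.0, scenario(c0=0.7))
        assert ss.c_room == pytest.approx(0.7)

    def test_unit_case(self):
        ss = one_box_steady_state(300.0, scenario(q_gv=300.0, q_lev=0.0))
        assert ss.c_room == pytest.approx(1.0)

    def test_tabulated_filling_case(self, clay1_cd_inhalable):
        # back-solved total flow reproducing the published one-box value
        scen = scenario(v=2100.0, q_gv=1054.6, q_lev=300.0)
        ss = one_box_steady_state(clay1_cd_inhalable.base_rate, scen)
        assert ss.c_room == pytest.approx(92.1, abs=0.05)

    def test_no_ventilation_no_steady_state(self):
        with pytest.raises(ValueError):
            one_box_steady_state(1.0, scenario(q_gv=0.0, q_lev=0.0))


class TestTwoBoxSteadyState:
    def test_hand_computed_symmetric_case(self):
        scen = scenario(q_gv=20.0, q_lev=0.0, q_lev_nf=0.0, beta=5.0)
        ss = two_box_steady_state(100.0, scen)
        assert ss.c_ff == pytest.approx(5.0)
        assert ss.c_nf == pytest.approx(25.0)

    def test_source_free_limit(self):
        scen = scenario(q_gv=30.0, q_lev=12.0, q_lev_nf=3.0, c0=0.8)
        ss = two_box_steady_state(0.0, scen)
        expected = 0.8 * (30.0 + 12.0) / (3.0 + 30.0)
        assert ss.c_nf == pytest.approx(expected)
        assert ss.c_ff == pytest.approx(expected)
        # with matched LEV flows the background passes through unchanged
        matched = two_box_steady_state(0.0, scenario(q_lev=5.0, q_lev_nf=5.0, c0=0.8))
        assert matched.c_nf == pytest.approx(0.8)

    def test_infinite_mixing_recovers_one_box(self):
        scen = scenario(q_lev=5.0, q_lev_nf=5.0, beta=1e6)
        ss = two_box_steady_state(200.0, scen)
        one = one_box_steady_state(200.0, scen).c_room
        assert ss.c_nf == pytest.approx(one, rel=1e-3)
        assert ss.c_ff == pytest.approx(one, rel=1e-3)

    @given(valid_scenarios, st.floats(1.0, 1e4))
    def test_nf_exceeds_ff_by_s_over_beta_i(self, scen, s):
        ss = two_box_steady_state(s, scen)
        assert ss.c_nf - ss.c_ff == pytest.approx(s / scen.beta_i, rel=1e-9)

    @given(valid_scenarios, st.floats(1.0, 1e4), st.floats(1.1, 4.0))
    def test_steady_state_monotone_in_ventilation(self, scen, s, k):
        """More ventilation never raises the steady state (zero background)."""
        scen = replace(scen, c0=0.0)
        more_gv = replace(scen, q_gv=scen.q_gv * k)
        assert (
            two_box_steady_state(s, more_gv).c_ff
            <= two_box_steady_state(s, scen).c_ff + 1e-12
        )
        assert (
            one_box_steady_state(s, more_gv).c_room
            <= one_box_steady_state(s, scen).c_room + 1e-12
        )
        more_lev = replace(scen, q_lev=scen.q_lev * k + 1.0)
        assert (
            one_box_steady_state(s, more_lev).c_room
            <= one_box_steady_state(s, scen).c_room + 1e-12
        )

    def test_degenerate_flows_rejected(self):
        with pytest.raises(ValueError):
            two_box_steady_state(1.0, scenario(q_gv=0.0, q_lev_nf=0.0))


class TestSolveOneBox:
    def test_initial_condition(self):
        series = solve_one_box(const_spec(50.0), scenario(c0=0.3), [0.0, 1.0])
        assert series.values[0, 0] == pytest.approx(0.3)
        custom = solve_one_box(const_spec(50.0), scenario(), [0.0, 1.0], c_init=2.0)
        assert custom.values[0, 0] == pytest.approx(2.0)

    def test_relaxes_to_steady_state(self):
        scen = scenario()
        series = solve_one_box(const_spec(50.0), scen, [0.0, 1000.0])
        ss = one_box_steady_state(50.0, scen).c_room
        assert series.values[-1, 0] == pytest.approx(ss, rel=1e-6)

    def test_pure_decay_half_life(self):
        scen = scenario(v=100.0, q_gv=10.0, q_lev=0.0, c0=0.0)
        t_half = math.log(2.0) * 100.0 / 10.0
        series = solve_one_box(const_spec(0.0), scen, [0.0, t_half], c_init=4.0)
        assert series.values[-1, 0] == pytest.approx(2.0, rel=1e-12)

    def test_scheduled_source_rises_and_decays(self):
        spec = const_spec(100.0, schedule=((10.0, 40.0),))
        scen = scenario()
        series = solve_one_box(spec, scen, np.arange(0.0, 121.0, 1.0))
        c = series.values[:, 0]
        assert c[5] == pytest.approx(0.0, abs=1e-12)  # before activity
        assert c[40] > c[20] > 0.0                     # build-up during activity
        assert c[120] < c[40] * 1e-3                   # decay afterwards


class TestSolveTwoBox:
    def test_initial_condition(self):
        series = solve_two_box(
            const_spec(10.0), scenario(), [0.0, 1.0], c_init_nf=1.5, c_init_ff=0.5
        )
        assert series.values[0].tolist() == pytest.approx([1.5, 0.5])

    def test_relaxes_to_steady_state(self):
        scen = scenario()
        series = solve_two_box(const_spec(10.0), scen, [0.0, 2000.0])
        ss = two_box_steady_state(10.0, scen)
        assert series.values[-1, 0] == pytest.approx(ss.c_nf, rel=1e-6)
        assert series.values[-1, 1] == pytest.approx(ss.c_ff, rel=1e-6)

    @given(valid_scenarios, st.floats(1.0, 1e4))
    def test_analytic_matches_numerical_integrator(self, scen, s):
        t = np.linspace(0.0, 60.0, 25)
        ana = solve_two_box(const_spec(s), scen, t)
        num = solve_two_box(const_spec(s), scen, t, method="numeric")
        scale = np.maximum(np.abs(num.values), np.max(num.values) * 1e-3 + 1e-12)
        assert np.max(np.abs(ana.values - num.values) / scale) < 1e-6

    @given(valid_scenarios, st.floats(1.0, 1e3), st.floats(0.1, 10.0))
    def test_linear_in_source_strength(self, scen, s, k):
        scen = replace(scen, c0=0.0)
        t = np.linspace(0.0, 30.0, 7)
        base = solve_two_box(const_spec(s), scen, t, c_init_nf=0.0, c_init_ff=0.0)
        scaled = solve_two_box(const_spec(s * k), scen, t, c_init_nf=0.0, c_init_ff=0.0)
        np.testing.assert_allclose(
            scaled.values, base.values * k, rtol=1e-9, atol=1e-12
        )

    def test_two_box_converges_to_one_box_at_large_beta(self):
        scen = scenario(q_lev=5.0, q_lev_nf=5.0, beta=1e6, c0=0.0)
        t = np.linspace(0.0, 500.0, 11)
        series = solve_two_box(const_spec(40.0), scen, t)
        one = one_box_steady_state(40.0, scen).c_room
        assert series.values[-1, 0] == pytest.approx(one, rel=1e-3)
        assert series.values[-1, 1] == pytest.approx(one, rel=1e-3)


class TestTimeWeightedAverage:
    def test_constant_series(self):
        series = ConcentrationSeries(
            np.arange(5.0), np.full((5, 1), 3.3), ("c_room_mg_m3",)
        )
        assert time_weighted_average(series)["c_room_mg_m3"] == pytest.approx(3.3)

    def test_linear_ramp_halves(self):
        t = np.linspace(0.0, 10.0, 11)
        series = ConcentrationSeries(t, (t * 0.5)[:, None], ("c_room_mg_m3",))
        assert time_weighted_average(series)["c_room_mg_m3"] == pytest.approx(2.5)

    def test_piecewise_series_matches_riemann_oracle(self, small_room):
        spec = const_spec(200.0, schedule=((5.0, 25.0),))
        t = np.arange(0.0, 61.0, 1.0)
        series = solve_two_box(spec, small_room, t)
        window = (7.5, 52.5)
        got = time_weighted_average(series, window)
        fine = np.linspace(*window, 200_001)
        for j, name in enumerate(series.columns):
            vals = np.interp(fine, t, series.values[:, j])
            oracle = np.sum(0.5 * (vals[1:] + vals[:-1]) * np.diff(fine)) / (
                window[1] - window[0]
            )
            assert got[name] == pytest.approx(oracle, rel=1e-6)

    def test_empty_window_rejected(self):
        series = ConcentrationSeries(np.arange(5.0), np.ones((5, 1)), ("c_room_mg_m3",))
        with pytest.raises(ValueError):
            time_weighted_average(series, (2.0, 2.0))
        with pytest.raises(ValueError):
            time_weighted_average(series, (3.0, 9.0))


class TestAirBalance:
    def test_matched_lev_flows_balance(self):
        report = air_balance_report(scenario(q_lev=5.0, q_lev_nf=5.0))
        assert report["balanced"]
        assert report["imbalance_m3_per_min"] == 0.0

    def test_line_l_defaults_flag_imbalance(self, scenario_l):
        report = air_balance_report(scenario_l)
        assert report["imbalance_m3_per_min"] == pytest.approx(290.0)
        assert not report["balanced"]
        assert "290" in report["warning"]

    def test_no_lev_is_balanced(self):
        report = air_balance_report(scenario(q_lev=0.0, q_lev_nf=0.0, beta=7.0))
        assert report["balanced"]


class TestScenarioIO:
    def test_yaml_round_trip(self, tmp_path, scenario_l):
        path = tmp_path / "scen.yaml"
        write_scenario_yaml({"L": scenario_l}, path)
        again = read_scenario_yaml(path)
        assert again["L"] == scenario_l

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            scenario(v=10.0, v_nf=10.0)
        with pytest.raises(ValueError):
            scenario(q_gv=-1.0)
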