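"""Body-mass trajectory recursion, scenarios, and departure metrics."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from goosefuel.bmt import (
    BMT,
    apply_max_foraging_scenario,
    apply_no_night_scenario,
    departure_metrics,
    precompute_energetics,
    run_recursion,
    simulate_bmt,
    source_night_doy,
    start_mass_from_size,
    step_mass,
)
from goosefuel.energetics import EnergeticsParams
from goosefuel.intake import PiModel, growing_degree_days


class TestStepMass:
    def test_balanced_budget_keeps_mass(self):
        assert step_mass(1600.0, 500.0, 500.0) == 1600.0

    def test_surplus_29kj_adds_point_eight_grams(self):
        assert step_mass(1600.0, 29.0, 0.0) == pytest.approx(1600.8)

    def test_deficit_29kj_burns_one_gram(self):
        assert step_mass(1600.0, 0.0, 29.0) == pytest.approx(1599.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            step_mass(0.0, 1.0, 0.0)


def _flat_inputs(n_steps, behavior, intercept_kj_h, t_air=15.0):
    """Single-bird fixes + warm weather + flat PI for hand-checkable runs."""
    times = pd.date_range("2015-01-01", periods=n_steps, freq="30min")
    fixes = pd.DataFrame(
        {
            "bird_id": "g1",
            "timestamp": times,
            "lat": 53.87,
            "lon": 7.30,
            "behavior": behavior,
            "habitat": "agricultural",
            "dt_min": 30.0,
        }
    )
    wtimes = pd.date_range("2015-01-01", "2015-01-06", freq="6h")
    weather = pd.DataFrame(
        {"timestamp": wtimes, "t_air_c": t_air, "u10": 0.0, "v10": 0.0,
         "radiation_wm2": 0.0, "cloud": 0.0}
    )
    daily = weather.set_index("timestamp")["t_air_c"].resample("D").mean()
    daily.index = daily.index.date
    gdd = growing_degree_days(daily, base_temp_c=t_air)  # stays at zero
    pi = PiModel({"agricultural": {"intercept": intercept_kj_h, "slope": 0.0,
                                   "intercept_sd": 1.0}})
    return fixes, weather, pi, gdd


class TestSimulate:
    def test_zero_intake_zero_cost_constant_mass(self):
        params = EnergeticsParams(
            multipliers={"inactive": 0.0, "active": 0.0, "foraging": 0.0}
        )
        fixes, weather, _, gdd = _flat_inputs(48, "inactive", 0.0)
        pi0 = PiModel({"agricultural": {"intercept": 0.0, "slope": 0.0, "intercept_sd": 0.0}})
        traj = simulate_bmt(fixes, weather, pi0, gdd, 1600.0, params=params)
        assert np.allclose(traj.mass_g, 1600.0)

    def test_constant_surplus_gives_exact_linear_growth(self):
        # zero-cost multipliers isolate the intake term: s = PI * 0.5 h per step
        params = EnergeticsParams(
            multipliers={"inactive": 0.0, "active": 0.0, "foraging": 0.0}
        )
        fixes, weather, pi, gdd = _flat_inputs(48, "foraging", 58.0)
        traj = simulate_bmt(fixes, weather, pi, gdd, 1600.0, params=params)
        s = 58.0 * 0.5
        per_step = 0.8 * s / 29.0
        expected = 1600.0 + per_step * np.arange(49)
        assert np.allclose(traj.mass_g, expected, atol=1e-9)

    def test_conservation_against_independent_accumulator(
        self, winter_track, winter_weather, winter_gdd
    ):
        from goosefuel.synthetic import DEFAULT_PI_TRUTH

        fixes = winter_track[winter_track["bird_id"] == "goose_01"]
        traj = simulate_bmt(fixes, winter_weather, DEFAULT_PI_TRUTH, winter_gdd, 1550.0)
        arrs = precompute_energetics(fixes, winter_weather, DEFAULT_PI_TRUTH, winter_gdd)
        p = EnergeticsParams()
        surplus_pos = deficit = 0.0
        for i in range(len(arrs["b_dt"])):
            ee = traj.mass_g[i] / p.w_ref_g * p.bmr_ref_w * arrs["b_dt"][i] / 1000.0
            s = arrs["intake_kj"][i] - (max(arrs["et_kj"][i], ee) + arrs["ef_kj"][i])
            if s >= 0:
                surplus_pos += s
            else:
                deficit += -s
        expected_end = 1550.0 + (0.8 * surplus_pos - deficit) / 29.0
        assert traj.mass_g[-1] == pytest.approx(expected_end, abs=1e-9)

    def test_weather_gap_raises(self, winter_track, winter_gdd):
        from goosefuel.synthetic import DEFAULT_PI_TRUTH

        fixes = winter_track[winter_track["bird_id"] == "goose_01"]
        empty_weather = pd.DataFrame(
            {"timestamp": pd.to_datetime([]), "t_air_c": [], "u10": [], "v10": [],
             "radiation_wm2": [], "cloud": []}
        )
        with pytest.raises(Exception):
            simulate_bmt(fixes, empty_weather, DEFAULT_PI_TRUTH, winter_gdd, 1550.0)


def _night_frame(rows):
    """rows: (timestamp, is_day, night_date, behavior, habitat)"""
    return pd.DataFrame(
        {
            "bird_id": "g1",
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "lat": 53.87,
            "lon": 7.30,
            "behavior": [r[3] for r in rows],
            "habitat": [r[4] for r in rows],
            "dt_min": 30.0,
            "is_day": [r[1] for r in rows],
            "night_date": [r[2] for r in rows],
        }
    )


class TestScenarios:
    def test_no_night_rewrites_only_night_fixes(self):
        fx = _night_frame(
            [
                ("2015-02-01 12:00", True, pd.NaT, "foraging", "agricultural"),
                ("2015-02-01 22:00", False, date(2015, 2, 1), "foraging", "agricultural"),
                ("2015-02-02 03:00", False, date(2015, 2, 1), "active", "natural"),
            ]
        )
        out = apply_no_night_scenario(fx)
        assert list(out["behavior"]) == ["foraging", "inactive", "inactive"]

    @pytest.mark.parametrize(
        "doy,src",
        [(61, 1), (32, 2), (91, 1), (121, 1), (1, 1), (30, 30), (31, 1), (62, 2)],
    )
    def test_lunar_cycle_night_mapping(self, doy, src):
        assert source_night_doy(doy) == src

    def test_replacement_copies_behavior_and_habitat(self):
        fx = _night_frame(
            [
                # source night: Jan 2 (doy 2)
                ("2015-01-02 17:00", False, date(2015, 1, 2), "foraging", "agricultural"),
                ("2015-01-02 17:30", False, date(2015, 1, 2), "active", "agricultural"),
                ("2015-01-02 18:00", False, date(2015, 1, 2), "foraging", "agricultural"),
                # target night: Feb 1 (doy 32) -> source doy 2
                ("2015-02-01 18:00", False, date(2015, 2, 1), "inactive", "natural"),
                ("2015-02-01 18:30", False, date(2015, 2, 1), "inactive", "natural"),
            ]
        )
        out = apply_max_foraging_scenario(fx)
        assert list(out["behavior"][:3]) == ["foraging", "active", "foraging"]
        assert list(out["behavior"][3:]) == ["foraging", "active"]
        assert list(out["habitat"][3:]) == ["agricultural", "agricultural"]

    def test_missing_source_night_falls_back_to_nearest(self, caplog):
        fx = _night_frame(
            [
                ("2015-01-02 17:00", False, date(2015, 1, 2), "foraging", "agricultural"),
                # target night doy 40 -> wanted source 10, only doy 2 exists
                ("2015-02-09 18:00", False, date(2015, 2, 9), "inactive", "natural"),
            ]
        )
        with caplog.at_level("WARNING"):
            out = apply_max_foraging_scenario(fx)
        assert out["behavior"].iloc[1] == "foraging"
        assert any("source night" in r.message for r in caplog.records)

    def test_pathwise_scenario_ordering(self, scenario_runs):
        for bird in scenario_runs["baseline"]:
            base = scenario_runs["baseline"][bird]["mass"]
            nonight = scenario_runs["no_night"][bird]["mass"]
            maxfor = scenario_runs["max_foraging"][bird]["mass"]
            assert np.all(nonight <= base + 1e-9)
            assert np.all(base <= maxfor + 1e-9)
            assert nonight.min() < base.min()  # night foraging matters in winter


class TestStartMass:
    def test_explicit_passthrough(self):
        assert start_mass_from_size(explicit_g=1500.0) == 1500.0

    def test_population_default(self):
        assert start_mass_from_size() == 1550.0

    def test_linear_size_rule(self):
        assert start_mass_from_size(size_mm=100.0, coef=(200.0, 13.0)) == 1500.0

    def test_nothing_provided_rejected(self):
        with pytest.raises(ValueError):
            start_mass_from_size(default_g=None)


class TestDepartureMetrics:
    def _bmt(self, mass):
        n = len(mass)
        ts = pd.date_range("2015-01-01", periods=n, freq="30min").to_numpy()
        return BMT("g1", "baseline", ts, np.asarray(mass, float), float(mass[0]))

    def test_increasing_trajectory_peaks_at_departure(self):
        traj = self._bmt(np.linspace(1500, 2500, 100))
        m = departure_metrics(traj)
        assert m.max_mass_g == 2500.0
        assert m.time_max_mass == pd.Timestamp(traj.timestamps[-1])

    def test_flat_trajectory_takes_first_timestamp(self):
        traj = self._bmt(np.full(50, 1600.0))
        m = departure_metrics(traj)
        assert m.time_max_mass == pd.Timestamp(traj.timestamps[0])

    def test_ramp_crossing_matches_analytic_time(self):
        # +1 g per 30-min step from 1500: 1510.5 g first reached at step 11
        traj = self._bmt(1500.0 + np.arange(100))
        m = departure_metrics(traj, reference_mass_g=1510.5)
        analytic = pd.Timestamp("2015-01-01") + pd.Timedelta(minutes=30 * 10.5)
        assert abs(m.time_reached_reference - analytic) <= pd.Timedelta(minutes=30)

    def test_unreachable_reference_flagged(self):
        traj = self._bmt(np.full(20, 1600.0))
        m = departure_metrics(traj, reference_mass_g=3000.0)
        assert not m.reference_reached and m.time_reached_reference is None

    def test_deposition_period_from_breakpoint(self):
        traj = self._bmt(1500.0 + np.arange(48))  # peaks within Jan 1 (doy 1)
        m = departure_metrics(traj, breakpoint_day=0.5)
        assert m.deposition_period_days == pytest.approx(
            1.0 + 47 * 0.5 / 24.0 - 0.5, abs=1e-6
        )
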