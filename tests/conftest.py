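from datetime import date

import pytest

from goosefuel.behavior import annotate_day_night, water_correction
from goosefuel.bmt import (
    apply_max_foraging_scenario,
    apply_no_night_scenario,
    precompute_energetics,
    run_recursion,
)
from goosefuel.intake import growing_degree_days
from goosefuel.synthetic import (
    DEFAULT_PI_TRUTH,
    SimConfig,
    generate_bursts,
    generate_track,
    generate_weather,
)


def daily_mean_temp(weather):
    s = weather.set_index("timestamp")["t_air_c"].resample("D").mean()
    s.index = s.index.date
    return s


@pytest.fixture(scope="session")
def default_bursts():
    """The full 945-burst calibration set at default class counts."""
    return generate_bursts(SimConfig(seed=11))


@pytest.fixture(scope="session")
def winter_config():
    """Two birds, January only — cheap fixture for budget/energetics tests."""
    return SimConfig(n_birds=2, start_date=date(2015, 1, 1),
                     end_date=date(2015, 1, 31), departure_jitter_days=0, seed=5)


@pytest.fixture(scope="session")
def winter_track(winter_config):
    return generate_track(winter_config)


@pytest.fixture(scope="session")
def winter_weather(winter_config):
    return generate_weather(winter_config)


@pytest.fixture(scope="session")
def winter_gdd(winter_weather):
    return growing_degree_days(daily_mean_temp(winter_weather))


@pytest.fixture(scope="session")
def scenario_runs():
    """Full-season trajectories for all three scenarios under conditions where
    every night's net intake is positive by construction: January nights all
    foraging, later nights all inactive in the baseline."""
    cfg = SimConfig(
        n_birds=2,
        night_forage_base_p=1.0,
        night_forage_moon_gain=0.0,
        night_winter_end_doy=30,
        night_forage_end_doy=31,
        water_fix_prob=0.0,
        day_fly_p=0.0,
        departure_jitter_days=0,
        seed=17,
    )
    track = annotate_day_night(
        water_correction(generate_track(cfg)), cfg.site_lat, cfg.site_lon
    )
    weather = generate_weather(cfg)
    gdd = growing_degree_days(daily_mean_temp(weather))
    scen_fixes = {
        "baseline": track,
        "no_night": apply_no_night_scenario(track),
        "max_foraging": apply_max_foraging_scenario(track),
    }
    out = {}
    for name, fixes in scen_fixes.items():
        out[name] = {}
        for bird, grp in fixes.groupby("bird_id"):
            arrs = precompute_energetics(grp, weather, DEFAULT_PI_TRUTH, gdd)
            mass, unreal = run_recursion(arrs, 1550.0)
            out[name][bird] = {"arrays": arrs, "mass": mass, "unrealistic": unreal}
    return out
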