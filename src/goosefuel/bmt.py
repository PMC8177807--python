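"""Body-mass trajectories under baseline and counterfactual foraging scenarios.

Mass is stepped fix-by-fix: intake of metabolized energy minus total energy
cost gives a surplus stored at 0.8 efficiency or a deficit burned at 1.0
efficiency, converted at 29 kJ/g of deposited tissue.  Existence energy uses
the evolving mass (mass-dependent BMR at the previous fix); thermoregulation
uses the fixed 1600-g parameterisation throughout, mirroring the two-track
treatment of the underlying energetics model.

Scenarios rewrite night behaviour before simulation: ``no_night`` sets every
night fix to inactive; ``max_foraging`` substitutes each post-January night's
budget (behaviour and habitat) with the same bird's January night one lunar
cycle (30 days) earlier, i.e. source night-of-year ((n - 1) mod 30) + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .energetics import (
    FORAGE_HABITATS,
    EnergeticsParams,
    bmr,
    detect_flight,
    thermoregulation_cost,
)
from .intake import GddSeries, PiModel, potential_intake

__all__ = [
    "BMT",
    "DepartureMetrics",
    "SCENARIOS",
    "DEFAULT_START_MASS_G",
    "step_mass",
    "simulate_bmt",
    "apply_no_night_scenario",
    "apply_max_foraging_scenario",
    "source_night_doy",
    "start_mass_from_size",
    "departure_metrics",
]

log = logging.getLogger(__name__)

SCENARIOS = ("baseline", "no_night", "max_foraging")
DEFAULT_START_MASS_G = 1550.0
_LUNAR_CYCLE_DAYS = 30


@dataclass
class BMT:
    """One bird's simulated body-mass time series under one scenario."""

    bird_id: str
    scenario: str
    timestamps: np.ndarray  # datetime64, length n_fixes + 1
    mass_g: np.ndarray      # mass at each timestamp; [0] is start mass
    start_mass_g: float
    unrealistic: bool = False  # mass hit zero or below during simulation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bird_id": self.bird_id,
                "scenario": self.scenario,
                "timestamp": pd.to_datetime(self.timestamps),
                "mass_g": self.mass_g,
            }
        )


@dataclass
class DepartureMetrics:
    max_mass_g: float
    time_max_mass: datetime
    onset_breakpoint_day: float | None = None
    deposition_period_days: float | None = None
    time_reached_reference: datetime | None = None
    reference_reached: bool = True


def step_mass(w_prev_g: float, intake_kj: float, cost_kj: float,
              params: EnergeticsParams | None = None) -> float:
    """One mass update: store surplus at 0.8, burn deficit at 1.0, 29 kJ/g."""
    p = params or EnergeticsParams()
    if w_prev_g <= 0:
        raise ValueError("previous mass must be positive")
    s = intake_kj - cost_kj
    eff = p.store_eff if s >= 0 else p.burn_eff
    return w_prev_g + eff * s / p.energy_density_kj_g


def precompute_energetics(fixes: pd.DataFrame, weather: pd.DataFrame,
                          pi_model: PiModel, gdd: GddSeries,
                          params: EnergeticsParams | None = None) -> dict:
    """Mass-independent per-fix arrays for one bird's fix table.

    Returns dt_s, the behaviour multiplier (0 where the interval is flight),
    thermoregulation cost (kJ, fixed mass), flight cost (kJ), the base intake
    (kJ) under the supplied PI model, and the intake hours (for re-scaling PI
    in sensitivity runs).  Raises if weather or GDD coverage has gaps.
    """
    p = params or EnergeticsParams()
    df = fixes.sort_values("timestamp").reset_index(drop=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).astype("datetime64[ns]")
    dt_s = df["dt_min"].to_numpy(dtype=float) * 60.0

    wx = weather.sort_values("timestamp").copy()
    wx["timestamp"] = pd.to_datetime(wx["timestamp"]).astype("datetime64[ns]")
    w = pd.merge_asof(
        df[["timestamp"]], wx, on="timestamp", direction="nearest",
    )
    if w["t_air_c"].isna().any():
        raise ValueError("weather table does not cover the track period")
    et_kj = thermoregulation_cost(
        w["t_air_c"].to_numpy(), w["u10"].to_numpy(), w["v10"].to_numpy(),
        w["radiation_wm2"].to_numpy(), p.thermo_mass_g, dt_s, p,
    ) / 1000.0

    # flight: accelerometer class OR displacement above the speed threshold
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    flew = np.zeros(len(df), dtype=bool)
    if len(df) > 1:
        fl, _ = detect_flight(lat[:-1], lon[:-1], lat[1:], lon[1:], dt_s[:-1], p)
        flew[:-1] = fl
    behavior = df["behavior"].to_numpy()
    flying = (behavior == "flying") | flew
    flight_power_w = p.flight_bmr_multiple * bmr(p.thermo_mass_g, p)
    ef_kj = np.where(flying, flight_power_w * dt_s / 1000.0, 0.0)

    b_dt = np.where(
        flying, 0.0,
        np.array([p.b(b) for b in behavior]) * dt_s,
    )

    dates = df["timestamp"].dt.date.to_numpy()
    gdd_map = {d: gdd.at(d) for d in set(dates)}
    habitat = df["habitat"].to_numpy()
    suitable = np.isin(habitat, list(FORAGE_HABITATS))
    eats = (~flying) & suitable & np.isin(behavior, ["foraging", "active"])
    dt_h = dt_s / 3600.0
    hours = np.where(eats, dt_h, 0.0)
    pi = np.array(
        [
            potential_intake(h, gdd_map[d], pi_model) if e else 0.0
            for h, d, e in zip(habitat, dates, eats)
        ]
    )
    return {
        "timestamps": df["timestamp"].to_numpy(),
        "dt_s": dt_s,
        "b_dt": b_dt,
        "et_kj": et_kj,
        "ef_kj": ef_kj,
        "intake_kj": pi * hours,
        "intake_hours": hours,
    }


def run_recursion(arrays: dict, start_mass_g: float,
                  params: EnergeticsParams | None = None,
                  bmr_ref_w: float | None = None,
                  pi_shift_kj_h: float = 0.0) -> tuple[np.ndarray, bool]:
    """Fix-by-fix mass recursion over precomputed arrays.

    ``bmr_ref_w`` overrides the reference BMR and ``pi_shift_kj_h`` shifts
    the PI intercept (sensitivity runs re-use the same arrays this way).
    Returns (mass series of length n+1, unrealistic flag).
    """
    p = params or EnergeticsParams()
    bref = p.bmr_ref_w if bmr_ref_w is None else bmr_ref_w
    b_dt, et, ef = arrays["b_dt"], arrays["et_kj"], arrays["ef_kj"]
    intake = arrays["intake_kj"] + pi_shift_kj_h * arrays["intake_hours"]
    n = len(b_dt)
    mass = np.empty(n + 1)
    mass[0] = w = start_mass_g
    k_bmr = bref / p.w_ref_g / 1000.0  # kJ per (g * b*dt_s)
    store = p.store_eff / p.energy_density_kj_g
    burn = p.burn_eff / p.energy_density_kj_g
    unrealistic = False
    for i in range(n):
        ee = w * k_bmr * b_dt[i]
        s = intake[i] - (max(et[i], ee) + ef[i])
        w = w + (store if s >= 0 else burn) * s
        if w <= 0:
            unrealistic = True
        mass[i + 1] = w
    return mass, unrealistic


def simulate_bmt(fixes: pd.DataFrame, weather: pd.DataFrame, pi_model: PiModel,
                 gdd: GddSeries, start_mass_g: float, scenario: str = "baseline",
                 params: EnergeticsParams | None = None) -> BMT:
    """Simulate one bird's body-mass trajectory from its (already scenario-
    transformed) fix table."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    birds = fixes["bird_id"].unique()
    if len(birds) != 1:
        raise ValueError("simulate_bmt expects fixes of a single bird")
    arrays = precompute_energetics(fixes, weather, pi_model, gdd, params)
    mass, unreal = run_recursion(arrays, start_mass_g, params)
    ts = arrays["timestamps"]
    last = pd.Timestamp(ts[-1]) + pd.Timedelta(seconds=arrays["dt_s"][-1])
    timestamps = np.append(ts, np.datetime64(last))
    return BMT(str(birds[0]), scenario, timestamps, mass, start_mass_g, unreal)


def apply_no_night_scenario(fixes: pd.DataFrame) -> pd.DataFrame:
    """Counterfactual: every night behaviour becomes inactive.

    Requires the ``is_day`` annotation (see behavior.annotate_day_night).
    """
    if "is_day" not in fixes.columns:
        raise ValueError("fixes must carry day/night annotation")
    out = fixes.copy()
    out.loc[~out["is_day"], "behavior"] = "inactive"
    return out


def source_night_doy(night_doy: int) -> int:
    """January source night for a target night: ((n - 1) mod 30) + 1.

    The substitution maps each night onto the night one whole 30-day lunar
    cycle (anchored at January 1) earlier, so e.g. nights starting on
    day-of-year 31, 61, 91, and 121 all take the budget of night 1.
    """
    if night_doy <= _LUNAR_CYCLE_DAYS:
        return night_doy
    return (night_doy - 1) % _LUNAR_CYCLE_DAYS + 1


def apply_max_foraging_scenario(fixes: pd.DataFrame) -> pd.DataFrame:
    """Counterfactual: post-January nights replay January night budgets.

    Per bird, each night's slots (ordered within the night) take the
    behaviour AND habitat of the same slot of the source January night —
    habitat travels with the budget because intake is habitat-specific.
    Slots beyond the (shorter) source night keep their own labels; a missing
    source night falls back to the nearest available one (logged).
    """
    if "is_day" not in fixes.columns or "night_date" not in fixes.columns:
        raise ValueError("fixes must carry day/night annotation")
    out = fixes.sort_values(["bird_id", "timestamp"]).reset_index(drop=True)
    behavior = out["behavior"].to_numpy(object).copy()
    habitat = out["habitat"].to_numpy(object).copy()

    for bird, grp in out.groupby("bird_id"):
        night = grp[~grp["is_day"]]
        by_doy: dict[int, pd.Index] = {}
        for nd, g in night.groupby("night_date"):
            by_doy[pd.Timestamp(nd).timetuple().tm_yday] = g.index
        sources = sorted(d for d in by_doy if d <= _LUNAR_CYCLE_DAYS)
        if not sources:
            log.warning("bird %s has no January source nights; left unchanged", bird)
            continue
        for doy, idx in by_doy.items():
            if doy <= _LUNAR_CYCLE_DAYS:
                continue
            src = source_night_doy(doy)
            if src not in by_doy:
                nearest = min(sources, key=lambda s: abs(s - src))
                log.warning(
                    "bird %s: source night %d missing, using night %d", bird, src, nearest
                )
                src = nearest
            src_idx = by_doy[src]
            k = min(len(idx), len(src_idx))
            behavior[idx[:k]] = behavior[src_idx[:k]]
            habitat[idx[:k]] = habitat[src_idx[:k]]
    out["behavior"] = behavior
    out["habitat"] = habitat
    return out


def start_mass_from_size(explicit_g: float | None = None,
                         size_mm: float | None = None,
                         coef: tuple[float, float] | None = None,
                         default_g: float | None = DEFAULT_START_MASS_G) -> float:
    """Starting body mass: explicit value, a linear size rule, or the
    population default constant."""
    if explicit_g is not None:
        return float(explicit_g)
    if size_mm is not None:
        if coef is None:
            raise ValueError("size given but no size->mass coefficients")
        return float(coef[0] + coef[1] * size_mm)
    if default_g is not None:
        return float(default_g)
    raise ValueError("no start mass, size rule, or default provided")


def departure_metrics(bmt: BMT, breakpoint_day: float | None = None,
                      reference_mass_g: float | None = None) -> DepartureMetrics:
    """Departure body mass (the trajectory maximum, first attainment on
    ties), optional first crossing of a reference mass, and the energy
    deposition period against a supplied fueling-onset breakpoint."""
    if len(bmt.mass_g) == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmax(bmt.mass_g))
    t_max = pd.Timestamp(bmt.timestamps[i]).to_pydatetime()
    m = DepartureMetrics(max_mass_g=float(bmt.mass_g[i]), time_max_mass=t_max)
    if breakpoint_day is not None:
        m.onset_breakpoint_day = float(breakpoint_day)
        doy_max = t_max.timetuple().tm_yday + (
            t_max - datetime(t_max.year, t_max.month, t_max.day)
        ).total_seconds() / 86400.0
        m.deposition_period_days = doy_max - breakpoint_day
    if reference_mass_g is not None:
        hit = np.nonzero(bmt.mass_g >= reference_mass_g)[0]
        if len(hit):
            m.time_reached_reference = pd.Timestamp(
                bmt.timestamps[hit[0]]
            ).to_pydatetime()
        else:
            m.reference_reached = False
    return m
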