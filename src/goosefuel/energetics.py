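"""Per-interval energy costs for a wintering goose.

Existence energy is basal metabolic rate (BMR) times a behaviour-specific
multiplier times interval duration; BMR scales proportionally with body mass
around a reference (5.536 W at 1825 g).  Thermoregulation below the lower
critical temperature (~10 degC) is a biophysical heat-loss model driven by air
temperature, 10-m wind, and shortwave radiation; heat generated by activity
substitutes for thermoregulation, so the total cost of an interval is
max(existence, thermoregulation), with flight costed separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BEHAVIORS",
    "HABITATS",
    "FORAGE_HABITATS",
    "EnergeticsParams",
    "bmr",
    "existence_energy",
    "thermoregulation_cost",
    "detect_flight",
    "flight_cost",
    "total_cost",
    "device_load_percent",
    "great_circle_m",
]

BEHAVIORS = ("inactive", "active", "foraging", "flying")
HABITATS = ("agricultural", "natural", "water", "other")
FORAGE_HABITATS = frozenset({"agricultural", "natural"})

_RHO_CP = 1200.0  # volumetric heat capacity of air, J m^-3 K^-1
_EARTH_R = 6371000.0


@dataclass
class EnergeticsParams:
    """All energetic constants; defaults are the barnacle-goose values."""

    bmr_ref_w: float = 5.536          # BMR at reference mass, W
    w_ref_g: float = 1825.0           # reference body mass, g
    multipliers: dict = field(
        default_factory=lambda: {"inactive": 1.5, "active": 1.9, "foraging": 1.6}
    )
    lct_c: float = 10.0               # lower critical temperature, degC
    bird_height_m: float = 0.15
    plumage_resistance_s_m: float = 200.0
    energy_density_kj_g: float = 29.0
    store_eff: float = 0.8            # depositing body stores
    burn_eff: float = 1.0             # mobilising body stores
    flight_speed_threshold_kmh: float = 20.0
    flight_bmr_multiple: float = 12.0  # default constant-power flight model
    thermo_mass_g: float = 1600.0     # fixed mass used for thermoregulation
    solar_absorptivity: float = 0.3
    thermo_model: Callable | None = None  # plug-in replacement for the default

    def b(self, behavior: str) -> float:
        if behavior == "flying":
            return 0.0  # flight costed separately
        try:
            return self.multipliers[behavior]
        except KeyError:
            raise ValueError(f"unknown behavior: {behavior!r}") from None


def bmr(mass_g, params: EnergeticsParams | None = None):
    """Mass-proportional basal metabolic rate in watts: (W/W_ref) * BMR_ref."""
    p = params or EnergeticsParams()
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("body mass must be positive")
    out = mass_g / p.w_ref_g * p.bmr_ref_w
    return float(out) if out.ndim == 0 else out


def existence_energy(behavior: str, bmr_w: float, dt_s: float,
                     params: EnergeticsParams | None = None) -> float:
    """Existence energy E_e = BMR * b * t in joules; zero for flight."""
    p = params or EnergeticsParams()
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior: {behavior!r}")
    if dt_s <= 0:
        raise ValueError("interval must be positive")
    return bmr_w * p.b(behavior) * dt_s


def _boundary_layer_resistance(wind_ms, height_m):
    # forced-convection resistance over a body of characteristic dimension d:
    # r_b ~ 307 sqrt(d/u) s/m; 10-m wind scaled to bird height by a log profile
    u = np.maximum(np.asarray(wind_ms, dtype=float), 0.1)
    z0 = 0.01
    u_bird = u * math.log(max(height_m, 2 * z0) / z0) / math.log(10.0 / z0)
    return 307.0 * np.sqrt(height_m / np.maximum(u_bird, 0.1))


def _surface_area_m2(mass_g):
    # Meeh rule: A (cm^2) = 10 * W(g)^(2/3)
    return 1e-3 * np.asarray(mass_g, dtype=float) ** (2.0 / 3.0)


def thermoregulation_cost(t_air_c, u10, v10, radiation_wm2, mass_g, dt_s,
                          params: EnergeticsParams | None = None):
    """Thermoregulation energy E_t in joules for one interval; vectorised.

    Default model: operative temperature T_op raises air temperature with
    absorbed shortwave radiation; below the lower critical temperature the
    bird loses heat at A * rho*c_p * (LCT - T_op) / (r_plumage + r_boundary),
    with the boundary-layer resistance shrinking as wind rises.  A custom
    model can be plugged in via ``params.thermo_model`` with this signature.
    """
    p = params or EnergeticsParams()
    if p.thermo_model is not None:
        return p.thermo_model(t_air_c, u10, v10, radiation_wm2, mass_g, dt_s, p)
    t_air = np.asarray(t_air_c, dtype=float)
    if np.any(np.isnan(t_air)):
        raise ValueError("missing air temperature in weather record")
    wind = np.hypot(np.asarray(u10, dtype=float), np.asarray(v10, dtype=float))
    r_b = _boundary_layer_resistance(wind, p.bird_height_m)
    t_op = t_air + p.solar_absorptivity * np.asarray(radiation_wm2, dtype=float) * r_b / _RHO_CP
    deficit = np.maximum(p.lct_c - t_op, 0.0)
    rate_w = _surface_area_m2(mass_g) * _RHO_CP * deficit / (p.plumage_resistance_s_m + r_b)
    out = rate_w * dt_s
    return float(out) if np.ndim(out) == 0 else out


def great_circle_m(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in metres; vectorised."""
    la1, lo1, la2, lo2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float),
                                          np.asarray(lat2, float), np.asarray(lon2, float)))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    out = 2 * _EARTH_R * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if np.ndim(out) == 0 else out


def detect_flight(lat1, lon1, lat2, lon2, dt_s, params: EnergeticsParams | None = None):
    """Flag displacement-based flight: ground speed above the threshold.

    Returns (flight: bool, distance_m); vectorised over arrays.
    """
    p = params or EnergeticsParams()
    dt = np.asarray(dt_s, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("interval must be positive")
    dist = great_circle_m(lat1, lon1, lat2, lon2)
    speed_kmh = np.asarray(dist) / dt * 3.6
    flight = speed_kmh > p.flight_speed_threshold_kmh
    if np.ndim(flight) == 0:
        return bool(flight), float(dist)
    return flight, dist


def default_flight_power(airspeed_ms: float, params: EnergeticsParams) -> float:
    """Constant-power flight model: a fixed multiple of reference-mass BMR (W)."""
    return params.flight_bmr_multiple * bmr(params.thermo_mass_g, params)


def flight_cost(ground_velocity, wind, dt_flying_s: float,
                params: EnergeticsParams | None = None,
                power_model: Callable | None = None) -> float:
    """Flight energy in joules: P(airspeed) * dt, airspeed = |v_ground - wind|.

    The power curve is pluggable; the default is a constant multiple of BMR
    (a U-shaped aerodynamic curve can be passed as ``power_model``).
    """
    p = params or EnergeticsParams()
    if dt_flying_s < 0:
        raise ValueError("flight duration must be non-negative")
    gv = np.asarray(ground_velocity, dtype=float)
    w = np.asarray(wind, dtype=float)
    airspeed = float(np.linalg.norm(gv - w))
    power = (power_model or default_flight_power)(airspeed, p)
    return power * dt_flying_s


def total_cost(ee_j: float, et_j: float, ef_j: float = 0.0) -> float:
    """Total cost E_s = max(E_t, E_e) + flight: activity heat substitutes
    for thermoregulation, so only the larger of the two is paid."""
    if min(ee_j, et_j, ef_j) < 0:
        raise ValueError("energy components must be non-negative")
    return max(et_j, ee_j) + ef_j


def device_load_percent(device_mass_g: float, body_mass_g: float) -> float:
    """Tracker+harness load as a percentage of body mass, to one decimal."""
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    return round(100.0 * device_mass_g / body_mass_g, 1)
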