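"""Metabolizable energy intake: growing degree days and habitat-specific
potential intake rate (PI).

PI (kJ/h) is modelled per habitat as a linear function of cumulative growing
degree days (GDD), fitted by ordinary least squares to field observations of
intake rate; the intercept standard error is retained because the sensitivity
analysis perturbs it.  Realised metabolizable intake multiplies PI by the
time spent foraging plus the time active on habitats suitable for foraging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .energetics import FORAGE_HABITATS

__all__ = [
    "PiModel",
    "GddSeries",
    "growing_degree_days",
    "fit_pi_regression",
    "potential_intake",
    "metabolizable_intake",
]


@dataclass
class PiModel:
    """Per-habitat linear model PI = intercept + slope * GDD (kJ/h)."""

    coef: dict[str, dict[str, float]] = field(default_factory=dict)
    # coef[habitat] = {"intercept": kJ/h, "slope": kJ/h per GDD, "intercept_sd": kJ/h}

    def habitats(self):
        return tuple(self.coef)

    def shifted(self, intercept_shift_kj_h: float) -> "PiModel":
        """A copy with every habitat intercept shifted (sensitivity runs)."""
        return PiModel(
            {
                h: {**c, "intercept": c["intercept"] + intercept_shift_kj_h}
                for h, c in self.coef.items()
            }
        )

    @property
    def pooled_intercept_sd(self) -> float:
        """Habitat-pooled intercept SD, the sensitivity sampling width."""
        sds = [c["intercept_sd"] for c in self.coef.values()]
        return float(np.mean(sds)) if sds else 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.coef, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PiModel":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass
class GddSeries:
    """Cumulative growing degree days indexed by date."""

    values: pd.Series  # index: date, values: degC*day, non-decreasing
    base_temp_c: float
    start_date: _date

    def at(self, date: _date) -> float:
        try:
            return float(self.values.loc[date])
        except KeyError:
            raise KeyError(f"no GDD value for {date}") from None


def growing_degree_days(daily_mean_temp: pd.Series, base_temp_c: float = 0.0,
                        start_date: _date | None = None) -> GddSeries:
    """Cumulative sum of max(0, T_day - base) from start_date onward.

    ``daily_mean_temp`` is indexed by date; the series must be gapless from
    ``start_date``.  The start day's own excess is included, so ten days at
    one degree above base accumulate 10 degree-days by day ten.
    """
    s = daily_mean_temp.sort_index()
    if start_date is None:
        start_date = s.index[0]
    s = s.loc[s.index >= start_date]
    idx = pd.Index(s.index)
    expected = pd.date_range(start_date, idx[-1], freq="D").date
    if len(idx) != len(expected) or not (idx == pd.Index(expected)).all():
        raise ValueError("daily temperature series has gaps")
    excess = np.maximum(s.to_numpy(dtype=float) - base_temp_c, 0.0)
    cum = np.cumsum(excess)
    return GddSeries(pd.Series(cum, index=idx), base_temp_c, start_date)


def fit_pi_regression(obs: pd.DataFrame) -> PiModel:
    """OLS fit of intake rate on GDD per habitat.

    ``obs`` needs columns habitat, gdd, intake_kj_h; each modelled habitat
    needs at least 3 observations.  Habitats absent from the data are simply
    absent from the model.
    """
    model = PiModel()
    for habitat, grp in obs.groupby("habitat"):
        if len(grp) < 3:
            raise ValueError(f"need >=3 observations for habitat {habitat!r}")
        x = sm.add_constant(grp["gdd"].to_numpy(dtype=float))
        fit = sm.OLS(grp["intake_kj_h"].to_numpy(dtype=float), x).fit()
        model.coef[habitat] = {
            "intercept": float(fit.params[0]),
            "slope": float(fit.params[1]),
            "intercept_sd": float(fit.bse[0]),
        }
    return model


def potential_intake(habitat: str, gdd_value: float, pi_model: PiModel) -> float:
    """PI in kJ/h at a GDD value; linear prediction floored at zero."""
    try:
        c = pi_model.coef[habitat]
    except KeyError:
        raise KeyError(f"habitat {habitat!r} not in PI model") from None
    return max(0.0, c["intercept"] + c["slope"] * gdd_value)


def metabolizable_intake(pi_kj_h: float, forage_h: float, active_h: float,
                         habitat: str) -> float:
    """Metabolized energy (kJ): PI times foraging-plus-active time on
    habitats suitable for foraging; zero elsewhere."""
    if forage_h < 0 or active_h < 0:
        raise ValueError("time must be non-negative")
    if habitat not in FORAGE_HABITATS:
        return 0.0
    return pi_kj_h * (forage_h + active_h)
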