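"""From accelerometer bursts to behaviours, and from fixes to daily time budgets.

A burst is 10 triaxial samples at 20 Hz (0.5 s).  Four features — overall
dynamic body acceleration (ODBA), mean pitch, and the mean absolute time
derivatives of the x and y axes — feed a 50-tree random forest trained on a
40/60 split of the annotated set.  Classified fixes are resampled to one per
30 min, foraging-on-water fixes are corrected to inactive (wave artefact),
and per-bird daily budgets split behaviour minutes by day/night and habitat,
with each night credited to the date of its sunset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .energetics import FORAGE_HABITATS
from .ephemeris import moon_intervals, night_window, solar_events

__all__ = [
    "FEATURE_NAMES",
    "ConfusionReport",
    "acc_features",
    "features_table",
    "train_classifier",
    "kappa",
    "resample_fixes",
    "water_correction",
    "annotate_day_night",
    "daily_time_budget",
]

FEATURE_NAMES = ("odba", "mean_pitch", "dx_abs", "dy_abs")
_HZ = 20.0


@dataclass
class ConfusionReport:
    classes: tuple[str, ...]
    matrix: np.ndarray  # rows true, cols predicted
    per_class_precision: dict[str, float]
    overall_accuracy: float
    kappa: float
    n_test: int


def acc_features(burst: np.ndarray) -> dict[str, float]:
    """Feature vector for one burst, shape (10, 3) columns (x, y, z) in g.

    ODBA sums, over axes, the mean absolute deviation from the within-burst
    mean (the static component; the 0.5-s burst is too short for a running
    mean).  Pitch is the angle of the anterior (x) axis against gravity,
    asin(mean_x / ||mean vector||), in degrees.  The derivative features are
    the mean absolute successive difference times the 20 Hz sampling rate.
    """
    a = np.asarray(burst, dtype=float)
    if a.shape != (10, 3):
        raise ValueError(f"burst must have shape (10, 3), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("burst contains non-finite values")
    mean = a.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        raise ValueError("zero-norm mean acceleration: pitch undefined")
    odba = float(np.abs(a - mean).mean(axis=0).sum())
    pitch = float(np.degrees(np.arcsin(np.clip(mean[0] / norm, -1.0, 1.0))))
    diffs = np.abs(np.diff(a, axis=0)).mean(axis=0) * _HZ
    return {"odba": odba, "mean_pitch": pitch,
            "dx_abs": float(diffs[0]), "dy_abs": float(diffs[1])}


def features_table(bursts) -> pd.DataFrame:
    """Feature rows for an iterable of (label, burst) pairs."""
    rows = []
    for label, burst in bursts:
        f = acc_features(burst)
        f["label"] = label
        rows.append(f)
    return pd.DataFrame(rows)


def kappa(matrix) -> float:
    """Cohen's kappa from a square confusion matrix (rows true, cols predicted).

    Returns NaN when expected chance agreement is 1 (degenerate margins).
    """
    m = np.asarray(matrix, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def train_classifier(features: pd.DataFrame, train_frac: float = 0.4,
                     n_trees: int = 50, seed: int = 0):
    """Train the burst random forest and report held-out performance.

    ``features`` has the four feature columns plus ``label``.  The set is
    split train_frac / (1 - train_frac); if the random split drops a class
    from the training half, a stratified re-split is used (with a warning).
    Returns (classifier, ConfusionReport).
    """
    x = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least two behaviour classes to train")
    xtr, xte, ytr, yte = train_test_split(x, y, train_size=train_frac, random_state=seed)
    if set(ytr) != set(classes):
        warnings.warn("class missing from training split; re-splitting stratified")
        xtr, xte, ytr, yte = train_test_split(
            x, y, train_size=train_frac, random_state=seed, stratify=y
        )
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(xtr, ytr)
    pred = clf.predict(xte)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(yte, pred):
        mat[idx[t], idx[p]] += 1
    col = mat.sum(axis=0)
    precision = {
        c: (mat[i, i] / col[i] if col[i] else float("nan")) for c, i in idx.items()
    }
    report = ConfusionReport(
        classes=classes,
        matrix=mat,
        per_class_precision=precision,
        overall_accuracy=float(np.trace(mat) / mat.sum()),
        kappa=kappa(mat),
        n_test=int(mat.sum()),
    )
    return clf, report


def holdout_size(n_samples: int, train_frac: float = 0.4) -> int:
    """Held-out set size under the train/test split (train rounded up)."""
    return n_samples - int(np.ceil(n_samples * train_frac))


def resample_fixes(fixes: pd.DataFrame, interval_min: int = 30) -> pd.DataFrame:
    """Thin fixes to one per interval slot per bird (first fix in slot kept).

    Slots are aligned to midnight UTC.  The retained fix's behaviour stands
    for the whole slot; ``dt_min`` is set to the slot length.  Empty slots
    are simply absent and surface later as missing minutes.
    """
    df = fixes.sort_values(["bird_id", "timestamp"]).copy()
    slot = df["timestamp"].dt.floor(f"{interval_min}min")
    df["slot"] = slot
    out = df.groupby(["bird_id", "slot"], as_index=False).first()
    out["dt_min"] = float(interval_min)
    return out.drop(columns="slot").sort_values(["bird_id", "timestamp"]).reset_index(drop=True)


def water_correction(fixes: pd.DataFrame) -> pd.DataFrame:
    """Re-label foraging-on-water fixes as inactive.

    Wave motion mimics the foraging accelerometer signature, so apparent
    foraging on open water is treated as resting.  Other behaviours on water
    are untouched.
    """
    out = fixes.copy()
    mask = (out["behavior"] == "foraging") & (out["habitat"] == "water")
    out.loc[mask, "behavior"] = "inactive"
    return out


def _solar_cache(dates, lat, lon):
    return {d: solar_events(d, lat, lon) for d in dates}


def annotate_day_night(fixes: pd.DataFrame, lat: float, lon: float) -> pd.DataFrame:
    """Add ``is_day`` and ``night_date`` columns.

    A fix is day iff sunrise <= t < sunset for its calendar date.  Night
    fixes are attributed to the night starting at the most recent sunset:
    pre-dawn fixes belong to the previous date's night.
    """
    out = fixes.copy()
    ts = out["timestamp"]
    dates = ts.dt.date
    cache = _solar_cache(sorted(set(dates)) + [min(dates) - timedelta(days=1)], lat, lon)
    is_day = np.empty(len(out), dtype=bool)
    night_date = np.empty(len(out), dtype=object)
    for i, (t, d) in enumerate(zip(ts, dates)):
        sol = cache[d]
        if sol.polar_day:
            is_day[i], night_date[i] = True, pd.NaT
        elif sol.polar_night:
            is_day[i], night_date[i] = False, d
        else:
            t_naive = t.to_pydatetime().replace(tzinfo=None)
            if sol.sunrise <= t_naive < sol.sunset:
                is_day[i], night_date[i] = True, pd.NaT
            else:
                is_day[i] = False
                night_date[i] = d if t_naive >= sol.sunset else d - timedelta(days=1)
    out["is_day"] = is_day
    out["night_date"] = night_date
    return out


def moonlit_by_date(dates, lat: float, lon: float,
                    moon_table: pd.DataFrame | None = None) -> dict[_date, float]:
    """Moonlit hours for the night starting at each date."""
    out = {}
    for d in dates:
        nw = night_window(d, lat, lon)
        if nw is None:
            out[d] = 0.0
            continue
        tbl = None
        if moon_table is not None:
            tbl = moon_table[moon_table["date"] == d]
        moon_intervals(nw, lat, lon, moon_table=tbl)
        out[d] = nw.moonlit_hours
    return out


def daily_time_budget(fixes: pd.DataFrame, lat: float, lon: float,
                      interval_min: int = 30,
                      moonlit: dict | None = None) -> pd.DataFrame:
    """Per-bird per-date budget of behaviour minutes by day/night and habitat.

    Input fixes must be resampled and carry behavior/habitat columns; day/
    night annotation is applied here if absent.  Day minutes are credited to
    the fix's calendar date, night minutes to the date of the night's sunset,
    missing minutes to the calendar date with absent slots, so that summed
    over a whole track: classified + missing = n_days * 1440.
    """
    df = fixes if "is_day" in fixes.columns else annotate_day_night(fixes, lat, lon)
    df = df.copy()
    df["date"] = df["timestamp"].dt.date
    df["budget_date"] = np.where(df["is_day"], df["date"], df["night_date"])

    dates = sorted(set(df["date"]))
    sol = _solar_cache(dates, lat, lon)
    if moonlit is None:
        moonlit = moonlit_by_date(dates, lat, lon)

    def habcol(h):
        return h if h in FORAGE_HABITATS else "other"

    rows = {}
    cols = (
        ["forage_day_agricultural_min", "forage_day_natural_min", "forage_day_other_min",
         "forage_night_agricultural_min", "forage_night_natural_min", "forage_night_other_min",
         "active_agricultural_min", "active_natural_min", "active_other_min",
         "inactive_min", "flying_min", "missing_min"]
    )

    def row(bird, d):
        key = (bird, d)
        if key not in rows:
            rows[key] = dict.fromkeys(cols, 0.0)
            rows[key]["bird_id"] = bird
            rows[key]["date"] = d
            rows[key]["day_length_h"] = sol[d].day_length_h if d in sol else np.nan
            rows[key]["moonlit_h"] = moonlit.get(d, np.nan)
        return rows[key]

    for rec in df.itertuples():
        r = row(rec.bird_id, rec.budget_date)
        minutes = rec.dt_min
        if rec.behavior == "foraging":
            part = "day" if rec.is_day else "night"
            r[f"forage_{part}_{habcol(rec.habitat)}_min"] += minutes
        elif rec.behavior == "active":
            r[f"active_{habcol(rec.habitat)}_min"] += minutes
        elif rec.behavior == "flying":
            r["flying_min"] += minutes
        else:
            r["inactive_min"] += minutes

    # missing slots, per bird and calendar date
    slots_per_day = int(round(1440 / interval_min))
    for bird, grp in df.groupby("bird_id"):
        counts = grp.groupby("date").size()
        for d in pd.date_range(grp["date"].min(), grp["date"].max(), freq="D").date:
            present = int(counts.get(d, 0))
            if present < slots_per_day:
                row(bird, d)["missing_min"] += (slots_per_day - present) * interval_min

    out = pd.DataFrame(rows.values())
    front = ["bird_id", "date", "day_length_h", "moonlit_h"]
    return out[front + cols].sort_values(["bird_id", "date"]).reset_index(drop=True)
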