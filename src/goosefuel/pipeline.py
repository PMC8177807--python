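"""End-to-end orchestration: generate -> classify -> budgets -> energetics ->
trajectories -> inference -> sensitivity, with CSV/JSON artefacts and a
manifest recording inputs, parameters, seed, and output hashes."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, bmt, inference, intake, synthetic
from .energetics import BEHAVIORS, HABITATS, EnergeticsParams
from .synthetic import SimConfig

__all__ = ["PipelineConfig", "run_pipeline", "validate_tables", "ValidationReport"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; YAML-serialisable."""

    outdir: str = "goosefuel_out"
    seed: int = 0
    use_generator: bool = True
    tracks_path: str | None = None
    weather_path: str | None = None
    intake_path: str | None = None
    moon_table_path: str | None = None
    sim: dict = field(default_factory=dict)            # SimConfig overrides
    energetics: dict = field(default_factory=dict)     # EnergeticsParams overrides
    scenarios: tuple = ("baseline", "no_night", "max_foraging")
    start_mass_g: float = bmt.DEFAULT_START_MASS_G
    gdd_base_temp_c: float = 0.0
    breakpoint_start: float = 4.0
    n_pi: int = 50
    n_bmr: int = 50
    n_both: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.scenarios, list):
            cfg.scenarios = tuple(cfg.scenarios)
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def energetics_params(self) -> EnergeticsParams:
        p = EnergeticsParams(**self.energetics)
        if self.energetics:
            log.info("energetics parameter overrides: %s", self.energetics)
        return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, until: str = "sensitivity") -> dict:
    """Execute the pipeline and return the in-memory artefacts.

    ``until`` stops after a named stage (generate, classify, budgets,
    energetics, bmt, inference, sensitivity).  Outputs land in
    ``config.outdir`` together with ``manifest.json``; a stage failure raises
    with the stage named, leaving earlier outputs in place.
    """
    order = ["generate", "classify", "budgets", "energetics", "bmt",
             "inference", "sensitivity"]
    if until not in order:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": config}
    stop = order.index(until)
    for stage in order[: stop + 1]:
        try:
            globals()[f"_stage_{stage}"](config, state, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest(config, outdir)
    return state


def _stage_generate(config: PipelineConfig, state: dict, outdir: Path) -> None:
    sim = config.sim_config()
    state["sim"] = sim
    if config.use_generator:
        tracks = synthetic.generate_track(sim)
        weather = synthetic.generate_weather(sim)
        intake_obs = synthetic.generate_intake_obs(sim)
        bursts = synthetic.generate_bursts(sim)
    else:
        missing = [
            n for n, p in [("tracks", config.tracks_path),
                           ("weather", config.weather_path),
                           ("intake", config.intake_path)] if p is None
        ]
        if missing:
            raise ValueError(
                f"generator disabled and no path for: {', '.join(missing)}"
            )
        tracks = pd.read_csv(config.tracks_path, parse_dates=["timestamp"])
        weather = pd.read_csv(config.weather_path, parse_dates=["timestamp"])
        intake_obs = pd.read_csv(config.intake_path)
        bursts = synthetic.generate_bursts(sim)
    state.update(tracks=tracks, weather=weather, intake_obs=intake_obs, bursts=bursts)
    _write(tracks, outdir / "tracks.csv")
    _write(weather, outdir / "weather.csv")
    _write(intake_obs, outdir / "intake_obs.csv")
    rows = []
    for i, (label, burst) in enumerate(bursts):
        row = {"burst_id": i, "label": label}
        for j, ax in enumerate("xyz"):
            for k in range(10):
                row[f"{ax}{k}"] = burst[k, j]
        rows.append(row)
    _write(pd.DataFrame(rows), outdir / "bursts.csv")


def _stage_classify(config: PipelineConfig, state: dict, outdir: Path) -> None:
    feats = behavior.features_table(state["bursts"])
    clf, report = behavior.train_classifier(feats, seed=config.seed)
    state["classifier"], state["classifier_report"] = clf, report
    with open(outdir / "classifier_report.json", "w") as fh:
        json.dump(
            {
                "classes": list(report.classes),
                "matrix": report.matrix.tolist(),
                "per_class_precision": report.per_class_precision,
                "overall_accuracy": report.overall_accuracy,
                "kappa": report.kappa,
                "n_test": report.n_test,
            },
            fh, indent=1,
        )


def _stage_budgets(config: PipelineConfig, state: dict, outdir: Path) -> None:
    sim = state["sim"]
    fixes = behavior.resample_fixes(state["tracks"], sim.fix_interval_min)
    fixes = behavior.water_correction(fixes)
    fixes = behavior.annotate_day_night(fixes, sim.site_lat, sim.site_lon)
    state["fixes"] = fixes
    moon_table = None
    if config.moon_table_path:
        from .ephemeris import load_moon_table

        moon_table = load_moon_table(config.moon_table_path)
    dates = sorted(set(fixes["timestamp"].dt.date))
    state["moonlit"] = behavior.moonlit_by_date(
        dates, sim.site_lat, sim.site_lon, moon_table
    )
    budgets = behavior.daily_time_budget(
        fixes, sim.site_lat, sim.site_lon, sim.fix_interval_min, state["moonlit"]
    )
    state["budgets"] = budgets
    _write(budgets, outdir / "budgets.csv")


def _stage_energetics(config: PipelineConfig, state: dict, outdir: Path) -> None:
    weather = state["weather"]
    daily_temp = (
        weather.set_index("timestamp")["t_air_c"].resample("D").mean()
    )
    daily_temp.index = daily_temp.index.date
    gdd = intake.growing_degree_days(daily_temp, config.gdd_base_temp_c)
    pi_model = intake.fit_pi_regression(state["intake_obs"])
    pi_model.to_json(outdir / "pi_model.json")
    state["gdd"], state["pi_model"] = gdd, pi_model
    params = config.energetics_params()
    state["params"] = params


def _stage_bmt(config: PipelineConfig, state: dict, outdir: Path) -> None:
    params, pi_model, gdd = state["params"], state["pi_model"], state["gdd"]
    fixes = state["fixes"]
    scen_fixes = {"baseline": fixes}
    if "no_night" in config.scenarios:
        scen_fixes["no_night"] = bmt.apply_no_night_scenario(fixes)
    if "max_foraging" in config.scenarios:
        scen_fixes["max_foraging"] = bmt.apply_max_foraging_scenario(fixes)
    start_mass = bmt.start_mass_from_size(explicit_g=config.start_mass_g)
    state["start_mass"] = {b: start_mass for b in fixes["bird_id"].unique()}

    trajectories: dict[str, dict[str, bmt.BMT]] = {}
    arrays: dict[str, dict[str, dict]] = {}
    for scenario in config.scenarios:
        trajectories[scenario] = {}
        arrays[scenario] = {}
        frames = []
        for bird, grp in scen_fixes[scenario].groupby("bird_id"):
            arrs = bmt.precompute_energetics(grp, state["weather"], pi_model, gdd, params)
            mass, unreal = bmt.run_recursion(arrs, start_mass, params)
            last = pd.Timestamp(arrs["timestamps"][-1]) + pd.Timedelta(
                seconds=arrs["dt_s"][-1]
            )
            traj = bmt.BMT(
                bird, scenario,
                np.append(arrs["timestamps"], np.datetime64(last)),
                mass, start_mass, unreal,
            )
            trajectories[scenario][bird] = traj
            arrays[scenario][bird] = arrs
            frames.append(traj.to_frame())
        _write(pd.concat(frames, ignore_index=True), outdir / f"bmt_{scenario}.csv")
    state["trajectories"], state["arrays"] = trajectories, arrays


def _daily_mass(traj: bmt.BMT) -> pd.Series:
    s = pd.Series(traj.mass_g, index=pd.to_datetime(traj.timestamps))
    return s.resample("D").last()


def _stage_inference(config: PipelineConfig, state: dict, outdir: Path) -> None:
    trajectories = state["trajectories"]
    rows, metric_rows = [], []
    for bird, traj in trajectories["baseline"].items():
        daily = _daily_mass(traj)
        doy = np.array([t.dayofyear for t in daily.index], dtype=float)
        fit = inference.fit_breakpoint(doy, daily.to_numpy(), config.breakpoint_start)
        metrics = bmt.departure_metrics(traj, breakpoint_day=fit.breakpoint)
        rows.append(
            {
                "bird_id": bird, "scenario": "baseline",
                "breakpoint_doy": fit.breakpoint, "pre_slope": fit.pre_slope,
                "post_slope": fit.post_slope, "degenerate": fit.degenerate,
            }
        )
        rec = {
            "bird_id": bird,
            "baseline_max_mass_g": metrics.max_mass_g,
            "baseline_t_max": metrics.time_max_mass,
            "baseline_onset_doy": fit.breakpoint,
            "baseline_deposition_days": metrics.deposition_period_days,
        }
        if "max_foraging" in trajectories:
            mf = trajectories["max_foraging"][bird]
            daily_mf = _daily_mass(mf)
            doy_mf = np.array([t.dayofyear for t in daily_mf.index], dtype=float)
            fit_mf = inference.fit_breakpoint(
                doy_mf, daily_mf.to_numpy(), config.breakpoint_start
            )
            m_mf = bmt.departure_metrics(
                mf, breakpoint_day=fit_mf.breakpoint,
                reference_mass_g=metrics.max_mass_g,
            )
            rec.update(
                maxfor_onset_doy=fit_mf.breakpoint,
                maxfor_t_reach=m_mf.time_reached_reference,
                maxfor_reached=m_mf.reference_reached,
            )
            rows.append(
                {
                    "bird_id": bird, "scenario": "max_foraging",
                    "breakpoint_doy": fit_mf.breakpoint, "pre_slope": fit_mf.pre_slope,
                    "post_slope": fit_mf.post_slope, "degenerate": fit_mf.degenerate,
                }
            )
        if "no_night" in trajectories:
            nn = trajectories["no_night"][bird]
            rec["no_night_min_mass_g"] = float(np.min(nn.mass_g))
            rec["baseline_min_mass_g"] = float(np.min(traj.mass_g))
        metric_rows.append(rec)
    breakpoints = pd.DataFrame(rows)
    metrics_df = pd.DataFrame(metric_rows)
    _write(breakpoints, outdir / "breakpoints.csv")
    _write(metrics_df, outdir / "metrics.csv")
    state["breakpoints"], state["metrics"] = breakpoints, metrics_df

    comparisons = {}
    if "max_foraging" in trajectories:
        onset = inference.compare_scenarios(
            metrics_df["baseline_onset_doy"], metrics_df["maxfor_onset_doy"]
        )
        reached = metrics_df.dropna(subset=["maxfor_t_reach"])
        t_base = reached["baseline_t_max"].map(inference._doy)
        t_mf = reached["maxfor_t_reach"].map(inference._doy)
        departure = inference.compare_scenarios(t_base.to_numpy(), t_mf.to_numpy())
        comparisons = {
            "onset": onset.summary(),
            "onset_median_diff_days": onset.median_difference,
            "departure": departure.summary(),
            "departure_advance_days": float(np.mean(t_base - t_mf)),
        }
    if "no_night" in trajectories:
        minmass = inference.compare_scenarios(
            metrics_df["baseline_min_mass_g"], metrics_df["no_night_min_mass_g"]
        )
        comparisons["min_mass"] = minmass.summary()
        comparisons["min_mass_median_diff_g"] = minmass.median_difference
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1, default=str)
    state["comparisons"] = comparisons


def _stage_sensitivity(config: PipelineConfig, state: dict, outdir: Path) -> None:
    if "max_foraging" not in state["arrays"]:
        log.info("max_foraging scenario disabled; skipping sensitivity")
        return
    report = inference.sensitivity_analysis(
        state["arrays"]["baseline"], state["arrays"]["max_foraging"],
        state["start_mass"], pi_sd=state["pi_model"].pooled_intercept_sd,
        n_pi=config.n_pi, n_bmr=config.n_bmr, n_both=config.n_both,
        seed=config.seed, params=state["params"],
    )
    grid = inference.two_sd_grid(
        state["arrays"]["baseline"], state["arrays"]["max_foraging"],
        state["start_mass"], pi_sd=state["pi_model"].pooled_intercept_sd,
        params=state["params"],
    )
    state["sensitivity"], state["two_sd_grid"] = report, grid
    _write(report.runs, outdir / "sensitivity_runs.csv")
    _write(grid, outdir / "two_sd_grid.csv")
    with open(outdir / "sensitivity_summary.json", "w") as fh:
        json.dump(
            {
                "requested": report.requested,
                "retained": report.retained,
                "omitted": len(report.omitted),
                "summary": report.summary(),
            },
            fh, indent=1,
        )


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    files = sorted(p for p in outdir.iterdir() if p.suffix in (".csv", ".json"))
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {p.name: _sha256(p) for p in files if p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file: str, row, message: str) -> None:
        self.violations.append({"file": file, "row": row, "message": message})


def validate_tables(tracks_path=None, weather_path=None, intake_path=None) -> ValidationReport:
    """Schema, vocabulary, and timestamp-ordering checks on input CSVs."""
    rep = ValidationReport()
    if tracks_path is not None:
        df = pd.read_csv(tracks_path, parse_dates=["timestamp"])
        for col in ("bird_id", "timestamp", "lat", "lon", "behavior", "habitat", "dt_min"):
            if col not in df.columns:
                rep.add(str(tracks_path), None, f"missing column {col!r}")
        if "behavior" in df.columns:
            bad = ~df["behavior"].isin(BEHAVIORS)
            for i in df.index[bad]:
                rep.add(str(tracks_path), int(i),
                        f"behavior vocabulary violation: {df.at[i, 'behavior']!r}")
        if "habitat" in df.columns:
            bad = ~df["habitat"].isin(HABITATS)
            for i in df.index[bad]:
                rep.add(str(tracks_path), int(i),
                        f"habitat vocabulary violation: {df.at[i, 'habitat']!r}")
        if {"bird_id", "timestamp"} <= set(df.columns):
            for bird, grp in df.groupby("bird_id"):
                ts = grp["timestamp"]
                nonmono = ts.diff().dt.total_seconds() <= 0
                for i in grp.index[nonmono.fillna(False)]:
                    rep.add(str(tracks_path), int(i),
                            f"non-monotone timestamp for bird {bird}")
        if "dt_min" in df.columns:
            for i in df.index[df["dt_min"] <= 0]:
                rep.add(str(tracks_path), int(i), "non-positive fix interval")
    if weather_path is not None:
        df = pd.read_csv(weather_path, parse_dates=["timestamp"])
        for col in ("timestamp", "t_air_c", "u10", "v10", "radiation_wm2", "cloud"):
            if col not in df.columns:
                rep.add(str(weather_path), None, f"missing column {col!r}")
        if "cloud" in df.columns:
            bad = (df["cloud"] < 0) | (df["cloud"] > 1)
            for i in df.index[bad]:
                rep.add(str(weather_path), int(i), "cloud fraction outside [0, 1]")
        if "timestamp" in df.columns:
            nonmono = df["timestamp"].diff().dt.total_seconds() <= 0
            for i in df.index[nonmono.fillna(False)]:
                rep.add(str(weather_path), int(i), "non-monotone timestamp")
    if intake_path is not None:
        df = pd.read_csv(intake_path)
        for col in ("habitat", "gdd", "intake_kj_h"):
            if col not in df.columns:
                rep.add(str(intake_path), None, f"missing column {col!r}")
        if "gdd" in df.columns:
            for i in df.index[df["gdd"] < 0]:
                rep.add(str(intake_path), int(i), "negative GDD")
    return rep
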