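# goosefuel

Wintering Arctic-breeding geese must deposit large energy reserves before
spring migration, and how early and how fast they can fuel is constrained by
daylight, moonlit nights, food quality, and thermoregulation costs.
`goosefuel` is a tested Python implementation of the full analysis chain for
this problem: from triaxial-accelerometer bursts and GPS fixes to behavioural
time budgets, per-interval energy budgets, simulated body-mass trajectories
under baseline and counterfactual night-foraging scenarios, fueling-onset
breakpoints, and a parameter-sensitivity analysis. A synthetic-data module
generates tracking, weather, calibration-burst, and field-intake tables with
the statistical structure the analysis assumes, so every stage runs and is
testable without any external data service.

It is aimed at movement ecologists and behavioural bioenergeticists who want
a reproducible, scriptable version of this modelling chain, or who want to
plug their own tracking tables into it.

## The model

**Behaviour.** Each GPS fix carries a 0.5-s burst of triaxial acceleration
(10 samples at 20 Hz). Four features — overall dynamic body acceleration
(ODBA, the per-axis mean absolute deviation from the burst-mean, summed),
mean pitch, and the mean absolute time derivatives of the *x* and *y* axes —
feed a 50-tree random forest that labels each burst *inactive*, *active*,
*foraging*, or *flying* (40/60 train/test split; Cohen's κ reported).
Fixes are thinned to one per 30 min; apparent foraging on open water is
corrected to inactive (wave artefact).

**Energetics.** For each inter-fix interval *t*:

- existence energy  E_e = BMR · b · t, with behaviour multipliers
  b ∈ {inactive 1.5, active 1.9, foraging 1.6} and flight costed separately;
- basal metabolic rate scales proportionally with mass,
  BMR_i = (W_i / W_ref) · BMR_ref with BMR_ref = 5.536 W at W_ref = 1825 g
  (so a 1600-g bird has BMR = 4.853 W);
- thermoregulation E_t follows a biophysical heat-loss model below the lower
  critical temperature (~10 °C), driven by air temperature, 10-m wind and
  shortwave radiation (pluggable parameterisation);
- activity heat substitutes for thermoregulation: E_s = max(E_t, E_e) + E_flight.

**Intake.** Habitat-specific potential metabolizable intake rate (kJ/h) is
linear in cumulative growing degree days, fitted by OLS to field
observations; realised intake multiplies it by foraging-plus-active time on
habitats suitable for foraging.

**Body-mass trajectory (BMT).** Mass is stepped fix by fix:
W_i = W_{i−1} + η · (I_i − E_s)/e, storing surpluses at η = 0.8, burning
deficits at η = 1, with tissue energy density e = 29 kJ/g. Counterfactual
scenarios rewrite night behaviour before simulation: `no_night` makes all
nights inactive; `max_foraging` replays each bird's January night budgets one
30-day lunar cycle later (night-of-year ((n−1) mod 30) + 1).

**Inference.** The fueling onset is the breakpoint of a continuous hinge
regression of daily mass (or foraging time) on day-of-year, chosen by
maximum Gaussian likelihood; scenarios are compared per bird with Wilcoxon
signed-rank tests; sensitivity re-simulates all trajectories under normal
perturbations of the PI intercept and BMR_ref (5.54 ± 0.42 W).

## Worked example

```python
from goosefuel.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo", seed=42,
                     sim={"n_birds": 6}, n_pi=10, n_bmr=10, n_both=20)
state = run_pipeline(cfg)

rep = state["classifier_report"]
print(f"classifier: accuracy {rep.overall_accuracy:.3f}, kappa {rep.kappa:.3f} "
      f"on {rep.n_test} held-out bursts")
m = state["metrics"]
print(f"baseline minimum mass  {m['baseline_min_mass_g'].mean():.0f} g "
      f"vs no-night {m['no_night_min_mass_g'].mean():.0f} g")
print("departure-mass advance:",
      f"{state['comparisons']['departure_advance_days']:.1f} days")
print(state["sensitivity"].summary())
```

prints

```
classifier: accuracy 1.000, kappa 1.000 on 567 held-out bursts
baseline minimum mass  1546 g vs no-night 1469 g
departure-mass advance: 7.8 days
Sensitivity runs: 40 requested, 40 retained, 0 omitted
  bmr: mean timing difference 7.77 days (n=10)
  both: mean timing difference 7.76 days (n=20)
  pi: mean timing difference 7.76 days (n=10)
```

Read: on the synthetic study conditions, the burst classifier separates the
four behaviours essentially perfectly on the 567-burst hold-out; suppressing
nocturnal foraging costs the birds ~80 g of winter body mass; and exploiting
all moonlit night-time would let them reach departure body mass about a week
earlier — a figure that is stable under sampled intake and metabolic-rate
parameters. The same pipeline is available from the shell
(`goosefuel run-all --seed 42`, plus per-stage subcommands and `goosefuel
validate` for input tables).

## Layout

- `goosefuel.synthetic` — study-condition generators (tracks, bursts, weather, intake)
- `goosefuel.ephemeris` — NOAA solar events, low-precision lunar intervals, moonlit hours
- `goosefuel.behavior` — burst features, random-forest classifier, time budgets
- `goosefuel.energetics` — BMR, existence/thermoregulation/flight costs
- `goosefuel.intake` — growing degree days and the PI regression
- `goosefuel.bmt` — mass recursion, scenarios, departure metrics
- `goosefuel.inference` — hinge breakpoints, Wilcoxon comparisons, sensitivity
- `goosefuel.pipeline` / `goosefuel.cli` — orchestration, validation, CLI

See `docs/methods.md` for model details, parameter defaults, and limitations.
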