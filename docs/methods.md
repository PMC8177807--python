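# Methods

This note documents the models implemented in `goosefuel`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user may want to override.

## Ephemeris

Sunrise and sunset use the NOAA solar-position algorithm (Meeus-style
truncated series) with the conventional −0.833° rise/set altitude
(refraction plus solar semidiameter); no further atmospheric or topographic
modelling. The solar series is evaluated at local solar noon with one
refinement pass, which keeps events within ~1 min of the reference
calculator at temperate latitudes. Polar day and polar night are flagged
rather than raising.

All timestamps are handled as naive UTC. Local civil time never enters the
computation, which avoids DST ambiguity for a study area spanning the
Dutch–German coast.

A *night* runs from a date's sunset to the next sunrise and is attributed to
the date of its sunset; civil twilight is not subtracted, so pre-dawn
foraging counts as night. Lunar altitude uses the Astronomical Almanac
low-precision series (~0.3°, valid 1900–2100) with an approximate parallax
correction (alt − π·cos alt); the moon counts as visible when above the
geometric horizon — its illuminated fraction is deliberately not used.
Moon-up intervals within a night are found on a one-minute altitude grid and
merged; an injected moonrise/moonset CSV can replace the algorithmic path
and is the reference path in the tests.

## Behaviour classification

Features per 10-sample 20-Hz burst: ODBA (sum over axes of mean absolute
deviation from the within-burst mean — the burst is too short for a running
static estimate), mean pitch asin(mean_x/‖mean‖) in degrees, and the mean
absolute successive difference of x and y times 20 Hz. The four features are
fixed; no feature-selection step is re-run. Pitch sign convention: positive
x = anterior axis up, so head-down grazing produces negative pitch in the
generator — only separability matters, not the sign itself.

The classifier is a 50-tree random forest trained on a random 40% of the
labelled set and evaluated on the remaining 60% (945 bursts → 567 test
samples at the defaults). If the random split drops a class from the
training half, the split is redone stratified with a warning. The confusion
report carries per-class precision, overall accuracy, and Cohen's κ
(computed in-package, cross-checked against scikit-learn in a test).

## Time budgets

Fixes are thinned to the first fix per 30-min slot (slots aligned to
midnight UTC); the retained behaviour stands for the whole slot. Foraging on
open-water habitat is re-labelled inactive before budgeting, because wave
motion mimics the grazing signature. Daily budgets split minutes by
behaviour × day/night × habitat; day minutes are credited to the calendar
date, night minutes to the night's sunset date, and absent slots accumulate
as missing minutes on their calendar date. Because a sunset-anchored night
spills past midnight, a single budget row spans slightly more or less than
24 h; conservation is exact in aggregate: over any whole track, classified +
missing minutes equal days × 1440.

## Energetics

Existence energy E_e = BMR·b·t with b = 1.5/1.9/1.6 for
inactive/active/foraging and zero for flight (costed separately). BMR scales
proportionally with mass around 5.536 W at 1825 g.

Thermoregulation uses a documented default biophysical parameterisation with
a plug-in point (`EnergeticsParams.thermo_model`) for any exact published
formula. Default model: operative temperature T_op = T_air + a·S·r_b/(ρc_p)
with solar absorptivity a = 0.3 and shortwave radiation S; below the lower
critical temperature (10 °C) heat is lost at A·ρc_p·(LCT − T_op)/(r_p + r_b),
where A is a Meeh surface area (10·W_g^⅔ cm²), r_p the plumage resistance
(default 200 s/m, configurable; species-specific values should be
substituted), and r_b = 307·√(d/u) s/m a forced-convection boundary-layer
resistance for characteristic dimension d = bird height 0.15 m, with the
10-m wind scaled to bird height by a log profile (z₀ = 1 cm). At 0 °C and
3 m/s this yields ~6 W for a 1600-g bird — of the same order as BMR, as
expected for a goose in winter. Shortwave-only radiation is the default;
the whole function is replaceable. The model guarantees, and the tests
enforce, that cost is non-increasing in air temperature and radiation and
non-decreasing in wind.

Thermoregulation always uses the fixed 1600-g parameterisation while
existence energy uses the evolving trajectory mass — an asymmetry kept
deliberately from the underlying energetics treatment.

Flight: intervals are flagged as flight when the accelerometer class says so
or when the great-circle displacement implies ground speed above 20 km/h
(the annotation threshold; configurable — the exact detection speed used in
the original workflow is not printed, so the annotation value is the
default). Flight energy is P(airspeed)·t with airspeed = ‖v_ground − wind‖;
the default power curve is a constant 12 × BMR(1600 g) ≈ 58 W, a mid-range
literature value for waterfowl flapping flight, and a U-shaped aerodynamic
curve can be plugged in. Existence energy is zeroed on flight intervals to
prevent double counting.

## Intake

Growing degree days are the cumulative sum of max(0, T_day − T_base) with
T_base = 0 °C from January 1 (both configurable); the start day's excess is
included, so ten days at one degree above base give 10 °C·day. Potential
intake rate PI (kJ/h) is linear in GDD per habitat, fitted by OLS; the
intercept standard error is retained because the sensitivity analysis
perturbs it. Predictions are floored at 0 kJ/h (negative intake from
extrapolation is unphysical). PI is expressed per hour; realised intake is
PI × (foraging + active hours) on agricultural or natural habitat and zero
elsewhere — foraging on unsuitable habitat should not survive the water
correction, so this is a belt-and-braces rule.

## Body-mass trajectories

Per fix: surplus s = intake − (max(E_t, E_e) + E_flight) in kJ; mass moves
by 0.8·s/29 g when s ≥ 0 and s/29 g when s < 0 (29 kJ/g tissue energy
density; storage efficiency 0.8, mobilisation 1.0). The recursion runs at
the 30-min fix resolution; daily series are aggregated afterwards. A
trajectory that hits non-positive mass is flagged unrealistic rather than
clamped. Start mass is an explicit value, a linear size rule, or the
population default of 1550 g (a mid-winter adult female value).

Scenarios operate on the fix table before simulation. `no_night` sets every
night behaviour to inactive. `max_foraging` replaces each post-January
night's slots (matched by position within the night) with the same bird's
source January night, one 30-day lunar cycle earlier: source night-of-year
((n − 1) mod 30) + 1, anchored at January 1 — the arithmetic that reproduces
all the listed calendar correspondences. The replacement copies behaviour
*and* habitat (intake is habitat-specific, and a night budget includes where
the bird fed), while intake uses the *target* night's GDD, since PI reflects
current food quality. January nights (night-of-year ≤ 30) map to themselves;
a missing source night falls back to the nearest available one, logged.
Source (winter) nights are longer than their spring targets, so truncation
to the target's slot count loses nothing; any slots beyond the source keep
their own labels.

Departure metrics: departure body mass is the trajectory maximum (first
attainment on ties); the energy-deposition period is the time from the
fueling-onset breakpoint to that maximum; for scenario comparison, the first
time the max-foraging trajectory reaches the baseline departure mass is
recorded (flagged when never reached).

## Breakpoint estimation

Fueling onset is the breakpoint ψ of the continuous hinge model
y = b₀ + b₁x + b₂·max(0, x − ψ). For each candidate ψ the linear parameters
are profiled out by least squares; ψ maximises the Gaussian log-likelihood,
equivalent to minimising RSS — Gaussian with constant variance is the
conventional choice when "maximum likelihood" is stated without a family,
and continuity at the break is enforced because an onset interpretation
requires it. The 1-D search is a bounded scalar optimisation backed by a
~200-point grid scan with local refinement, so a poor start value cannot
trap the estimate in a local optimum (the optimiser start value is accepted
for interface compatibility, in day units, and is not load-bearing). The fit
is flagged degenerate when the hinge does not improve on a single line
(pure-linear data) or the RSS profile is flat. The estimator is exactly
shift-equivariant in x, and segmented RSS never exceeds single-line RSS.

Scenario timings are compared per bird with Wilcoxon signed-rank tests; the
V statistic (sum of positive signed ranks, zeros dropped) is computed
in-package and the p-value comes from scipy.

## Sensitivity analysis

Normal perturbations: PI intercept shift ~ N(0, SD_pooled) where SD_pooled
is the habitat-pooled intercept standard error of the fitted PI regression,
and BMR_ref ~ N(5.54, 0.42) W. Default run counts are 500 (PI only), 500
(BMR only) and 1000 (both); the pipeline's bundled configuration scales
these down (50/50/100) so a full run stays interactive — pass `--n-pi` etc.
for the full design. Each run re-simulates baseline and maximum-foraging
trajectories for every bird over precomputed mass-independent arrays, which
makes a run linear in the number of fixes. A run is omitted, with its reason
recorded, when the PI draw falls below −0.5 SD *and* a baseline trajectory
has its maximum on the first study day — under such parameters mass only
declines, the "departure mass" is meaningless, and the baseline/max-foraging
difference is wildly negative. Retained plus omitted runs always equal the
requested count. Deterministic ±2 SD runs produce a five-row grid
(unperturbed, PI ± 2 SD, BMR_ref ± 2 SD) with the same timing summaries.

## Synthetic study conditions

The generator emulates the design of a winter-to-spring goose tracking
study: 23 birds, 30-min fixes from January 1 to mid-May 2015 at a Wadden Sea
site (53.87° N, 7.30° E), with departure jittered up to 4 days per bird.
Daylight slots forage with probability 0.66 — the stable fraction of
daylight spent grazing. Night slots forage with probability
w(doy)·(0.12 + gain/60·moon_up): the moon gain default of 4.6 min of
foraging per moonlit hour is the winter night-model coefficient scale, and
the seasonal weight w holds at 1 through February and tapers to zero by
day 120, reproducing the decline of nocturnal foraging through spring.
Habitat is agricultural, with half the birds switching to natural habitat at
day-of-year 90; rare foraging-on-water artefact fixes (p = 0.004) exercise
the downstream correction. Weather is a linear seasonal ramp of daily mean
temperature (3 → 14 °C) with a diel cycle and AR(1) noise, 6-hourly, plus
wind components and a cloud-damped daytime radiation curve. True PI lines
are agricultural 95 + 0.08·GDD and natural 78 + 0.10·GDD kJ/h (intercept SD
8): chosen so that at the site's GDD trajectory winter intake roughly
balances winter expenditure only when nights are used — suppressing night
foraging produces a clear winter mass deficit — and spring intake fuels
birds from ~1550 g to departure mass by mid-May.

What the generator does *not* emulate: movement (habitat is a label stream,
positions are jittered around the site, so displacement-based flight
detection stays quiet), spatial heterogeneity in weather, observation error
in the accelerometer features beyond class-conditional noise, tidal or
disturbance structure in behaviour, and between-bird heterogeneity in
intake. Passing tests therefore demonstrate internal correctness and the
direction/ordering of scenario effects under controlled conditions — not
that the effect sizes printed from synthetic runs transfer to real tracking
data.

Determinism: every generator and the classifier take a seed; seeded runs
are bit-identical, and the pipeline manifest records output hashes so
reproducibility is checkable end to end.

## Problem sizes in the shipped configuration

The bundled demo/default pipeline configuration runs a handful of birds and
scaled-down sensitivity counts so that a complete run (generation through
sensitivity) takes seconds on one CPU; the full 23-bird, 500/500/1000-run
design is a configuration change, not a code change.

## Known limitations

- The thermoregulation default is a generic biophysical parameterisation
  anchored at the stated constants (LCT 10 °C, height 0.15 m); published
  species-specific coefficient sets should be plugged in for quantitative
  work.
- The flight power curve default is a constant BMR multiple; no
  aerodynamic flight-range modelling.
- Mixed-effects model selection (AICc, variance and autocorrelation
  structures) for the foraging-duration analyses is out of scope; stock
  statistical routines can be applied to the budget tables the pipeline
  writes.
- The lunar series is low-precision (~0.3°); adequate for moonlit-hours at
  1-min resolution, not for precise rise/set times.
- Cloud cover is generated and stored but does not clip moon visibility.
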