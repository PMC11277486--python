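# Methods

This note records the models implemented in `thermaldev`, their assumptions,
the defaults and why they were chosen, and the places where the design was
genuinely open.

## The development model

Development is modelled as thermal summation: above a developmental minimum
`t₀` an individual accumulates physiological time at `(T − t₀)` degree-days
per day, and enters the next life stage when its accumulated thermal age
crosses a per-stage threshold (the stage's thermal constant, ADD). The
developmental minimum is a regression parameter — the x-intercept of the
fitted rate line — and is distinct from the *biological* minimum, the
temperature below which development actually stops. Linearity of the rate
response is an approximation valid only over a mid-range temperature band;
near the biological minimum and at high temperatures the true response is
curvilinear, which is exactly why the degree-day fit is validated and pruned
rather than taken at face value.

Individual variation is placed on the physiological scale: per-stage ADD
thresholds are drawn `Normal(mean, cv·mean)`, truncated to positive values.
Consequences that match stage-frequency data generally: transition times are
normally distributed at every temperature, and their spread scales with
stage duration (the post-feeding third instar and the pupa, the longest
stages, show the largest transition variance). Clock time and physiological
time are related by the rate, so a cohort's transition at temperature `T`
is centred at `24·ADD_cum/(T − t₀)` hours.

## Synthetic cohort generator (`thermaldev.simulate`)

The generator emulates a destructive-sampling rearing study. Defaults are
the reference design:

| parameter | default | meaning |
|---|---|---|
| `temperatures` | 7.5–32.5 °C, 2.5 °C steps (11) | programmed chamber setpoints |
| `eggs_per_cup` | 20 | individuals per experimental unit |
| `replicates` | 4 | cups pulled per sampling time |
| `samples_per_stage` | 5 | sampling times per life stage |
| `true_dev_min` | 10.2 °C | generating developmental minimum |
| `true_stage_add` | 8.4, 12.1, 14.4, 29.3, 30.2, 84.9 dd | E, L1, L2, L3f, L3m, P thermal constants |
| `transition_cv` | 0.05 | CV of individual thresholds |
| `biological_min` | 11.0 °C | no development at or below |
| `linear_range` | 15.0–32.5 °C | band of exact linearity |
| `curvature_strength` | 1.0 | attenuation exponent outside the band |
| `mortality_per_stage` | 0 | per-stage Bernoulli death at stage entry |

The stage thermal constants and the developmental minimum are the published
estimates for *Phormia regina*; the biological minimum sits inside the
published bracket (between 10.0 and 12.5 °C). Below `linear_range` the rate
is multiplied by `((T − biological_min)/(low − biological_min))^s`, which
reaches zero at the biological minimum; above the band it decays as
`exp(−s·(T − high)/5)`. The exact functional form is a package choice — no
curvilinear model is fitted here — and `s = 0` gives a perfectly linear
response for ground-truth experiments.

Sampling schedules are built the way such studies are planned: pilot stage
durations at a reference temperature (derived from the thermal constants
with an *assumed* minimum of 10.0 °C and a 1.1 safety margin, mimicking
a-priori literature estimates) are converted to accumulated degree-hours and
divided into five equal sampling times per stage window; windows are
consecutive, so a transition expected at the end of one stage's window has
its completion captured by the next. Temperatures at or below the assumed
minimum reuse the schedule of the lowest temperature above it (the design
still samples where development is not expected). With the defaults the
egg-stage sampling interval at 25 °C is ~3 h, matching the reference
design's order of magnitude.

Individuals are classified in the earlier stage until their threshold is
crossed, which is the pharate-larva convention (apolysis without ecdysis
does not advance the recorded stage) — in the simulator this holds by
construction. Deaths (optional, default off, since the reference study saw
no temperature-associated mortality worth modelling) occur at stage entry
and are excluded from all denominators downstream.

What the generator does **not** emulate: diet, density, photoperiod and
humidity effects; within-cup correlation beyond shared sampling times;
observation error in staging; non-constant temperature histories. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated stochastic model, not robustness to those real-world factors.

## Stage-frequency curves (`thermaldev.curves`)

Four shapes: Gaussian, modified Gaussian (plateau exponent `d`), cumulative
and reversed-cumulative Gaussian. Fits are ordinary nonlinear least squares
(`scipy.optimize.curve_fit`) with moment-based starts: `a` from the series
maximum, `b` from the peak (peaked forms) or the interpolated half-range
crossing (cumulative forms), `c` from the half-maximum width divided by
`√(2 ln 2)` (or the quartile-crossing distance over 1.349), `d = 2`.
Bounds keep `a ≤ 1.05×` the data scale, `c` within the observation window
and `d ∈ (0.5, 10]` so the plateau exponent cannot blow up. A bounded
solver can never legitimately end worse than its start; if it does, the
start point is kept and flagged. Non-convergence is flagged on the results
object, never silently dropped, and constant series are rejected with the
series named.

Model choice between plain and modified Gaussian for within-stage series is
a plateau rule: at least 3 consecutive points within 5 % of the maximum
selects the modified form. Proportions are computed over live sampled
individuals and pooled across replicate cups at each sampling time before
fitting (replicates are exchangeable cups in identical chambers; per-cup
averaging is available as an option). Cups sampled more than `m·c`
(default `m = 4`) past a fitted transition centre while still holding
earlier-stage individuals are flagged as extended-residence outliers;
exclusion is an explicit opt-in, never automatic.

## Transition times and durations (`thermaldev.transitions`)

Both published routes are implemented. The cumulative-Gaussian route reads
`t50 = b` (the curve crosses half its plateau at its centre) with the
parameter's standard error; it is the default input to the degree-day
chain. The probit route fits a binomial GLM with probit link
(`statsmodels`); `t50 = −intercept/slope`, the delta method gives its
standard error, and the fitted quantile function yields any desired percent
transition. Both estimate the median of the same normal transition-time
distribution and agree within sampling error; the report records which
route produced each number.

Each boundary's cumulative series is truncated at the first time it reaches
its plateau — only the 0–100 % rise informs the transition — and a boundary
is only fitted when at least half the transition was observed
(`min_rise = 0.5`), since a barely-started rise cannot pin the centre.
Durations are differences of consecutive boundary `t50`s; the egg stage's
duration is the first boundary's `t50` itself, so the egg-stage thermal
constant and the first transition's are identical by construction. Missing
boundaries propagate as missing durations, never interpolated; a
non-monotone `t50` sequence signals an upstream fitting failure and is
raised (the pipeline logs and skips the offending stage).

## Degree-day models (`thermaldev.degreeday`)

Rates are `1/days` (hours/24). The regression is unweighted OLS throughout
(no weighting scheme is part of the published procedure). The runs test on
ordered residual signs is exact — the closed-form Wald–Wolfowitz runs
distribution, identical to enumerating all `C(n, n₊)` arrangements — for up
to 20 signed residuals, and a continuity-corrected normal approximation
beyond; zero residuals are dropped; the two-sided p-value is twice the
smaller tail, capped at 1. `alpha = 0.05` for both the runs test and the
zero-slope t-test.

Pruning removes one temperature per iteration, always an endpoint (the
curvilinear tails live at the extremes, and endpoint-only exclusion keeps
the valid range contiguous): the end with the larger absolute standardized
residual, ties toward the low end, since rates collapse more sharply near
the biological minimum. Validation computes `ADD_i = days_i·(T_i − t₀)` at
the retained temperatures and requires the regression of `ADD_i` on `T_i`
to be flat and patternless; otherwise another endpoint is excluded and the
whole loop (regression → runs test → accumulation check) repeats. Every
exclusion is logged with its step and reason, making the procedure
deterministic and auditable. Numerically flat accumulations (all `ADD_i`
equal to within 1e-9 relative) are accepted directly, since a t-test on
pure rounding error is meaningless. The per-temperature `ADD_i` are
summarised by their mean and **population** standard deviation (divisor n,
matching the published tables) plus the percent deviation from the
regression ADD.

### Detection power of the pruning tests

A point worth documenting explicitly: with 8–9 temperatures, a *single*
strongly curved endpoint is mathematically undetectable at `alpha = 0.05`.
The exact two-sided runs test's smallest attainable p-value at n = 9 with
the deterministic single-outlier sign pattern (R = 3) is 0.143, and the
zero-slope t statistic saturates near 1.4 as the outlier grows, because the
outlier inflates the residual variance as fast as the slope. Detection
requires either more temperatures or a curved *region*: on a 1.25 °C grid
(17 temperatures) with two curved sub-15 °C points, the leverage-induced
sign pattern drives the runs test below 0.05 and pruning removes exactly
the curved temperatures. The curvature-specificity checks therefore use
the dense grid with strong curvature; on the default 2.5 °C grid a lone
mildly curved 12.5 °C point can survive pruning, and the resulting bias is
visible in the reported per-temperature ADD spread.

## Problem sizes used in the checks

Ground-truth recovery checks use: a noiseless cohort (cv = 0, no curvature,
one egg, one replicate, 60 samples per stage — destructive sampling
quantises a noiseless step transition to the sampling grid, so the
noiseless check uses a fine grid); 200 stochastic cohorts at the reference
design (cv = 0.05, 20 eggs × 4 replicates × 5 times per stage,
10 developing temperatures); and 30 replicates of the dense-grid curvature
design. Typical results: median absolute developmental-minimum error
~0.03 °C and median relative ADD error ~0.4 % for total development under
the reference design.

## Known limitations

* Constant-temperature treatments only; degree-day accumulation at a
  constant temperature is `days·(T − t₀)` and no hourly integration or
  fluctuating-temperature support is provided.
* No curvilinear rate models (Brière, Logan, …); the attenuation in the
  simulator is a data-generating device, not a fittable model.
* The runs test is conservative at small n (discrete null), so mild
  curvature at few temperatures passes undetected — see the power note
  above; this mirrors the method being modelled rather than a fixable bug.
* The published per-temperature ADD and percent-time summaries ship in
  `thermaldev.datasets` for cross-checking; the raw per-cup observations
  behind them are not redistributed with the package.
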