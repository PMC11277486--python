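# thermaldev

Thermal development modeling for stage-structured insect cohorts, built
around the workflow used in forensic entomology to turn constant-temperature
rearing experiments into **validated linear degree-day models**.

## The scientific problem

The age of a blow-fly immature found on remains is the usual basis of a
minimum postmortem interval. Age is read off laboratory development data
through thermal time: above a developmental minimum `t₀`, development rate is
approximately linear in temperature, so completing an event (say oviposition
to pupariation) takes a fixed number of accumulated degree-days,

```
rate(T) = 1/days = slope · T + intercept
t₀  = −intercept / slope        (x-intercept, the developmental minimum)
ADD = 1/slope                   (thermal constant, degree-days)
```

The catch is that the rate–temperature response is only linear over a band;
using points from the curvilinear tails biases `t₀` and ADD systematically.
This package implements the full chain from raw destructive-sampling stage
counts to degree-day models whose linearity assumptions are explicitly
tested and enforced:

1. **Stage-frequency curves** — the proportion of a cohort in (or past) a
   stage versus time follows a Gaussian family: plain Gaussian
   `y = a·exp(−½((x−b)/c)²)` for transient stages, a modified Gaussian
   `y = a·exp(−½|(x−b)/c|^d)` for long stages that plateau, and cumulative /
   reversed-cumulative Gaussians `y = (a/2)(1 ± erf((x−b)/(√2·c)))` for the
   monotone entry/exit series.
2. **50% transition times** — the centre `b` of a cumulative fit, or
   equivalently a binomial probit regression of P(past the boundary) on
   time; both assume normally distributed individual transition times.
   Stage durations follow by subtraction of consecutive `t50` values.
3. **Validated degree-day regression** — OLS of `1/days` on temperature; a
   Wald–Wolfowitz runs test on the ordered residual signs (exact, by the
   closed-form runs distribution, up to n = 20) detects systematic curvature
   and prunes endpoint temperatures until linearity holds; the degree-day
   accumulations `days·(T − t₀)` at the retained temperatures must then be
   flat (zero-slope t-test) and patternless, or pruning continues. The
   result carries the valid temperature range and a complete exclusion
   audit trail.
4. **Synthetic cohorts** — a generator reproducing the reference study
   design (11 temperatures 7.5–32.5 °C, 20 eggs per cup, five sampling
   times per life stage, four replicates, destructive sampling) with
   normally distributed per-stage thermal thresholds, a biological minimum,
   and configurable curvilinear attenuation at the temperature extremes.

The package is aimed at forensic entomologists and insect ecologists who
build or audit degree-day models from stage-frequency data.

## Worked example

```python
from thermaldev import AnalysisConfig, DevelopmentStudy
from thermaldev.simulate import SimulationConfig, generate_cohort

obs = generate_cohort(SimulationConfig(seed=1))          # simulated study
report = DevelopmentStudy(obs, AnalysisConfig()).run()   # full analysis
print(report.models["E-A"].summary())
```

prints

```
Degree-day model: E-A
  slope 0.00557689 /(day*degC), intercept -0.05701 /day
  dev min 10.22 degC   ADD 179.3 degree-days
  r^2 1.00   n 8   valid range 15.0-32.5 degC
  runs test: R=4 (n+=5, n-=3), p=0.857 [exact]
  ADD accumulation: slope p=0.750, runs p=0.857, mean 179.3 (sd 0.9), deviation vs regression -0.0%
```

The simulated cohort was generated with a true developmental minimum of
10.2 °C and a total (egg-to-adult) thermal constant of 179.3 degree-days;
the fitted model recovers both, keeps the eight temperatures inside the
linear band (15.0–32.5 °C), and the flat degree-day accumulation (slope
p = 0.75) confirms the thermal-summation assumption on the retained range.
`report.percent_time` gives the percent-time-in-stage table (rows sum to
100), `report.degree_day_table` the one-row-per-event summary, and
`report.models[event].exclusions` the pruning trail.

The same chain is scriptable from the shell:

```
thermaldev all --seed 2 --outdir out/          # simulate + full report
thermaldev simulate --seed 2 --out obs.csv     # or stage by stage
thermaldev report --in obs.csv --outdir out/
```

`thermaldev report` accepts CSV or XLSX observation tables (tidy long or
wide stage-count layout; `--help` lists the other subcommands).

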