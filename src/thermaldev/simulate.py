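"""Synthetic cohort generator for destructive-sampling development studies.

Emulates a constant-temperature rearing experiment on a blow-fly cohort: cups
of eggs are held at each test temperature and, at scheduled sampling times,
one cup per replicate is pulled and every individual is staged morphologically
(destructive sampling — a cup is observed once).  The generator draws, for
each individual, per-stage thermal requirements (accumulated degree-days,
ADD) from normal distributions, converts elapsed clock time at a given
temperature into physiological time via a linear rate with optional
curvilinear attenuation at the temperature extremes, and bins individuals
into stages by threshold crossing.

Model assumptions
-----------------
* Individual variation lives on the physiological scale: per-stage ADD
  thresholds are ``Normal(mean, cv * mean)`` truncated to positive values, so
  transition-time spread scales with stage duration at every temperature.
* Development rate is ``(T - true_dev_min)`` degree-days per day inside the
  linear temperature range, attenuated multiplicatively outside it, and zero
  at or below the biological minimum (no egg development at all).
* Individuals are classified in the earlier stage until the threshold is
  crossed (the pharate-larva convention: apolysis without ecdysis does not
  advance the recorded stage).
* Optional mortality is an independent per-stage Bernoulli applied at stage
  entry; dead individuals stop developing and are recorded as dead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stages import DEAD, PREADULT_STAGES, STAGES

__all__ = [
    "SimulationConfig",
    "SamplingSchedule",
    "build_sampling_schedule",
    "generate_cohort",
    "rate_attenuation",
]

#: Published stage-level thermal constants (degree-days above the
#: developmental minimum) used as the generator's default ground truth.
DEFAULT_STAGE_ADD: dict[str, float] = {
    "E": 8.4,
    "L1": 12.1,
    "L2": 14.4,
    "L3f": 29.3,
    "L3m": 30.2,
    "P": 84.9,
}

DEFAULT_TEMPERATURES: tuple[float, ...] = tuple(
    round(7.5 + 2.5 * i, 1) for i in range(11)
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and experimental design of a simulated rearing study.

    Defaults reproduce the reference study design: eleven constant
    temperatures from 7.5 to 32.5 °C in 2.5 °C steps, 20 eggs per cup, five
    sampling times per life stage, four replicate cups per sampling time,
    normally distributed transition thresholds, development linear in
    temperature between 15.0 and 32.5 °C with curvilinear attenuation below,
    and a biological minimum (no development) at 11 °C.

    Parameters
    ----------
    temperatures : tuple of float
        Programmed chamber temperatures, °C, strictly increasing.
    true_dev_min : float
        Developmental minimum of the linear rate model, °C.
    true_stage_add : mapping stage -> float
        Thermal constant per pre-adult stage, degree-days; all positive.
    transition_cv : float
        Coefficient of variation of individual per-stage ADD thresholds
        (dimensionless, ``0 <= cv < 1``).
    biological_min : float
        Temperature at or below which no development occurs, °C.
    linear_range : (float, float)
        Temperature band over which the rate is exactly linear, °C.
    curvature_strength : float
        Dimensionless attenuation exponent applied outside ``linear_range``;
        0 disables curvature.
    eggs_per_cup, replicates, samples_per_stage : int
        Design sizes (defaults 20, 4, 5).
    mortality_per_stage : float
        Per-stage Bernoulli death probability at stage entry (default 0).
    seed : int
        Default random seed for :func:`generate_cohort`.
    assumed_dev_min, reference_temp : float
        A-priori values used only to build the sampling schedule (the
        planner's pilot knowledge, deliberately distinct from the truth).
    reference_durations : mapping stage -> hours, optional
        Pilot stage durations at ``reference_temp``.  When omitted they are
        derived from ``true_stage_add`` with ``assumed_dev_min`` and inflated
        by ``schedule_margin`` (pilot estimates err long).
    schedule_margin : float
        Multiplicative safety margin on the pilot durations (default 1.1).
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    true_dev_min: float = 10.2
    true_stage_add: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_ADD)
    )
    transition_cv: float = 0.05
    biological_min: float = 11.0
    linear_range: tuple[float, float] = (15.0, 32.5)
    curvature_strength: float = 1.0
    eggs_per_cup: int = 20
    replicates: int = 4
    samples_per_stage: int = 5
    mortality_per_stage: float = 0.0
    seed: int = 0
    assumed_dev_min: float = 10.0
    reference_temp: float = 25.0
    reference_durations: Mapping[str, float] | None = None
    schedule_margin: float = 1.1

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        if len(temps) == 0:
            raise ValueError("temperatures must be non-empty")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        missing = [s for s in PREADULT_STAGES if s not in self.true_stage_add]
        if missing:
            raise ValueError(f"true_stage_add missing stages: {missing}")
        if any(self.true_stage_add[s] <= 0 for s in PREADULT_STAGES):
            raise ValueError("all stage ADD values must be positive")
        if not 0.0 <= self.transition_cv < 1.0:
            raise ValueError("transition_cv must be in [0, 1)")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError("linear_range must satisfy low < high")
        if self.eggs_per_cup < 1:
            raise ValueError("eggs_per_cup must be at least 1")
        if self.replicates < 1 or self.samples_per_stage < 1:
            raise ValueError("replicates and samples_per_stage must be >= 1")
        if not 0.0 <= self.mortality_per_stage < 1.0:
            raise ValueError("mortality_per_stage must be in [0, 1)")
        if self.reference_temp <= self.assumed_dev_min:
            raise ValueError("reference_temp must exceed assumed_dev_min")

    @property
    def stage_add_array(self) -> np.ndarray:
        return np.array([self.true_stage_add[s] for s in PREADULT_STAGES])

    def pilot_durations(self) -> dict[str, float]:
        """Stage durations (hours at ``reference_temp``) used for scheduling."""
        if self.reference_durations is not None:
            return {s: float(self.reference_durations[s]) for s in PREADULT_STAGES}
        denom = self.reference_temp - self.assumed_dev_min
        return {
            s: self.schedule_margin * 24.0 * self.true_stage_add[s] / denom
            for s in PREADULT_STAGES
        }


@dataclass(frozen=True)
class SamplingSchedule:
    """Scheduled sampling times (hours since oviposition) per temperature.

    ``windows[T]`` maps each pre-adult stage to its ``samples_per_stage``
    strictly increasing, equally spaced times.  Consecutive stage windows
    partition the expected development timeline, so the transition out of a
    stage is expected near the end of that stage's window and its completion
    is captured by the following window.
    """

    windows: dict[float, dict[str, np.ndarray]]

    def times_for(self, temperature: float) -> dict[str, np.ndarray]:
        try:
            return self.windows[float(temperature)]
        except KeyError:
            raise KeyError(
                f"temperature {temperature} not in schedule "
                f"(have {sorted(self.windows)})"
            ) from None

    def all_times(self, temperature: float) -> np.ndarray:
        per_stage = self.times_for(temperature)
        return np.unique(np.concatenate([per_stage[s] for s in PREADULT_STAGES]))


def build_sampling_schedule(
    reference_durations: Mapping[str, float],
    reference_temp: float,
    assumed_dev_min: float,
    temperatures: Sequence[float],
    samples_per_stage: int = 5,
) -> SamplingSchedule:
    """Translate pilot stage durations into per-temperature sampling times.

    Each stage's pilot duration at ``reference_temp`` is converted to
    accumulated degree-hours, ``ADH = duration * (reference_temp -
    assumed_dev_min)``; at temperature ``T`` the stage window spans
    ``ADH / (T - assumed_dev_min)`` hours and is divided into
    ``samples_per_stage`` equal intervals, the last sample falling at the
    window's end.  Temperatures at or below ``assumed_dev_min`` reuse the
    schedule of the lowest temperature above the minimum (development there
    is not expected, but the design still samples).
    """
    if reference_temp <= assumed_dev_min:
        raise ValueError("reference_temp must exceed assumed_dev_min")
    if not reference_durations:
        raise ValueError("reference_durations must be non-empty")
    missing = [s for s in PREADULT_STAGES if s not in reference_durations]
    if missing:
        raise ValueError(f"reference_durations missing stages: {missing}")
    durations = np.array([float(reference_durations[s]) for s in PREADULT_STAGES])
    if np.any(durations <= 0):
        raise ValueError("all reference durations must be positive")
    temps = [float(t) for t in temperatures]
    above = [t for t in temps if t > assumed_dev_min]
    if not above:
        raise ValueError("no temperature lies above assumed_dev_min")
    fallback = min(above)

    adh = durations * (reference_temp - assumed_dev_min)
    cum_adh = np.concatenate([[0.0], np.cumsum(adh)])
    frac = np.arange(1, samples_per_stage + 1) / samples_per_stage

    windows: dict[float, dict[str, np.ndarray]] = {}
    for temp in temps:
        t_eff = temp if temp > assumed_dev_min else fallback
        denom = t_eff - assumed_dev_min
        per_stage: dict[str, np.ndarray] = {}
        for k, stage in enumerate(PREADULT_STAGES):
            start = cum_adh[k] / denom
            end = cum_adh[k + 1] / denom
            per_stage[stage] = start + frac * (end - start)
        windows[temp] = per_stage
    return SamplingSchedule(windows=windows)


def rate_attenuation(temperature: float, config: SimulationConfig) -> float:
    """Multiplicative rate factor modelling curvilinear departure at extremes.

    Returns 1 inside ``linear_range``.  Below the lower bound the factor
    decays as ``((T - biological_min)/(low - biological_min)) ** strength``,
    reaching 0 at the biological minimum; above the upper bound it decays as
    ``exp(-strength * (T - high) / 5)``.  With ``curvature_strength = 0``
    the response is linear everywhere above the biological minimum.
    """
    if temperature <= config.biological_min:
        return 0.0
    low, high = config.linear_range
    factor = 1.0
    if temperature < low:
        base = (temperature - config.biological_min) / (low - config.biological_min)
        factor *= base**config.curvature_strength
    elif temperature > high:
        factor *= math.exp(-config.curvature_strength * (temperature - high) / 5.0)
    return factor


def development_rate(temperature: float, config: SimulationConfig) -> float:
    """Physiological speed in degree-days per day at ``temperature``."""
    linear = max(0.0, temperature - config.true_dev_min)
    return linear * rate_attenuation(temperature, config)


def _draw_thresholds(
    rng: np.random.Generator, means: np.ndarray, cv: float, n: int
) -> np.ndarray:
    """Per-individual, per-stage ADD thresholds, normal truncated to > 0."""
    if cv == 0.0:
        return np.tile(means, (n, 1))
    draws = rng.normal(means, cv * means, size=(n, means.size))
    # Redraw the (rare, cv < 1) non-positive values so truncation does not
    # distort the upper tail.
    for _ in range(100):
        bad = draws <= 0
        if not bad.any():
            break
        draws[bad] = rng.normal(
            np.broadcast_to(means, draws.shape)[bad],
            cv * np.broadcast_to(means, draws.shape)[bad],
        )
    else:  # pragma: no cover - unreachable for cv < 1 in practice
        draws[draws <= 0] = 1e-9
    return draws


def generate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    schedule: SamplingSchedule | None = None,
) -> pd.DataFrame:
    """Simulate the full destructive-sampling study.

    Returns a wide observation table with one row per sampled cup:
    columns ``temperature_c``, ``time_h``, ``replicate``, one count column
    per stage (``E`` … ``A``), ``dead``, and ``n_total``.  Counts plus deaths
    sum to ``eggs_per_cup`` in every row.  Output is bit-identical for a
    fixed ``(config, seed)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if schedule is None:
        schedule = build_sampling_schedule(
            config.pilot_durations(),
            config.reference_temp,
            config.assumed_dev_min,
            config.temperatures,
            config.samples_per_stage,
        )
    for temp in config.temperatures:
        schedule.times_for(temp)  # raises if the schedule lacks a temperature

    means = config.stage_add_array
    n_stages = means.size
    rows: list[dict] = []
    for temp in config.temperatures:
        rate = development_rate(temp, config)
        per_stage_times = schedule.times_for(temp)
        for stage in PREADULT_STAGES:
            for time_h in per_stage_times[stage]:
                for rep in range(1, config.replicates + 1):
                    thresholds = _draw_thresholds(
                        rng, means, config.transition_cv, config.eggs_per_cup
                    )
                    cum = np.cumsum(thresholds, axis=1)
                    elapsed = rate * time_h / 24.0  # degree-days
                    stage_idx = (elapsed >= cum).sum(axis=1)
                    if config.mortality_per_stage > 0.0:
                        death_draws = (
                            rng.random((config.eggs_per_cup, n_stages))
                            < config.mortality_per_stage
                        )
                        death_stage = np.where(
                            death_draws.any(axis=1),
                            death_draws.argmax(axis=1),
                            n_stages + 1,
                        )
                        dead = stage_idx >= death_stage
                        # Dead individuals stopped developing at death.
                        stage_idx = np.minimum(stage_idx, death_stage)
                    else:
                        dead = np.zeros(config.eggs_per_cup, dtype=bool)
                    counts = np.bincount(
                        stage_idx[~dead], minlength=len(STAGES)
                    )[: len(STAGES)]
                    row = {
                        "temperature_c": temp,
                        "time_h": float(time_h),
                        "replicate": rep,
                        **{s: int(c) for s, c in zip(STAGES, counts)},
                        DEAD: int(dead.sum()),
                        "n_total": config.eggs_per_cup,
                    }
                    rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["temperature_c", "time_h", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
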