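"""50% stage-transition times and stage durations.

Two routes estimate the time at which half of a cohort has crossed a stage
boundary (``t50``):

* **Probit** — a binomial GLM with probit link of P(at or past the later
  stage) on time.  The probit link assumes individual transition times are
  normally distributed, so ``t50 = -intercept/slope`` is the fitted normal
  mean and ``1/slope`` its standard deviation; any other transition
  percentile follows from the fitted quantile function.
* **Cumulative Gaussian** — the centre ``b`` of a fitted cumulative (or
  reversed cumulative) Gaussian stage curve, since the curve crosses half
  its plateau exactly at ``x = b``.

Both estimate the median of the same normal transition-time distribution and
agree asymptotically.  Stage durations follow by subtraction of consecutive
boundary ``t50`` values; the egg stage's duration is the oviposition-to-hatch
``t50`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .curves import StageCurveResults
from .stages import BOUNDARIES, boundary_label

__all__ = [
    "TransitionEstimate",
    "StageDuration",
    "ProbitTransitionModel",
    "ProbitTransitionResults",
    "t50_from_cumulative",
    "stage_durations",
]


@dataclass(frozen=True)
class TransitionEstimate:
    """50% transition time (hours) for one stage boundary at one temperature."""

    temperature: float
    boundary: tuple[str, str]
    t50: float
    se_t50: float
    method: str  # "probit" | "cumulative_gaussian"
    n_times: int

    def __post_init__(self):
        if self.t50 <= 0:
            raise ValueError(
                f"t50 must be positive, got {self.t50} for "
                f"{boundary_label(self.boundary)} at {self.temperature} degC"
            )
        if not (self.se_t50 >= 0 or np.isnan(self.se_t50)):
            raise ValueError("se_t50 must be non-negative")


@dataclass(frozen=True)
class StageDuration:
    """Time spent in one stage at one temperature."""

    temperature: float
    stage: str
    hours: float

    def __post_init__(self):
        if self.hours <= 0:
            raise ValueError(
                f"non-positive duration {self.hours} h for stage {self.stage} "
                f"at {self.temperature} degC"
            )

    @property
    def days(self) -> float:
        return self.hours / 24.0


class ProbitTransitionResults:
    """Results of a probit transition fit.

    Wraps the underlying GLM results; ``t50`` and its delta-method standard
    error are the quantities of interest, ``quantile(p)`` gives the time of
    any desired percent transition.
    """

    def __init__(self, glm_results, model: "ProbitTransitionModel"):
        self._res = glm_results
        self.model = model
        icept, slope = glm_results.params
        if not np.isfinite(slope) or slope <= 0:
            raise ValueError(
                "probit slope is not positive; no usable information about "
                "the transition crossing"
            )
        self.intercept = float(icept)
        self.slope = float(slope)
        self.t50 = -self.intercept / self.slope
        # sd of the latent normal transition-time distribution
        self.transition_sd = 1.0 / self.slope
        cov = np.asarray(glm_results.cov_params())
        grad = np.array([-1.0 / self.slope, self.intercept / self.slope**2])
        var = float(grad @ cov @ grad)
        self.se_t50 = float(np.sqrt(max(var, 0.0)))

    def quantile(self, p: float) -> float:
        """Time (hours) by which a fraction ``p`` of the cohort has crossed."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        return (stats.norm.ppf(p) - self.intercept) / self.slope

    def as_estimate(
        self, temperature: float, boundary: tuple[str, str]
    ) -> TransitionEstimate:
        return TransitionEstimate(
            temperature=temperature,
            boundary=boundary,
            t50=self.t50,
            se_t50=self.se_t50,
            method="probit",
            n_times=len(self.model.time),
        )

    def summary(self) -> str:
        return (
            "Probit transition fit\n"
            f"  t50 = {self.t50:.4g} h  (se {self.se_t50:.3g})\n"
            f"  transition sd = {self.transition_sd:.4g} h\n"
            f"  n sampling times = {len(self.model.time)}"
        )


class ProbitTransitionModel:
    """Binomial probit regression of 'crossed the boundary' on time.

    Parameters
    ----------
    time : array-like
        Sampling times, hours.
    n_crossed : array-like
        Individuals found at or past the later stage at each time.
    n_total : array-like
        Live individuals examined at each time (deaths excluded upstream).
    """

    def __init__(self, time, n_crossed, n_total):
        self.time = np.asarray(time, dtype=float)
        self.n_crossed = np.asarray(n_crossed, dtype=float)
        self.n_total = np.asarray(n_total, dtype=float)
        if not (self.time.shape == self.n_crossed.shape == self.n_total.shape):
            raise ValueError("time, n_crossed, n_total must have equal shapes")
        if np.any(self.n_crossed < 0) or np.any(self.n_crossed > self.n_total):
            raise ValueError("need 0 <= n_crossed <= n_total at every time")
        frac = self.n_crossed / self.n_total
        partial = np.any((frac > 0) & (frac < 1))
        spans = np.any(frac == 0) and np.any(frac == 1)
        if not (partial or spans):
            raise ValueError(
                "no information about the transition crossing: all "
                "observations are on one side (never or always crossed)"
            )

    def fit(self) -> ProbitTransitionResults:
        exog = sm.add_constant(self.time)
        endog = np.column_stack([self.n_crossed, self.n_total - self.n_crossed])
        glm = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
        res = glm.fit(maxiter=200)
        return ProbitTransitionResults(res, self)


def t50_from_cumulative(
    fit: StageCurveResults,
    temperature: float,
    boundary: tuple[str, str],
) -> TransitionEstimate:
    """Read the 50% transition off a cumulative-Gaussian stage-curve fit.

    The (reversed) cumulative Gaussian equals half its plateau at ``x = b``,
    so ``t50 = b``; the standard error is the fitted parameter's.  Refuses
    fits of the wrong family or that did not converge.
    """
    if fit.kind not in ("cumulative_gaussian", "reversed_cumulative_gaussian"):
        raise ValueError(f"need a cumulative-family fit, got {fit.kind!r}")
    if not fit.converged:
        raise ValueError(
            f"refusing t50 from non-converged fit for "
            f"{boundary_label(boundary)} at {temperature} degC: {fit.message}"
        )
    return TransitionEstimate(
        temperature=temperature,
        boundary=boundary,
        t50=fit.b,
        se_t50=fit.bse()["b"],
        method="cumulative_gaussian",
        n_times=fit.n_obs,
    )


def stage_durations(
    transitions: Sequence[TransitionEstimate],
    strict: bool = True,
) -> list[StageDuration]:
    """Stage durations by subtraction of consecutive boundary t50 values.

    ``transitions`` are estimates at a single temperature, in developmental
    order.  The egg stage's duration is the first boundary's t50 (entry into
    the egg stage is oviposition at time zero); each later stage's duration
    is t50(exit) - t50(entry).  Missing boundaries leave the adjacent stages
    without a duration — never interpolated.

    A non-monotone t50 sequence signals an upstream fitting failure: with
    ``strict=True`` it raises naming the offending pair, otherwise the
    offending stage is skipped.
    """
    if len(transitions) < 1:
        raise ValueError("need at least one transition estimate")
    temps = {t.temperature for t in transitions}
    if len(temps) != 1:
        raise ValueError(f"transitions span several temperatures: {sorted(temps)}")
    by_boundary = {t.boundary: t for t in transitions}
    unknown = set(by_boundary) - set(BOUNDARIES)
    if unknown:
        raise ValueError(f"unknown boundaries: {sorted(unknown)}")

    temperature = transitions[0].temperature
    out: list[StageDuration] = []
    for i, boundary in enumerate(BOUNDARIES):
        stage = boundary[0]
        exit_est = by_boundary.get(boundary)
        if exit_est is None:
            continue
        if i == 0:
            entry_t50 = 0.0
        else:
            entry_est = by_boundary.get(BOUNDARIES[i - 1])
            if entry_est is None:
                continue
            entry_t50 = entry_est.t50
        duration = exit_est.t50 - entry_t50
        if duration <= 0:
            msg = (
                f"non-monotone t50 sequence at {temperature} degC: "
                f"{boundary_label(boundary)} (t50 {exit_est.t50:.3g} h) does not "
                f"follow the previous boundary (t50 {entry_t50:.3g} h); "
                "upstream fit is suspect"
            )
            if strict:
                raise ValueError(msg)
            continue
        out.append(StageDuration(temperature=temperature, stage=stage, hours=duration))
    return out
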