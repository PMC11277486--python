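"""Validated linear degree-day models from rate–temperature data.

A degree-day model summarises thermal development as a straight line: the
development rate (1/days to complete an event) is regressed on temperature;
the x-intercept of the line is the developmental minimum (the temperature at
which the fitted rate is zero — a model parameter, not the biological
minimum) and the reciprocal slope is the thermal constant, the accumulated
degree-days (ADD) the event requires.  The model is only meaningful over the
temperature band where the rate response really is linear, so the fit is
validated and pruned:

1. Ordinary least squares of rate on temperature.
2. A Wald–Wolfowitz runs test on the ordered residual signs flags systematic
   curvature; while it rejects, the endpoint temperature with the larger
   absolute standardized residual is excluded and the line refitted
   (curvature lives at the temperature extremes, so only endpoints are ever
   removed, keeping the valid range contiguous).
3. Degree-day accumulations ``ADD_i = days_i * (T_i - dev_min)`` are computed
   at each retained temperature and regressed on temperature.  A valid
   degree-day model must make this regression flat (zero-slope t-test) and
   patternless (runs test); otherwise another endpoint is excluded and steps
   1–3 repeat until every assumption holds or too few points remain.

The runs test is exact (closed-form Wald–Wolfowitz runs distribution,
equivalent to enumerating all orderings) up to 20 signed residuals and uses
the normal approximation with continuity correction beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import comb

__all__ = [
    "RunsTestResult",
    "runs_distribution",
    "runs_test",
    "DegreeDayResults",
    "DevelopmentRateModel",
    "rate_regression",
    "prune_until_linear",
    "fit_validated_degree_day_model",
    "summarize_add",
]


# ----------------------------------------------------------------------
# Runs test
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RunsTestResult:
    """Wald–Wolfowitz runs test on ordered residual signs."""

    n_pos: int
    n_neg: int
    runs: int
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"
    note: str = ""

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def runs_distribution(n_pos: int, n_neg: int) -> np.ndarray:
    """Exact pmf of the number of runs; index r holds P(R = r), r = 0..n.

    All ``C(n, n_pos)`` arrangements of the signs are equally likely under
    the null of exchangeable residual signs; the closed form counts the
    arrangements with a given number of runs.
    """
    n = n_pos + n_neg
    pmf = np.zeros(n + 1)
    if n_pos == 0 or n_neg == 0:
        pmf[1 if n >= 1 else 0] = 1.0
        return pmf
    total = comb(n, n_pos, exact=True)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n_pos - 1, k - 1, exact=True) * comb(
                n_neg - 1, k - 1, exact=True
            )
        else:
            k = (r - 1) // 2
            ways = comb(n_pos - 1, k - 1, exact=True) * comb(
                n_neg - 1, k, exact=True
            ) + comb(n_pos - 1, k, exact=True) * comb(n_neg - 1, k - 1, exact=True)
        pmf[r] = ways / total
    return pmf


def runs_test(residuals: Sequence[float], exact_max: int = 20) -> RunsTestResult:
    """Two-sided runs test on the signs of ``residuals`` (ordered upstream,
    here by temperature).  Zero residuals are dropped before counting.

    Too few runs indicate clustered signs — systematic curvature around the
    fitted line; too many indicate alternation.  The two-sided p-value is
    twice the smaller tail probability, capped at 1.  With all residuals of
    one sign the test runs but is uninformative about curvature direction.
    """
    resid = np.asarray(residuals, dtype=float)
    signs = np.sign(resid)
    signs = signs[signs != 0]
    if signs.size < 2:
        raise ValueError("need at least two nonzero residuals for a runs test")
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    runs = int(1 + (np.diff(signs) != 0).sum())
    n = n_pos + n_neg

    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(
            n_pos, n_neg, runs, 1.0, "degenerate",
            "all residuals share one sign; uninformative for curvature",
        )
    if n <= exact_max:
        pmf = runs_distribution(n_pos, n_neg)
        lower = float(pmf[: runs + 1].sum())
        upper = float(pmf[runs:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
        return RunsTestResult(n_pos, n_neg, runs, p, "exact")
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    sd = np.sqrt(var)
    z = (runs - mu + 0.5) / sd if runs < mu else (runs - mu - 0.5) / sd
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return RunsTestResult(n_pos, n_neg, runs, p, "normal")


# ----------------------------------------------------------------------
# Degree-day regression
# ----------------------------------------------------------------------
@dataclass
class DegreeDayResults:
    """A fitted (optionally pruned and validated) linear degree-day model.

    ``add * slope == 1`` and ``dev_min == -intercept/slope`` hold exactly by
    construction.  ``exclusions`` is the ordered audit trail of removed
    temperatures; ``validation`` is populated once the ADD-accumulation
    check has run.
    """

    event: str
    slope: float  # 1/(days * degC)
    intercept: float  # 1/days
    r2: float
    temperatures: np.ndarray
    rates: np.ndarray
    residuals: np.ndarray
    runs: RunsTestResult | None
    exclusions: list[dict] = field(default_factory=list)
    validation: dict | None = None

    @property
    def dev_min(self) -> float:
        """Developmental minimum, °C (x-intercept of the rate line)."""
        return -self.intercept / self.slope

    @property
    def add(self) -> float:
        """Thermal constant, degree-days (reciprocal slope)."""
        return 1.0 / self.slope

    @property
    def n(self) -> int:
        return int(self.temperatures.size)

    @property
    def temperature_range(self) -> tuple[float, float]:
        return float(self.temperatures.min()), float(self.temperatures.max())

    def predict(self, temperature) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(temperature, dtype=float)

    def summary(self) -> str:
        lo, hi = self.temperature_range
        lines = [
            f"Degree-day model: {self.event}",
            f"  slope {self.slope:.6g} /(day*degC), intercept {self.intercept:.6g} /day",
            f"  dev min {self.dev_min:.2f} degC   ADD {self.add:.1f} degree-days",
            f"  r^2 {self.r2:.2f}   n {self.n}   valid range {lo:.1f}-{hi:.1f} degC",
        ]
        if self.runs is not None:
            lines.append(
                f"  runs test: R={self.runs.runs} (n+={self.runs.n_pos}, "
                f"n-={self.runs.n_neg}), p={self.runs.p_value:.3f} [{self.runs.method}]"
            )
        for exc in self.exclusions:
            lines.append(
                f"  excluded {exc['temperature']:.1f} degC at step {exc['step']}: "
                f"{exc['reason']}"
            )
        if self.validation is not None:
            v = self.validation
            lines.append(
                f"  ADD accumulation: slope p={v['slope_p']:.3f}, runs p="
                f"{v['runs'].p_value:.3f}, mean {v['add_mean']:.1f} "
                f"(sd {v['add_sd']:.1f}), deviation vs regression "
                f"{v['pct_deviation']:+.1f}%"
            )
        return "\n".join(lines)


class DevelopmentRateModel:
    """Linear model of development rate (1/days) on temperature (°C).

    The statsmodels-style entry point for degree-day analysis: construct from
    rate–temperature points, then :meth:`fit` (plain OLS) or
    :meth:`fit_pruned` (OLS with runs-test endpoint pruning).
    """

    def __init__(self, temperature, rate, event: str = "event"):
        temperature = np.asarray(temperature, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if temperature.ndim != 1 or temperature.shape != rate.shape:
            raise ValueError("temperature and rate must be 1-D of equal length")
        if temperature.size < 3:
            raise ValueError(
                f"{event}: need at least 3 rate points for a degree-day "
                f"regression, got {temperature.size}"
            )
        if np.any(rate <= 0):
            raise ValueError(f"{event}: all rates must be positive (1/days)")
        if np.unique(temperature).size != temperature.size:
            raise ValueError(f"{event}: duplicate temperatures in rate points")
        order = np.argsort(temperature)
        self.temperature = temperature[order]
        self.rate = rate[order]
        self.event = event

    # ------------------------------------------------------------------
    def fit(self) -> DegreeDayResults:
        """Ordinary least squares; fails when there is no positive thermal
        response (non-positive slope)."""
        return self._fit_subset(self.temperature, self.rate, [])

    def _fit_subset(
        self, temps: np.ndarray, rates: np.ndarray, exclusions: list[dict]
    ) -> DegreeDayResults:
        res = stats.linregress(temps, rates)
        if res.slope <= 0:
            raise ValueError(
                f"{self.event}: non-positive slope ({res.slope:.3g}); "
                "no thermal response to model"
            )
        fitted = res.intercept + res.slope * temps
        residuals = rates - fitted
        runs = None
        if np.count_nonzero(residuals) >= 2:
            runs = runs_test(residuals)
        return DegreeDayResults(
            event=self.event,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r2=float(res.rvalue**2),
            temperatures=temps.copy(),
            rates=rates.copy(),
            residuals=residuals,
            runs=runs,
            exclusions=list(exclusions),
        )

    # ------------------------------------------------------------------
    def fit_pruned(
        self, alpha: float = 0.05, min_points: int = 3
    ) -> DegreeDayResults:
        """Iteratively refit, excluding one endpoint temperature per round
        while the runs test rejects linearity at level ``alpha``.

        The endpoint whose point has the larger absolute standardized
        residual goes first; ties break toward the low end (biological
        minima distort rates more sharply).  Fails if linearity cannot be
        reached with at least ``min_points`` points.
        """
        if self.temperature.size < 4:
            raise ValueError(
                f"{self.event}: pruning needs at least 4 initial points"
            )
        temps, rates = self.temperature, self.rate
        exclusions: list[dict] = []
        step = 0
        while True:
            result = self._fit_subset(temps, rates, exclusions)
            if result.runs is None or result.runs.p_value >= alpha:
                return result
            if temps.size - 1 < min_points:
                raise ValueError(
                    f"{self.event}: cannot reach linearity with >= "
                    f"{min_points} points; exclusion trace: {exclusions}"
                )
            step += 1
            drop = _endpoint_to_drop(temps, result.residuals)
            exclusions.append(
                {
                    "temperature": float(temps[drop]),
                    "step": step,
                    "reason": (
                        f"runs test p={result.runs.p_value:.4f} < {alpha} "
                        f"(R={result.runs.runs})"
                    ),
                }
            )
            keep = np.ones(temps.size, dtype=bool)
            keep[drop] = False
            temps, rates = temps[keep], rates[keep]


def _endpoint_to_drop(temps: np.ndarray, residuals: np.ndarray) -> int:
    """Index of the endpoint with the larger |standardized residual|;
    ties break toward the low-temperature end."""
    scale = float(np.std(residuals, ddof=min(2, residuals.size - 1)))
    if scale == 0:
        return 0
    low, high = abs(residuals[0]) / scale, abs(residuals[-1]) / scale
    return 0 if low >= high else int(temps.size - 1)


# ----------------------------------------------------------------------
# Functional surface
# ----------------------------------------------------------------------
def rate_regression(temperature, rate, event: str = "event") -> DegreeDayResults:
    """Plain OLS degree-day regression (no pruning, no validation)."""
    return DevelopmentRateModel(temperature, rate, event).fit()


def prune_until_linear(
    temperature, rate, alpha: float = 0.05, event: str = "event",
    min_points: int = 3,
) -> DegreeDayResults:
    """Runs-test pruning of endpoint temperatures until linearity holds."""
    return DevelopmentRateModel(temperature, rate, event).fit_pruned(
        alpha=alpha, min_points=min_points
    )


def summarize_add(
    per_temperature_add: Sequence[float], regression_add: float | None = None
) -> dict:
    """Mean and spread of the per-temperature calculated ADD values.

    The spread is the population standard deviation (divisor n), matching
    how the reference tables report it.  When ``regression_add`` is given,
    the percent deviation of the calculated mean from the regression ADD is
    included.
    """
    values = np.asarray(per_temperature_add, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one ADD value")
    out = {
        "add_mean": float(values.mean()),
        "add_sd": float(values.std(ddof=0)),
        "n": int(values.size),
    }
    if regression_add is not None:
        out["pct_deviation"] = float(
            100.0 * (values.mean() - regression_add) / regression_add
        )
    return out


def fit_validated_degree_day_model(
    temperature,
    days,
    alpha: float = 0.05,
    event: str = "event",
    min_points: int = 3,
    max_rounds: int = 20,
) -> DegreeDayResults:
    """Full validated degree-day fit from event times/durations in days.

    Runs the complete loop: rates ``1/days`` are regressed on temperature
    with runs-test endpoint pruning; degree-day accumulations
    ``days_i * (T_i - dev_min)`` at the retained temperatures are then
    regressed on temperature and must be flat (slope t-test p >= alpha) and
    patternless (runs test p >= alpha).  While either check fails, the
    endpoint with the larger absolute standardized accumulation residual is
    excluded and the whole procedure repeats on the reduced set.  The
    returned model carries the final valid temperature range, the exclusion
    trail, and the per-temperature calculated ADD summary.
    """
    temperature = np.asarray(temperature, dtype=float)
    days = np.asarray(days, dtype=float)
    if temperature.shape != days.shape or temperature.ndim != 1:
        raise ValueError("temperature and days must be 1-D of equal length")
    if np.any(days <= 0):
        raise ValueError(f"{event}: all event times must be positive days")
    order = np.argsort(temperature)
    temps, days = temperature[order], days[order]
    carried: list[dict] = []

    for _ in range(max_rounds):
        model = DevelopmentRateModel(temps, 1.0 / days, event)
        if temps.size >= 4:
            result = model.fit_pruned(alpha=alpha, min_points=min_points)
        else:
            result = model.fit()
        result.exclusions = carried + result.exclusions
        mask = np.isin(temps, result.temperatures)
        kept_days = days[mask]

        add_i = kept_days * (result.temperatures - result.dev_min)
        if np.allclose(add_i, add_i.mean(), rtol=1e-9, atol=1e-12):
            # numerically flat accumulation: assumptions hold exactly
            acc_slope, slope_p = 0.0, 1.0
            acc_resid = np.zeros_like(add_i)
            acc_runs = RunsTestResult(0, 0, 1, 1.0, "degenerate", "exact fit")
        else:
            acc = stats.linregress(result.temperatures, add_i)
            acc_resid = add_i - (acc.intercept + acc.slope * result.temperatures)
            acc_slope = float(acc.slope)
            slope_p = float(acc.pvalue)
            if not np.isfinite(slope_p):
                slope_p = 1.0
            if np.count_nonzero(acc_resid) >= 2:
                acc_runs = runs_test(acc_resid)
            else:
                acc_runs = RunsTestResult(0, 0, 1, 1.0, "degenerate", "exact fit")
        accepted = slope_p >= alpha and acc_runs.p_value >= alpha
        result.validation = {
            "add_values": dict(zip(result.temperatures, add_i)),
            "acc_slope": acc_slope,
            "slope_p": slope_p,
            "runs": acc_runs,
            "accepted": accepted,
            **summarize_add(add_i, regression_add=result.add),
        }
        if accepted:
            return result

        if result.temperatures.size - 1 < min_points:
            raise ValueError(
                f"{event}: degree-day assumptions cannot be met with >= "
                f"{min_points} points; exclusion trace: {result.exclusions}"
            )
        drop = _endpoint_to_drop(result.temperatures, acc_resid)
        reason = (
            f"ADD accumulation slope p={slope_p:.4f}"
            if slope_p < alpha
            else f"ADD accumulation runs p={acc_runs.p_value:.4f}"
        )
        carried = result.exclusions + [
            {
                "temperature": float(result.temperatures[drop]),
                "step": len(result.exclusions) + 1,
                "reason": f"{reason} < {alpha}",
            }
        ]
        keep_t = np.delete(result.temperatures, drop)
        final_mask = np.isin(temps, keep_t)
        temps, days = temps[final_mask], days[final_mask]

    raise ValueError(
        f"{event}: validation loop did not converge in {max_rounds} rounds; "
        f"trace: {carried}"
    )
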