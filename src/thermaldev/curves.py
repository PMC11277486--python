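"""Gaussian-family stage-frequency curves and their least-squares fits.

The proportion of a cohort found in (or at/past) a stage, plotted against
time at one temperature, follows one of four shapes:

* ``gaussian`` — a transient stage entered and left within the observation
  window: ``y = a * exp(-0.5 * ((x - b) / c)**2)``.
* ``modified_gaussian`` — a long-lasting stage whose occupancy plateaus while
  the whole cohort sits in it: ``y = a * exp(-0.5 * |(x - b) / c|**d)``;
  ``d > 2`` flattens the peak into a plateau, ``d = 2`` recovers the plain
  Gaussian.
* ``cumulative_gaussian`` — a sigmoidal rise to a plateau (proportion that
  has *entered* a stage): ``y = (a / 2) * (1 + erf((x - b) / (sqrt(2) * c)))``.
* ``reversed_cumulative_gaussian`` — a sigmoidal fall from a plateau
  (proportion still in the egg stage): ``y = (a / 2) * (1 - erf(...))``.

``a`` is the amplitude or plateau (same unit as y, proportion or percent),
``b`` the centre in hours (for the cumulative forms, the 50% transition
time), ``c`` the spread in hours, and ``d`` the dimensionless shape exponent
of the modified form.  Fitting is ordinary nonlinear least squares
(scipy ``curve_fit``) with moment-based initialisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import erf

__all__ = [
    "CURVE_KINDS",
    "gaussian",
    "modified_gaussian",
    "cumulative_gaussian",
    "reversed_cumulative_gaussian",
    "evaluate_curve",
    "StageCurveModel",
    "StageCurveResults",
    "select_larval_model",
]

_SQRT2 = np.sqrt(2.0)
_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


def gaussian(x, a, b, c):
    x = np.asarray(x, dtype=float)
    return a * np.exp(-0.5 * ((x - b) / c) ** 2)


def modified_gaussian(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    return a * np.exp(-0.5 * np.abs((x - b) / c) ** d)


def cumulative_gaussian(x, a, b, c):
    x = np.asarray(x, dtype=float)
    return 0.5 * a * (1.0 + erf((x - b) / (_SQRT2 * c)))


def reversed_cumulative_gaussian(x, a, b, c):
    x = np.asarray(x, dtype=float)
    return 0.5 * a * (1.0 - erf((x - b) / (_SQRT2 * c)))


_CURVES = {
    "gaussian": (gaussian, ("a", "b", "c")),
    "modified_gaussian": (modified_gaussian, ("a", "b", "c", "d")),
    "cumulative_gaussian": (cumulative_gaussian, ("a", "b", "c")),
    "reversed_cumulative_gaussian": (reversed_cumulative_gaussian, ("a", "b", "c")),
}

CURVE_KINDS = tuple(_CURVES)


def evaluate_curve(kind: str, x, *params) -> np.ndarray:
    """Evaluate the named curve at ``x`` (total function, no domain errors)."""
    func, names = _CURVES[kind]
    if len(params) != len(names):
        raise TypeError(f"{kind} takes parameters {names}, got {len(params)}")
    return func(x, *params)


@dataclass
class StageCurveResults:
    """Fitted parameters and diagnostics of one stage-frequency curve."""

    kind: str
    params: dict[str, float]
    cov: np.ndarray | None
    rss: float
    n_obs: int
    converged: bool
    message: str = ""
    x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def a(self) -> float:
        return self.params["a"]

    @property
    def b(self) -> float:
        return self.params["b"]

    @property
    def c(self) -> float:
        return self.params["c"]

    @property
    def d(self) -> float | None:
        return self.params.get("d")

    def bse(self) -> dict[str, float]:
        """Standard errors of the parameters (NaN when unavailable)."""
        names = _CURVES[self.kind][1]
        if self.cov is None or not np.all(np.isfinite(self.cov)):
            return {k: float("nan") for k in names}
        return dict(zip(names, np.sqrt(np.diag(self.cov))))

    def predict(self, x) -> np.ndarray:
        names = _CURVES[self.kind][1]
        return evaluate_curve(self.kind, x, *(self.params[k] for k in names))

    def summary(self) -> str:
        se = self.bse()
        lines = [
            f"Stage-frequency curve fit: {self.kind}",
            f"  n obs: {self.n_obs}   rss: {self.rss:.6g}   converged: {self.converged}",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k} = {v:.6g}  (se {se[k]:.3g})")
        return "\n".join(lines)


class StageCurveModel:
    """Nonlinear least-squares model for one stage-frequency series.

    Parameters
    ----------
    x : array-like
        Sampling times, hours since oviposition; non-negative.
    y : array-like
        Proportion (0–1) or percentage (0–100) in/at/past the stage; the
        scale only affects the amplitude ``a``.
    kind : str
        One of :data:`CURVE_KINDS`.
    """

    def __init__(self, x, y, kind: str = "gaussian"):
        if kind not in _CURVES:
            raise ValueError(f"unknown curve kind {kind!r}; choose from {CURVE_KINDS}")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be one-dimensional and equal length")
        order = np.argsort(x, kind="mergesort")
        self.x = x[order]
        self.y = y[order]
        self.kind = kind
        n_par = len(_CURVES[kind][1])
        if self.x.size < n_par + 1:
            raise ValueError(
                f"{kind} needs at least {n_par + 1} points, got {self.x.size}"
            )
        if np.ptp(self.y) == 0.0:
            raise ValueError(
                f"degenerate series for {kind}: y is constant "
                f"({self.y[0]!r} at all {self.y.size} times)"
            )

    # ------------------------------------------------------------------
    def start_params(self) -> dict[str, float]:
        """Moment-based initial values: amplitude from the max, centre from
        the peak (peaked forms) or the interpolated half-range crossing
        (cumulative forms), spread from the half-maximum width."""
        x, y = self.x, self.y
        a0 = float(np.max(y))
        span = float(np.ptp(x)) or 1.0
        if self.kind in ("gaussian", "modified_gaussian"):
            b0 = float(x[int(np.argmax(y))])
            c0 = self._half_width(b0, a0) * _HWHM_TO_SIGMA
        else:
            rising = self.kind == "cumulative_gaussian"
            b0 = self._crossing(0.5 * (y.min() + y.max()), rising)
            lo = self._crossing(y.min() + 0.25 * np.ptp(y), rising)
            hi = self._crossing(y.min() + 0.75 * np.ptp(y), rising)
            c0 = abs(hi - lo) / 1.349 if hi != lo else span / 4.0
        c0 = float(np.clip(c0, 1e-6 * span, span))
        start = {"a": a0, "b": b0, "c": c0}
        if self.kind == "modified_gaussian":
            start["d"] = 2.0
        return start

    def _half_width(self, b0: float, a0: float) -> float:
        above = self.x[self.y >= 0.5 * a0]
        if above.size >= 2:
            return max(0.5 * float(above.max() - above.min()), 1e-6)
        return float(np.ptp(self.x)) / 4.0 or 1.0

    def _crossing(self, level: float, rising: bool) -> float:
        """Linearly interpolated time at which y crosses ``level``."""
        y = self.y if rising else -self.y
        lvl = level if rising else -level
        idx = np.nonzero(y >= lvl)[0]
        if idx.size == 0:
            return float(self.x[-1])
        i = int(idx[0])
        if i == 0:
            return float(self.x[0])
        x0, x1 = self.x[i - 1], self.x[i]
        y0, y1 = y[i - 1], y[i]
        if y1 == y0:
            return float(0.5 * (x0 + x1))
        return float(x0 + (lvl - y0) * (x1 - x0) / (y1 - y0))

    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Parameter box keeping amplitudes near the data scale, spreads
        within the observation window, and the shape exponent in (0.5, 10]."""
        span = float(np.ptp(self.x)) or 1.0
        ymax = float(np.max(np.abs(self.y))) or 1.0
        lower = [1e-12, self.x[0] - span, 1e-9 * span]
        upper = [1.05 * ymax, self.x[-1] + span, span]
        if self.kind == "modified_gaussian":
            lower.append(0.5)
            upper.append(10.0)
        return np.array(lower), np.array(upper)

    # ------------------------------------------------------------------
    def fit(
        self,
        start_params: dict[str, float] | None = None,
        bounds: tuple | None = None,
        max_nfev: int = 10_000,
    ) -> StageCurveResults:
        """Fit by nonlinear least squares; non-convergence is flagged on the
        results object, never silently dropped."""
        func, names = _CURVES[self.kind]
        start = dict(self.start_params())
        if start_params:
            start.update(start_params)
        lower, upper = bounds if bounds is not None else self.default_bounds()
        p0 = np.clip([start[k] for k in names], lower, upper)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    func,
                    self.x,
                    self.y,
                    p0=p0,
                    bounds=(lower, upper),
                    max_nfev=max_nfev,
                )
            converged, message = True, ""
        except RuntimeError as err:  # max_nfev exceeded etc.
            popt, pcov = p0, None
            converged, message = False, str(err)

        resid = self.y - func(self.x, *popt)
        rss = float(resid @ resid)
        init_resid = self.y - func(self.x, *p0)
        init_rss = float(init_resid @ init_resid)
        if converged and rss > init_rss + 1e-12:
            # A bounded solver should never do worse than its start point.
            popt, rss = p0, init_rss
            pcov = None
            message = "solver returned worse fit than initialisation; kept start"
        return StageCurveResults(
            kind=self.kind,
            params=dict(zip(names, (float(p) for p in popt))),
            cov=pcov,
            rss=rss,
            n_obs=self.x.size,
            converged=converged,
            message=message,
            x=self.x,
            y=self.y,
        )


def select_larval_model(
    y, plateau_points: int = 3, tolerance: float = 0.05
) -> str:
    """Choose between the plain and modified Gaussian for a within-stage
    series: long-lasting stages plateau while the whole cohort occupies them.

    Returns ``'modified_gaussian'`` when at least ``plateau_points``
    consecutive observations lie within ``tolerance`` (fractional) of the
    series maximum, else ``'gaussian'``.  Series shorter than
    ``plateau_points`` default to ``'gaussian'`` with a warning.
    """
    y = np.asarray(y, dtype=float)
    if y.size < plateau_points:
        warnings.warn(
            f"series has {y.size} < {plateau_points} points; "
            "defaulting to plain gaussian",
            stacklevel=2,
        )
        return "gaussian"
    top = float(np.max(y))
    if top <= 0:
        return "gaussian"
    near_max = y >= (1.0 - tolerance) * top
    run = longest = 0
    for flag in near_max:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return "modified_gaussian" if longest >= plateau_points else "gaussian"
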