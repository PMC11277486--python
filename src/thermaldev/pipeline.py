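"""End-to-end orchestration: observations in, validated degree-day models out.

The analysis chain mirrors how a constant-temperature development study is
processed:

1. Read/validate the stage-count observation table (CSV or XLSX).
2. Per temperature and stage boundary, pool replicates into a cumulative
   "entered the later stage" proportion series, truncate it at its plateau
   (only the 0–100% rise informs the transition), and fit a cumulative
   Gaussian; its centre is the 50% transition time.  A probit route is
   available as a cross-check.
3. Stage durations by subtraction of consecutive transition times.
4. Per event (cumulative transitions E-L1 … E-A and within-stage durations),
   fit the runs-test-validated linear degree-day model.
5. Report percent-time-in-stage and degree-day summary tables with the full
   exclusion audit trail.

Everything in the report is recomputable from the observation table plus the
configuration; re-running with the same inputs reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .curves import StageCurveModel, StageCurveResults
from .degreeday import DegreeDayResults, fit_validated_degree_day_model
from .stages import (
    BOUNDARIES,
    DEAD,
    PREADULT_STAGES,
    STAGE_EVENTS,
    STAGES,
    TRANSITION_EVENTS,
    boundary_label,
)
from .transitions import (
    ProbitTransitionModel,
    StageDuration,
    TransitionEstimate,
    stage_durations,
    t50_from_cumulative,
)

__all__ = [
    "AnalysisConfig",
    "DevelopmentStudy",
    "StudyReport",
    "read_observations",
    "write_observations",
    "observations_to_long",
    "long_to_wide",
    "boundary_series",
    "truncate_at_plateau",
    "percent_time_in_stage",
    "flag_outliers",
]

_WIDE_COLUMNS = ["temperature_c", "time_h", "replicate", *STAGES, DEAD, "n_total"]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def observations_to_long(obs: pd.DataFrame) -> pd.DataFrame:
    """Wide observation table -> tidy long (one row per stage count)."""
    long = obs.melt(
        id_vars=["temperature_c", "time_h", "replicate"],
        value_vars=[*STAGES, DEAD],
        var_name="stage",
        value_name="count",
    )
    return long.sort_values(
        ["temperature_c", "time_h", "replicate", "stage"], kind="mergesort"
    ).reset_index(drop=True)


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Tidy long table -> wide, filling absent stage rows with zero counts."""
    wide = (
        long.pivot_table(
            index=["temperature_c", "time_h", "replicate"],
            columns="stage",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=[*STAGES, DEAD], fill_value=0)
        .reset_index()
    )
    wide.columns.name = None
    wide["n_total"] = wide[[*STAGES, DEAD]].sum(axis=1)
    return wide[_WIDE_COLUMNS]


def _validate_long(long: pd.DataFrame, source: str) -> None:
    required = {"temperature_c", "time_h", "replicate", "stage", "count"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    bad_stage = ~long["stage"].isin([*STAGES, DEAD])
    if bad_stage.any():
        rows = (long.index[bad_stage] + 2).tolist()[:10]  # 1-based + header
        labels = sorted(long.loc[bad_stage, "stage"].unique())
        raise ValueError(
            f"{source}: unknown stage label(s) {labels} at line(s) {rows}; "
            f"accepted labels: {', '.join([*STAGES, DEAD])}"
        )
    negative = long["count"] < 0
    if negative.any():
        rows = (long.index[negative] + 2).tolist()[:10]
        raise ValueError(f"{source}: negative counts at line(s) {rows}")
    dup = long.duplicated(["temperature_c", "time_h", "replicate", "stage"])
    if dup.any():
        rows = (long.index[dup] + 2).tolist()[:10]
        raise ValueError(
            f"{source}: duplicate (temperature, time, replicate, stage) rows "
            f"at line(s) {rows}; destructive sampling observes each cup once"
        )


def read_observations(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an observation table from CSV or XLSX into the wide layout.

    Accepts either the tidy long schema (``temperature_c, time_h, replicate,
    stage, count``) or the wide schema (one count column per stage).
    ``column_map`` renames source columns to the documented schema first,
    so spreadsheets with their own headers can be adapted.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    if "stage" in raw.columns:
        _validate_long(raw, str(path))
        return long_to_wide(raw)
    # wide layout
    missing = {"temperature_c", "time_h", "replicate"} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(raw.columns) - set(_WIDE_COLUMNS)
    if unknown:
        raise ValueError(
            f"{path}: unknown columns {sorted(unknown)}; accepted stage "
            f"labels: {', '.join([*STAGES, DEAD])}"
        )
    for col in (*STAGES, DEAD):
        if col not in raw.columns:
            raw[col] = 0
    if (raw[[*STAGES, DEAD]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    if raw.duplicated(["temperature_c", "time_h", "replicate"]).any():
        raise ValueError(
            f"{path}: duplicate (temperature, time, replicate) rows; "
            "destructive sampling observes each cup once"
        )
    if "n_total" not in raw.columns:
        raw["n_total"] = raw[[*STAGES, DEAD]].sum(axis=1)
    return raw[_WIDE_COLUMNS].sort_values(
        ["temperature_c", "time_h", "replicate"], kind="mergesort"
    ).reset_index(drop=True)


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy long CSV form of a wide observation table."""
    observations_to_long(obs).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Series extraction
# ----------------------------------------------------------------------
def boundary_series(
    obs: pd.DataFrame, boundary_index: int, pooled: bool = True
) -> pd.DataFrame:
    """Cumulative 'entered the later stage' series for one boundary.

    For boundary k (between ``STAGES[k]`` and ``STAGES[k+1]``) the entered
    count at a sampling time is the number of live individuals found at or
    past the later stage; transitions are monotone, so this proportion is the
    empirical cumulative transition curve.  Deaths are excluded from the
    denominator.  With ``pooled=True`` replicate cups at the same time are
    summed before forming the proportion; otherwise per-cup proportions are
    averaged.

    Returns a frame with columns ``time_h, n_entered, n_live, proportion``
    sorted by time (single temperature expected in ``obs``).
    """
    later = list(STAGES[boundary_index + 1 :])
    work = obs.copy()
    work["n_entered"] = work[later].sum(axis=1)
    work["n_live"] = work[list(STAGES)].sum(axis=1)
    work = work[work["n_live"] > 0]
    if pooled:
        grouped = work.groupby("time_h", as_index=False)[["n_entered", "n_live"]].sum()
        grouped["proportion"] = grouped["n_entered"] / grouped["n_live"]
    else:
        work["proportion"] = work["n_entered"] / work["n_live"]
        grouped = work.groupby("time_h", as_index=False).agg(
            n_entered=("n_entered", "sum"),
            n_live=("n_live", "sum"),
            proportion=("proportion", "mean"),
        )
    return grouped.sort_values("time_h").reset_index(drop=True)


def truncate_at_plateau(series: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Keep only the first portion of a cumulative series, through the first
    time its proportion reaches the plateau (1.0 within ``tol``); later
    samples repeat the plateau and carry no information about the rise."""
    at_top = series["proportion"] >= 1.0 - tol
    if at_top.any():
        first = int(np.flatnonzero(at_top.to_numpy())[0])
        return series.iloc[: first + 1].reset_index(drop=True)
    return series


# ----------------------------------------------------------------------
# Outlier audit
# ----------------------------------------------------------------------
def flag_outliers(
    obs: pd.DataFrame,
    fits: Mapping[tuple[float, int], StageCurveResults],
    m: float = 4.0,
) -> pd.DataFrame:
    """Flag cups with extraordinarily extended stage residence.

    A cup is flagged for boundary k when it was sampled more than ``m``
    fitted spreads past the 50% transition time (``time > b + m*c``) yet
    still held live individuals in the earlier stage.  Flagged rows are only
    reported; exclusion is an explicit opt-in upstream.
    """
    records = []
    for (temp, k), fit in fits.items():
        stage_from = STAGES[k]
        cutoff = fit.b + m * fit.c
        sub = obs[(obs["temperature_c"] == temp) & (obs["time_h"] > cutoff)]
        late = sub[sub[stage_from] > 0]
        for _, row in late.iterrows():
            records.append(
                {
                    "temperature_c": temp,
                    "boundary": boundary_label(BOUNDARIES[k]),
                    "time_h": row["time_h"],
                    "replicate": row["replicate"],
                    "count_in_earlier_stage": int(row[stage_from]),
                    "cutoff_h": cutoff,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "temperature_c", "boundary", "time_h", "replicate",
            "count_in_earlier_stage", "cutoff_h",
        ],
    )


# ----------------------------------------------------------------------
# Reporting tables
# ----------------------------------------------------------------------
def percent_time_in_stage(durations: list[StageDuration]) -> pd.DataFrame:
    """Percent of total immature development spent in each stage.

    One row per temperature (columns ``Egg, L1, …, P``), a ``Mean`` row
    averaging the complete rows.  Percentages are taken over the stages
    observed in the row, so complete rows sum to 100 over the six pre-adult
    stages; rows missing a stage keep their known cells (percent of the
    observed total) but are excluded from the column means.
    """
    frame = pd.DataFrame(
        [(d.temperature, d.stage, d.hours) for d in durations],
        columns=["temperature_c", "stage", "hours"],
    )
    if frame.empty:
        return pd.DataFrame(columns=list(STAGE_EVENTS))
    wide = frame.pivot(index="temperature_c", columns="stage", values="hours")
    wide = wide.reindex(columns=list(PREADULT_STAGES))
    complete = wide.notna().all(axis=1)
    totals = wide.sum(axis=1, skipna=True)
    pct = 100.0 * wide.div(totals, axis=0)
    pct.columns = list(STAGE_EVENTS)  # 'E' reported as 'Egg'
    mean_row = pct[complete].mean(axis=0)
    out = pd.concat([pct, mean_row.to_frame().T])
    out.index = [*pct.index.tolist(), "Mean"]
    out.index.name = "temperature_c"
    return out


# ----------------------------------------------------------------------
# Study orchestration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the end-to-end analysis.

    ``route`` selects how 50% transition times are estimated
    (``"cumulative_gaussian"`` — the default consumed by the degree-day
    chain — or ``"probit"`` for cross-validation).  ``alpha`` governs both
    the runs test and the zero-slope test.  ``min_rise`` is the minimum
    observed transition fraction required to attempt a boundary fit.
    ``temperature_map`` translates programmed setpoints to measured chamber
    means before any regression.
    """

    alpha: float = 0.05
    route: str = "cumulative_gaussian"
    pooled: bool = True
    min_rise: float = 0.5
    min_points: int = 3
    outlier_m: float = 4.0
    exclude_outliers: bool = False
    plateau_tol: float = 1e-9
    temperature_map: Mapping[float, float] | None = None

    def __post_init__(self):
        if self.route not in ("cumulative_gaussian", "probit"):
            raise ValueError("route must be 'cumulative_gaussian' or 'probit'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class StudyReport:
    """Everything the analysis produced, traceable to the raw observations."""

    transitions: pd.DataFrame
    durations: pd.DataFrame
    percent_time: pd.DataFrame
    degree_day_table: pd.DataFrame
    models: dict[str, DegreeDayResults]
    curve_fits: dict[tuple[float, int], StageCurveResults]
    outliers: pd.DataFrame
    skipped: list[dict]
    metadata: dict

    def to_json(self) -> str:
        """Deterministic JSON body (no timestamps) for reproducibility checks."""
        payload = {
            "metadata": self.metadata,
            "transitions": self.transitions.to_dict("records"),
            "durations": self.durations.to_dict("records"),
            "percent_time": {
                str(k): {c: _round(v) for c, v in row.items()}
                for k, row in self.percent_time.iterrows()
            },
            "degree_day": self.degree_day_table.to_dict("records"),
            "skipped": self.skipped,
            "exclusions": {
                event: model.exclusions for event, model in self.models.items()
            },
        }
        return json.dumps(payload, sort_keys=True, default=_round, indent=1)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.transitions.to_csv(outdir / "transitions.csv", index=False)
        self.durations.to_csv(outdir / "durations.csv", index=False)
        self.percent_time.to_csv(outdir / "percent_time_in_stage.csv")
        self.degree_day_table.to_csv(outdir / "degree_day_models.csv", index=False)
        if len(self.outliers):
            self.outliers.to_csv(outdir / "flagged_outliers.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _round(x):
    if isinstance(x, (np.floating, float)):
        return round(float(x), 10)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


class DevelopmentStudy:
    """Full analysis of one observation table.

    Parameters
    ----------
    observations : DataFrame
        Wide observation table (see :func:`read_observations`).
    config : AnalysisConfig, optional
    """

    def __init__(self, observations: pd.DataFrame, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        obs = observations.copy()
        if self.config.temperature_map:
            obs["temperature_c"] = obs["temperature_c"].replace(
                dict(self.config.temperature_map)
            )
        self.observations = obs

    # ------------------------------------------------------------------
    def estimate_transitions(
        self,
    ) -> tuple[list[TransitionEstimate], dict, list[dict]]:
        """Per (temperature, boundary) 50% transition estimates."""
        cfg = self.config
        estimates: list[TransitionEstimate] = []
        fits: dict[tuple[float, int], StageCurveResults] = {}
        skipped: list[dict] = []
        for temp in sorted(self.observations["temperature_c"].unique()):
            at_temp = self.observations[self.observations["temperature_c"] == temp]
            for k, boundary in enumerate(BOUNDARIES):
                label = boundary_label(boundary)
                series = boundary_series(at_temp, k, pooled=cfg.pooled)
                series = truncate_at_plateau(series, tol=cfg.plateau_tol)
                top = series["proportion"].max() if len(series) else 0.0
                if len(series) < 4 or top < cfg.min_rise:
                    skipped.append(
                        {
                            "temperature_c": float(temp),
                            "boundary": label,
                            "reason": (
                                f"insufficient transition signal (max observed "
                                f"fraction {top:.2f}, {len(series)} times)"
                            ),
                        }
                    )
                    continue
                try:
                    fit = StageCurveModel(
                        series["time_h"], series["proportion"], "cumulative_gaussian"
                    ).fit()
                    fits[(float(temp), k)] = fit
                    if cfg.route == "probit":
                        est = ProbitTransitionModel(
                            series["time_h"], series["n_entered"], series["n_live"]
                        ).fit().as_estimate(float(temp), boundary)
                    else:
                        est = t50_from_cumulative(fit, float(temp), boundary)
                except ValueError as err:
                    skipped.append(
                        {
                            "temperature_c": float(temp),
                            "boundary": label,
                            "reason": str(err),
                        }
                    )
                    continue
                estimates.append(est)
        return estimates, fits, skipped

    # ------------------------------------------------------------------
    def run(self) -> StudyReport:
        cfg = self.config
        estimates, fits, skipped = self.estimate_transitions()

        durations: list[StageDuration] = []
        for temp in sorted({e.temperature for e in estimates}):
            at_temp = [e for e in estimates if e.temperature == temp]
            durations.extend(stage_durations(at_temp, strict=False))

        outliers = flag_outliers(self.observations, fits, m=cfg.outlier_m)

        # Event times in days: cumulative transitions and stage durations.
        event_days: dict[str, dict[float, float]] = {e: {} for e in
                                                     (*TRANSITION_EVENTS, *STAGE_EVENTS)}
        for est in estimates:
            event = f"E-{est.boundary[1]}"
            event_days[event][est.temperature] = est.t50 / 24.0
        for dur in durations:
            event = "Egg" if dur.stage == "E" else dur.stage
            event_days[event][dur.temperature] = dur.days

        models: dict[str, DegreeDayResults] = {}
        for event, by_temp in event_days.items():
            if len(by_temp) < max(3, cfg.min_points):
                skipped.append(
                    {
                        "temperature_c": None,
                        "boundary": event,
                        "reason": f"only {len(by_temp)} temperatures with an "
                                  "event time; degree-day model needs >= 3",
                    }
                )
                continue
            temps = np.array(sorted(by_temp))
            days = np.array([by_temp[t] for t in temps])
            try:
                models[event] = fit_validated_degree_day_model(
                    temps, days, alpha=cfg.alpha, event=event,
                    min_points=cfg.min_points,
                )
            except ValueError as err:
                skipped.append(
                    {"temperature_c": None, "boundary": event, "reason": str(err)}
                )

        report = StudyReport(
            transitions=pd.DataFrame(
                [
                    {
                        "temperature_c": e.temperature,
                        "boundary": boundary_label(e.boundary),
                        "t50_h": e.t50,
                        "se_h": e.se_t50,
                        "method": e.method,
                        "n_times": e.n_times,
                    }
                    for e in estimates
                ]
            ),
            durations=pd.DataFrame(
                [
                    {
                        "temperature_c": d.temperature,
                        "stage": d.stage,
                        "hours": d.hours,
                        "days": d.days,
                    }
                    for d in durations
                ]
            ),
            percent_time=percent_time_in_stage(durations),
            degree_day_table=degree_day_table(models),
            models=models,
            curve_fits=fits,
            outliers=outliers,
            skipped=skipped,
            metadata=self._metadata(),
        )
        return report

    def _metadata(self) -> dict:
        cfg = asdict(self.config)
        cfg["temperature_map"] = (
            dict(self.config.temperature_map) if self.config.temperature_map else None
        )
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {
            "package_version": __version__,
            "config": cfg,
            "config_hash": digest,
            "n_observation_rows": int(len(self.observations)),
        }


def degree_day_table(models: Mapping[str, DegreeDayResults]) -> pd.DataFrame:
    """Summary table of validated degree-day models, one row per event."""
    rows = []
    for event in (*TRANSITION_EVENTS, *STAGE_EVENTS):
        model = models.get(event)
        if model is None:
            continue
        v = model.validation or {}
        lo, hi = model.temperature_range
        rows.append(
            {
                "event": event,
                "kind": "transition" if event in TRANSITION_EVENTS else "stage",
                "dev_min_c": model.dev_min,
                "add": model.add,
                "r2": model.r2,
                "n": model.n,
                "range_min_c": lo,
                "range_max_c": hi,
                "calculated_add_mean": v.get("add_mean"),
                "calculated_add_sd": v.get("add_sd"),
                "pct_deviation": v.get("pct_deviation"),
                "n_excluded": len(model.exclusions),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "kind", "dev_min_c", "add", "r2", "n", "range_min_c",
            "range_max_c", "calculated_add_mean", "calculated_add_sd",
            "pct_deviation", "n_excluded",
        ],
    )
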