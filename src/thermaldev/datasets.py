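"""Published reference values for *Phormia regina* development.

Small, printed summary tables from the published constant-temperature
development study of the black blow fly *Phormia regina* (11 temperatures,
7.5–32.5 °C; no egg eclosion at 7.5 °C and no development past the first
instar at 10.0 °C, so summaries start at the third temperature).  They are
used as desk-scale cross-checks of the package's own arithmetic (per-event
ADD means and spreads, percent-time-in-stage column means) and as realistic
inputs for the degree-day regression machinery.

Temperatures are the measured chamber means, not the programmed setpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stages import STAGE_EVENTS, TRANSITION_EVENTS

__all__ = [
    "load_percent_time_rows",
    "load_add_per_temperature",
    "load_add_regression_summary",
    "PUBLISHED_PERCENT_TIME_MEAN",
]

_NA = np.nan

# Percent of total immature development spent in each stage, by measured
# temperature (°C).  The 10.4 °C treatment produced no usable series.
_PERCENT_TIME = {
    12.7: (4.8, 19.6, 14.5, 3.3, 15.9, 41.8),
    15.1: (6.4, 9.6, 7.9, 22.3, 2.3, 51.5),
    17.5: (6.4, 14.0, 14.6, 9.6, 6.6, 48.8),
    20.1: (5.4, 11.3, 10.8, 17.8, 9.5, 45.3),
    22.5: (4.4, 9.6, 11.7, 11.9, 12.4, 49.9),
    25.0: (5.3, 9.9, 9.9, 18.3, 11.1, 45.4),
    27.5: (5.8, 8.4, 9.5, 16.2, 11.2, 49.0),
    30.0: (4.7, 7.8, 8.9, 13.3, 14.3, 51.0),
    32.5: (4.9, 7.3, 8.2, 17.6, 13.5, 48.5),
}

#: The published column means of the percent-time table.
PUBLISHED_PERCENT_TIME_MEAN = {
    "Egg": 5.3, "L1": 10.8, "L2": 10.7, "L3f": 14.5, "L3m": 10.8, "P": 47.9,
}

# Per-temperature calculated ADD (degree-days), by event.  Transition events
# accumulate from oviposition; stage events are within-stage requirements.
# Missing cells are temperatures excluded as non-linear (or unobserved).
_ADD_TEMPS = (10.2, 12.5, 15.0, 17.5, 20.0, 22.4, 25.0, 27.5, 30.0, 32.5)
_ADD_PER_TEMP = {
    "E-L1": (_NA, _NA, 8.9, 10.0, 8.6, 7.0, 8.5, 9.2, 7.9, 8.8),
    "E-L2": (_NA, _NA, 13.7, 24.6, 22.2, 19.7, 21.9, 20.6, 19.5, 20.5),
    "E-L3f": (_NA, _NA, 21.3, 42.8, 37.0, 36.6, 36.2, 34.6, 33.4, 34.5),
    "E-L3m": (_NA, _NA, 58.8, 65.6, 69.0, 58.8, 67.5, 62.1, 57.1, 67.3),
    "E-P": (_NA, _NA, _NA, 94.0, 97.8, 88.7, 93.9, 86.7, 86.8, _NA),
    "E-A": (_NA, _NA, _NA, 191.2, 184.1, 181.5, 175.3, 172.8, 179.9, _NA),
    "Egg": (_NA, _NA, 8.9, 10.0, 8.6, 7.0, 8.5, 9.2, 7.9, 8.8),
    "L1": (_NA, _NA, 6.0, 14.7, 13.8, 12.7, 13.5, 11.7, 11.7, 11.9),
    "L2": (_NA, _NA, 7.9, 18.9, 15.0, 17.2, 14.5, 14.2, 14.0, 14.1),
    "L3f": (_NA, _NA, _NA, 23.3, 39.3, 25.1, 36.4, 31.2, 26.3, _NA),
    "L3m": (_NA, _NA, _NA, 26.2, 31.4, 37.1, 29.9, 28.1, 35.9, _NA),
    "P": (_NA, _NA, _NA, 89.2, 80.5, 88.2, 77.8, 83.0, 90.2, 91.5),
}

# Published regression summary per event.
_REGRESSION_ROWS = {
    "dev_min": (11.5, 12.9, 12.8, 11.9, 10.5, 10.2, 11.5, 13.5, 12.5, 8.2, 2.3, 10.5),
    "add": (8.4, 20.4, 34.7, 62.9, 91.4, 181.9, 8.4, 12.1, 14.4, 29.3, 30.2, 84.9),
    "r2": (0.96, 0.99, 0.99, 0.97, 0.98, 0.99, 0.96, 0.98, 0.97, 0.74, 0.72, 0.98),
    "n": (8, 8, 8, 8, 6, 6, 8, 8, 8, 6, 6, 7),
    "range_min": (15.0,) * 6 + (15.0, 15.0, 15.0, 17.5, 17.5, 15.0),
    "range_max": (32.5,) * 6 + (32.5, 32.5, 32.5, 30.0, 27.5, 32.5),
    "calculated_add_mean": (8.6, 20.3, 34.6, 63.3, 91.3, 180.8,
                            8.6, 12.0, 14.5, 30.2, 31.4, 85.8),
    "calculated_add_sd": (0.8, 2.9, 5.7, 4.4, 4.2, 6.0,
                          0.8, 2.5, 3.0, 5.9, 4.0, 4.9),
}

_EVENTS = tuple(TRANSITION_EVENTS) + tuple(STAGE_EVENTS)


def load_percent_time_rows() -> pd.DataFrame:
    """Percent time in stage per measured temperature (rows sum to ~100)."""
    frame = pd.DataFrame.from_dict(
        _PERCENT_TIME, orient="index",
        columns=["Egg", "L1", "L2", "L3f", "L3m", "P"],
    )
    frame.index.name = "temperature_c"
    return frame


def load_add_per_temperature() -> pd.DataFrame:
    """Calculated ADD (degree-days) per measured temperature and event."""
    frame = pd.DataFrame(
        {event: _ADD_PER_TEMP[event] for event in _EVENTS}, index=_ADD_TEMPS
    )
    frame.index.name = "temperature_c"
    return frame


def load_add_regression_summary() -> pd.DataFrame:
    """Published degree-day regression summary, one column per event."""
    frame = pd.DataFrame(
        {e: [r[i] for r in _REGRESSION_ROWS.values()] for i, e in enumerate(_EVENTS)},
        index=list(_REGRESSION_ROWS),
    )
    return frame
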