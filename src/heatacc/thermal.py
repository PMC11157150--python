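"""Blackglobe heat index, daily maxima, and hottest/coolest-day selection.

Blackglobe temperature integrates air temperature, solar radiation and
relative humidity into a single heat-stress measure emulating a black
globe thermometer.  The estimator here is a pluggable empirical linear
regression; the default coefficients are this package's synthetic-default
choice (there is no single canonical regression), constrained so that the
index is monotone in air temperature and solar radiation and never falls
below air temperature while the sun is up.  An identity fallback
(blackglobe = air temperature) keeps the pipeline runnable without any
coefficient configuration and is labelled in logs.

Extreme-day selection ranks calendar days by daily maximum air temperature
within a month window (default October–December, the hottest months at the
study site) and takes the top and bottom n (default 10), ties broken by
earlier date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Synthetic-default regression coefficients (°C from °C, W/m², %).
DEFAULT_BLACKGLOBE_COEFFS: dict[str, float] = {
    "intercept": 2.0,
    "air_temp": 1.08,
    "solar": 0.0203,
    "rh": -0.02,
}

DEFAULT_N_EXTREME_DAYS = 10
DEFAULT_WINDOW_MONTHS = frozenset({10, 11, 12})


def blackglobe(air_temp, solar, rh, coeffs: dict[str, float] | None = None):
    """Blackglobe temperature (°C) from a linear empirical regression.

    ``coeffs`` must provide intercept/air_temp/solar/rh; ``None`` selects
    the identity fallback (blackglobe = air temperature), which is logged.
    Vectorized: accepts scalars or aligned arrays.
    """
    air_temp = np.asarray(air_temp, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise ValueError("relative humidity must be within [0, 100]")
    if coeffs is None:
        logger.info("blackglobe: no coefficients configured, using identity fallback")
        return air_temp + 0.0
    missing = {"intercept", "air_temp", "solar", "rh"} - set(coeffs)
    if missing:
        raise KeyError(f"blackglobe coefficients missing keys: {sorted(missing)}")
    out = (
        coeffs["intercept"]
        + coeffs["air_temp"] * air_temp
        + coeffs["solar"] * np.asarray(solar, dtype=float)
        + coeffs["rh"] * rh_arr
    )
    return out


def add_blackglobe(
    weather: pd.DataFrame, coeffs: dict[str, float] | None = DEFAULT_BLACKGLOBE_COEFFS
) -> pd.DataFrame:
    """Return the weather frame with a ``blackglobe`` column appended."""
    out = weather.copy()
    out["blackglobe"] = blackglobe(
        out["air_temp"].to_numpy(), out["solar"].to_numpy(), out["rh"].to_numpy(), coeffs
    )
    return out


def daily_max(series: pd.DataFrame, field: str = "air_temp") -> pd.Series:
    """Per-calendar-date maximum of ``field`` (index: date).

    A precomputed ``date`` column (e.g. local dates from the budget
    module) takes precedence; otherwise dates derive from the UTC
    timestamps.
    """
    if not len(series):
        raise ValueError("daily_max needs a non-empty series")
    if "date" in series.columns:
        return series.groupby("date")[field].max()
    ts = pd.to_datetime(series["timestamp"], utc=True)
    return series.groupby(ts.dt.date)[field].max()


@dataclass(frozen=True)
class ExtremeDays:
    """The n hottest and n coolest dates by daily maximum air temperature."""

    hottest: tuple
    coolest: tuple
    criterion: str = "daily max air temperature"

    def __post_init__(self):
        if set(self.hottest) & set(self.coolest):
            raise ValueError("hottest and coolest day sets must be disjoint")

    def day_class(self, dates) -> pd.Series:
        """Map dates to 'hot'/'cool'/NaN."""
        hot, cool = set(self.hottest), set(self.coolest)
        return pd.Series(
            ["hot" if d in hot else "cool" if d in cool else np.nan for d in dates],
            index=getattr(dates, "index", None),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": list(self.hottest) + list(self.coolest),
                "day_class": ["hot"] * len(self.hottest) + ["cool"] * len(self.coolest),
            }
        )


def select_extreme_days(
    daily_max_map: pd.Series,
    n: int = DEFAULT_N_EXTREME_DAYS,
    window_months=DEFAULT_WINDOW_MONTHS,
) -> ExtremeDays:
    """Top-n and bottom-n dates by daily maximum within the month window.

    Ties broken by earlier date.  Raises if fewer than 2n dates fall in
    the window (the two sets must not overlap).
    """
    window_months = set(window_months)
    in_window = daily_max_map[
        [pd.Timestamp(d).month in window_months for d in daily_max_map.index]
    ]
    if len(in_window) < 2 * n:
        raise ValueError(
            f"need >= {2 * n} dates within months {sorted(window_months)}, "
            f"have {len(in_window)}"
        )
    frame = in_window.reset_index()
    frame.columns = ["date", "value"]
    hottest = frame.sort_values(["value", "date"], ascending=[False, True]).head(n)
    coolest = frame.sort_values(["value", "date"], ascending=[True, True]).head(n)
    return ExtremeDays(
        hottest=tuple(hottest["date"]), coolest=tuple(coolest["date"])
    )
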