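"""Time-budget and mean-ODBA aggregation over grouping cells.

Each 5-minute burst is one time tick, so the proportion of ticks in a cell
allocated to a behaviour estimates the proportion of time spent on it.
Cells are keyed by integer blackglobe °C bin (floor convention), local
hour, calendar month and individual for the afternoon heat analysis, and
by hot/cool day class, hour and individual for the diel comparison.
Mean-ODBA cells are retained only when backed by at least 30 recordings
(100 s of measurement); sparser cells carry too little signal.

The afternoon window is 12:00–17:59 local time; hours are derived from UTC
timestamps with a configurable UTC offset (the study site is UTC+2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ethogram import ANALYSIS_CATEGORIES
from .thermal import ExtremeDays

logger = logging.getLogger(__name__)

DEFAULT_JOIN_TOLERANCE = pd.Timedelta(minutes=30)
DEFAULT_MIN_RECORDINGS = 30
AFTERNOON_HOURS = range(12, 18)
DEFAULT_UTC_OFFSET_HOURS = 2

HEAT_KEYS = ["blackglobe_bin", "hour", "month", "individual_id"]
DIEL_KEYS = ["day_class", "hour", "individual_id"]


def add_local_time(
    records: pd.DataFrame, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS
) -> pd.DataFrame:
    """Attach local ``hour``, ``month`` and ``date`` columns from UTC timestamps."""
    out = records.copy()
    local = pd.to_datetime(out["timestamp"], utc=True) + pd.Timedelta(
        hours=utc_offset_hours
    )
    out["hour"] = local.dt.hour
    out["month"] = local.dt.month
    out["date"] = local.dt.date
    return out


def join_weather(
    records: pd.DataFrame,
    thermal_series: pd.DataFrame,
    tolerance: pd.Timedelta = DEFAULT_JOIN_TOLERANCE,
) -> pd.DataFrame:
    """Attach the nearest-in-time blackglobe value to each behaviour record.

    Records farther than ``tolerance`` from any weather record are dropped
    (count logged).  The thermal series needs ``timestamp`` and
    ``blackglobe`` columns.
    """
    if not len(thermal_series):
        raise ValueError("thermal series is empty")
    if not len(records):
        return records.assign(blackglobe=pd.Series(dtype=float))
    left = records.sort_values("timestamp").reset_index(drop=True)
    right = thermal_series[["timestamp", "blackglobe"]].sort_values("timestamp")
    joined = pd.merge_asof(
        left,
        right,
        on="timestamp",
        direction="nearest",
        tolerance=tolerance,
    )
    dropped = int(joined["blackglobe"].isna().sum())
    if dropped:
        logger.info("join_weather: dropped %d records beyond tolerance", dropped)
    return joined.dropna(subset=["blackglobe"]).reset_index(drop=True)


def afternoon_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records with local hour in 12..17 (the hottest part of the day)."""
    if not len(records):
        return records
    return records[records["hour"].isin(AFTERNOON_HOURS)].reset_index(drop=True)


def _bin_blackglobe(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["blackglobe_bin"] = np.floor(out["blackglobe"]).astype(int)
    return out


def time_budget(
    records: pd.DataFrame,
    keys: list[str] = HEAT_KEYS,
    categories=ANALYSIS_CATEGORIES,
) -> pd.DataFrame:
    """Per-cell behaviour proportions (one row per key combination).

    Output columns: keys, one proportion column per category (summing to 1
    within each cell), and ``n_records``.  Record order does not matter.
    """
    recs = records
    if "blackglobe_bin" in keys and "blackglobe_bin" not in recs.columns:
        recs = _bin_blackglobe(recs)
    counts = (
        recs.groupby(keys, observed=True)["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(categories), fill_value=0)
    )
    n = counts.sum(axis=1)
    props = counts.div(n, axis=0)
    props["n_records"] = n
    return props.reset_index()


def mean_odba_cells(
    records: pd.DataFrame,
    keys: list[str] = HEAT_KEYS,
    min_n: int = DEFAULT_MIN_RECORDINGS,
) -> pd.DataFrame:
    """Mean ODBA per (cell, category), keeping cells with >= min_n recordings.

    Discarded-cell count is logged; columns: keys, category, mean_odba,
    n_recordings.
    """
    recs = records
    if "blackglobe_bin" in keys and "blackglobe_bin" not in recs.columns:
        recs = _bin_blackglobe(recs)
    grouped = (
        recs.groupby([*keys, "category"], observed=True)["odba"]
        .agg(mean_odba="mean", n_recordings="size")
        .reset_index()
    )
    keep = grouped["n_recordings"] >= min_n
    if (~keep).any():
        logger.info(
            "mean_odba_cells: discarded %d cells with < %d recordings",
            int((~keep).sum()),
            min_n,
        )
    return grouped[keep].reset_index(drop=True)


def diel_budget(
    records: pd.DataFrame,
    extreme_days: ExtremeDays,
    categories=ANALYSIS_CATEGORIES,
) -> pd.DataFrame:
    """Hot/cool-day behaviour proportions over the full 24-hour cycle.

    Records outside the extreme-day sets are dropped; the rest are labelled
    'hot'/'cool' and aggregated per (day_class, hour, individual).
    """
    recs = records.copy()
    recs["day_class"] = extreme_days.day_class(recs["date"]).to_numpy()
    recs = recs.dropna(subset=["day_class"])
    return time_budget(recs, keys=DIEL_KEYS, categories=categories)
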