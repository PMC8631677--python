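"""Passive-acoustic-monitoring presence and feeding statistics.

Presence is summarized as detection positive hours (DPH): a clock hour
counts once if any beluga signal (echolocation, call, or whistle) was
detected in it, regardless of how many.  Feeding occurrence is summarized
as foraging positive minutes (FPM): a clock minute counts once if at least
one feeding-classified click train started in it.  Daily DPH is smoothed
with a centered 7-day running average for seasonal trend description.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .feedclassify import FEEDING, TrainVerdict

SIGNAL_TYPES = ("echolocation", "call", "whistle")


def _daily_index(
    stamps: pd.Series,
    start: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
) -> pd.DatetimeIndex:
    if len(stamps) == 0 and (start is None or end is None):
        raise ValueError("empty input and no monitored span given")
    lo = pd.Timestamp(start) if start is not None else stamps.min().normalize()
    hi = pd.Timestamp(end) if end is not None else stamps.max().normalize()
    return pd.date_range(lo.normalize(), hi.normalize(), freq="D")


def detection_positive_hours(
    events: pd.DataFrame,
    start: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
) -> pd.Series:
    """Distinct positive clock hours per monitored day.

    ``events`` needs a parsed ``timestamp`` column; monitored days without
    events count 0.  The span defaults to the events' date range.
    """
    stamps = pd.to_datetime(events["timestamp"])
    days = _daily_index(stamps, start, end)
    hours = stamps.dt.floor("h").drop_duplicates()
    dph = hours.dt.normalize().value_counts()
    out = pd.Series(0, index=days, dtype=int, name="dph")
    common = dph.index.intersection(days)
    out.loc[common] = dph.loc[common].astype(int)
    return out


def detection_positive_minutes(
    events: pd.DataFrame,
    start: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
) -> pd.Series:
    """Distinct positive clock minutes per monitored day (any signal type)."""
    stamps = pd.to_datetime(events["timestamp"])
    days = _daily_index(stamps, start, end)
    minutes = stamps.dt.floor("min").drop_duplicates()
    dpm = minutes.dt.normalize().value_counts()
    out = pd.Series(0, index=days, dtype=int, name="dpm")
    common = dpm.index.intersection(days)
    out.loc[common] = dpm.loc[common].astype(int)
    return out


def running_average(daily: pd.Series, window: int = 7) -> pd.Series:
    """Centered moving average; edges use the available shorter window."""
    if len(daily) == 0:
        raise ValueError("empty daily series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    return daily.rolling(window, center=True, min_periods=1).mean()


def foraging_positive_minutes(
    verdicts: Iterable[TrainVerdict] | pd.DataFrame,
    start: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
) -> pd.Series:
    """Distinct clock minutes per day holding at least one feeding train.

    A train belongs to the minute of its first click; duplicated feeding
    trains within a minute count once.
    """
    if isinstance(verdicts, pd.DataFrame):
        frame = verdicts
    else:
        frame = pd.DataFrame(
            {
                "timestamp": [v.first_click_time for v in verdicts],
                "verdict": [v.verdict for v in verdicts],
            }
        )
    feeding = frame[frame["verdict"] == FEEDING]
    stamps = pd.to_datetime(feeding["timestamp"])
    if stamps.isna().any():
        raise ValueError("feeding verdicts must carry timestamps")
    all_stamps = pd.to_datetime(frame["timestamp"].dropna())
    days = _daily_index(all_stamps if len(all_stamps) else stamps, start, end)
    minutes = stamps.dt.floor("min").drop_duplicates()
    fpm = minutes.dt.normalize().value_counts()
    out = pd.Series(0, index=days, dtype=int, name="fpm")
    common = fpm.index.intersection(days)
    out.loc[common] = fpm.loc[common].astype(int)
    return out


@dataclass
class PresenceSeries:
    """Daily presence/feeding table for one mooring.

    ``daily`` is indexed by date with columns ``dph`` (0-24), ``dph_smooth``
    (centered running average), ``dpm`` (detection positive minutes,
    0-1440) and ``fpm`` (foraging positive minutes, ``fpm <= dpm``).
    """

    daily: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.daily
        if ((d["dph"] < 0) | (d["dph"] > 24)).any():
            raise ValueError("DPH out of 0..24")
        if ((d["fpm"] < 0) | (d["fpm"] > 1440)).any():
            raise ValueError("FPM out of 0..1440")
        if (d["fpm"] > d["dpm"]).any():
            raise ValueError("FPM exceeds detection-positive minutes")


def build_presence(
    events: pd.DataFrame,
    verdicts: Iterable[TrainVerdict] | pd.DataFrame,
    window: int = 7,
    start: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
) -> PresenceSeries:
    """Assemble the daily DPH/FPM table from events and train verdicts."""
    stamps = pd.to_datetime(events["timestamp"])
    days = _daily_index(stamps, start, end)
    lo, hi = days[0], days[-1]
    dph = detection_positive_hours(events, lo, hi)
    dpm = detection_positive_minutes(events, lo, hi)
    fpm = foraging_positive_minutes(verdicts, lo, hi)
    daily = pd.DataFrame(
        {
            "dph": dph,
            "dph_smooth": running_average(dph, window),
            "dpm": dpm,
            "fpm": fpm,
        }
    )
    return PresenceSeries(daily=daily)


def monthly_summary(presence: PresenceSeries) -> pd.DataFrame:
    """Per-month feeding summary over the days that had any FPM.

    For each calendar month: the number of days with at least one FPM, the
    sum of FPM over those days, and the sum of non-FPM over those days,
    where a day's non-FPM is its detection-positive minutes without a
    feeding verdict (``dpm - fpm``).
    """
    d = presence.daily
    active = d[d["fpm"] >= 1]
    months = d.index.to_period("M").unique()
    rows = []
    for month in months:
        sub = active[active.index.to_period("M") == month]
        rows.append(
            {
                "month": str(month),
                "days_with_fpm": int(len(sub)),
                "fpm_sum": int(sub["fpm"].sum()),
                "non_fpm_sum": int((sub["dpm"] - sub["fpm"]).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["month", "days_with_fpm", "fpm_sum", "non_fpm_sum"])
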