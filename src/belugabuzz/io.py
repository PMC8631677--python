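"""Readers and writers for the pipeline's delimited-text formats.

All tables are UTF-8 comma-separated with a required header row:

``clicks``
    ``train_id, source_id, context, click_time_s[, timestamp]`` — one row
    per click; ``timestamp`` (ISO 8601) is the absolute time of the
    train's first click and needs to be present only on that row.
``events``
    ``timestamp, signal_type, instrument``.
``weir``
    ``date, species, count``.
``travel_times``
    ``lag_days`` — one integer lag per row.
``config``
    flat ``key = value`` lines; ``#`` starts a comment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .buzzfeatures import BuzzFeatureVector, ClickTrain, features_frame
from .errors import RowError, SchemaError

logger = logging.getLogger(__name__)

CLICK_COLUMNS = ("train_id", "source_id", "context", "click_time_s")
EVENT_COLUMNS = ("timestamp", "signal_type", "instrument")
WEIR_COLUMNS = ("date", "species", "count")


def _require(frame: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_click_table(path) -> list:
    """Read click trains grouped by ``train_id``, clicks sorted by time.

    Duplicate ``(train_id, click_time_s)`` rows are collapsed with a
    warning.  An empty file yields an empty dataset with a warning.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        logger.warning("%s: empty click table", path)
        return []
    _require(frame, CLICK_COLUMNS, path)
    before = len(frame)
    frame = frame.drop_duplicates(subset=["train_id", "click_time_s"])
    if len(frame) < before:
        logger.warning(
            "%s: collapsed %d duplicate (train_id, click_time_s) rows",
            path,
            before - len(frame),
        )
    trains = []
    for train_id, group in frame.groupby("train_id", sort=False):
        group = group.sort_values("click_time_s")
        start_time = None
        if "timestamp" in group.columns:
            stamps = pd.to_datetime(group["timestamp"].dropna(), errors="coerce")
            if len(stamps) and stamps.notna().any():
                start_time = stamps.dropna().iloc[0]
        trains.append(
            ClickTrain(
                train_id=str(train_id),
                source_id=str(group["source_id"].iloc[0]),
                context=str(group["context"].iloc[0]),
                click_times=group["click_time_s"].to_numpy(float),
                start_time=start_time,
            )
        )
    return trains


def write_click_table(trains: Sequence[ClickTrain], path) -> None:
    rows = []
    for t in trains:
        for i, s in enumerate(t.click_times):
            rows.append(
                {
                    "train_id": t.train_id,
                    "source_id": t.source_id,
                    "context": t.context,
                    "click_time_s": s,
                    "timestamp": (
                        t.start_time.isoformat()
                        if i == 0 and t.start_time is not None
                        else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_features(features, path) -> None:
    """Write one row per train with the five variables and onset index."""
    if not isinstance(features, pd.DataFrame):
        features = features_frame(list(features))
    features.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read the detection-event table, raising on unparseable timestamps."""
    frame = pd.read_csv(path)
    _require(frame, EVENT_COLUMNS, path)
    stamps = pd.to_datetime(frame["timestamp"], errors="coerce", format="mixed")
    bad = np.nonzero(stamps.isna().to_numpy())[0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise RowError(f"{path}: unparseable timestamp at line(s) {lines}")
    frame = frame.copy()
    frame["timestamp"] = stamps
    return frame


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(
        lambda t: t.isoformat()
    )
    out.to_csv(path, index=False)


def read_weir(path) -> dict:
    """Read daily weir counts; returns ``{species: Series}`` keyed by date."""
    frame = pd.read_csv(path)
    _require(frame, WEIR_COLUMNS, path)
    stamps = pd.to_datetime(frame["date"], errors="coerce")
    bad = np.nonzero(stamps.isna().to_numpy())[0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise RowError(f"{path}: unparseable date at line(s) {lines}")
    frame = frame.copy()
    frame["date"] = stamps
    if (frame["count"] < 0).any():
        raise RowError(f"{path}: negative count")
    out = {}
    for species, group in frame.groupby("species", sort=False):
        if group["date"].duplicated().any():
            raise RowError(f"{path}: duplicate dates for species {species!r}")
        out[str(species)] = (
            group.set_index("date")["count"].sort_index().rename(str(species))
        )
    return out


def write_weir(series_by_species: dict, path) -> None:
    rows = []
    for species, series in series_by_species.items():
        for date, count in series.items():
            rows.append(
                {"date": date.date().isoformat(), "species": species, "count": int(count)}
            )
    pd.DataFrame(rows, columns=WEIR_COLUMNS).to_csv(path, index=False)


def read_travel_times(path) -> np.ndarray:
    frame = pd.read_csv(path)
    _require(frame, ("lag_days",), path)
    lags = frame["lag_days"].to_numpy()
    if np.any(lags < 0):
        raise RowError(f"{path}: negative travel time")
    return lags.astype(int)


def write_travel_times(lags, path) -> None:
    pd.DataFrame({"lag_days": np.asarray(lags, dtype=int)}).to_csv(path, index=False)


def write_verdicts(result, path) -> None:
    """Write the verdict table (train_id, timestamp, verdict, minICI, ICIir)."""
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    out = frame.copy()
    out["timestamp"] = out["timestamp"].map(
        lambda t: t.isoformat() if pd.notna(t) else ""
    )
    out.to_csv(path, index=False)


def read_verdicts(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require(frame, ("train_id", "timestamp", "verdict", "minICI"), path)
    frame = frame.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], errors="coerce", format="mixed")
    return frame


def read_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file."""
    config = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RowError(f"{path}: line {lineno} is not 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        config[key] = value
    return config
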