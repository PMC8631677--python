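"""Inter-click-interval (ICI) features of echolocation click trains.

A beluga click train that ends in prey capture shows a characteristic
gradual decrease of the inter-click interval into a *terminal buzz*; social
buzzes instead show irregular, longer ICI.  This module computes the ICI
sequence of a train and the five summary variables used to separate the two
behaviors:

``minICI``, ``maxICI``
    minimum and maximum ICI of the whole train, in milliseconds.
``ICIr``
    the ICI range, ``maxICI - minICI``.
``slope``
    ordinary-least-squares slope of ICI (ms) against the peak time (s) of
    the click opening each interval.
``ICIir``
    the ICI increment range: the maximum difference between consecutive
    ICIs within the buzz section.  Negative when the buzz ICI strictly
    decreases (feeding), positive when the ICI jumps upward (social).

The buzz section of a feeding or unlabeled train starts at the first ICI at
or below the onset threshold (9 ms by default); a social buzz is buzzing
throughout, so its entire ICI sequence is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTrainError, InputOrderError

#: Default ICI threshold (ms) marking the onset of a terminal buzz.
ONSET_THRESHOLD_MS = 9.0

#: Canonical ordering of the five acoustic variables.
FEATURE_COLUMNS = ("minICI", "maxICI", "ICIr", "ICIir", "slope")

CONTEXTS = ("feeding", "social", "unknown")


@dataclass(frozen=True)
class ClickTrain:
    """An ordered sequence of click peak times from one echolocation event.

    Parameters
    ----------
    train_id : str
        Unique identifier of the click train within a dataset.
    source_id : str
        Whale or mooring identifier the train was recorded from.
    context : {"feeding", "social", "unknown"}
        Presumed behavioral context; ``unknown`` for moored-recorder data.
    click_times : numpy.ndarray
        Click peak times in seconds from an arbitrary epoch, strictly
        increasing.
    start_time : pandas.Timestamp, optional
        Absolute timestamp of the first click (moored-recorder data only).
    """

    train_id: str
    source_id: str = ""
    context: str = "unknown"
    click_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )
        object.__setattr__(
            self, "click_times", np.asarray(self.click_times, dtype=float)
        )

    @property
    def n_clicks(self) -> int:
        return len(self.click_times)


@dataclass(frozen=True)
class ICISeries:
    """Inter-click intervals of one train and their consecutive differences.

    ``ici[i]`` is the interval (ms) between clicks ``i`` and ``i+1``;
    ``increments[i] = ici[i+1] - ici[i]``.
    """

    ici: np.ndarray
    increments: np.ndarray


@dataclass(frozen=True)
class BuzzFeatureVector:
    """The five acoustic variables of one click train plus buzz bookkeeping."""

    train_id: str
    min_ici: float
    max_ici: float
    ici_range: float
    ici_increment_range: Optional[float]
    slope: float
    buzz_onset_index: Optional[int]
    n_clicks: int
    context: str = "unknown"

    def as_dict(self) -> dict:
        """Row representation using the field's printed variable names."""
        return {
            "train_id": self.train_id,
            "context": self.context,
            "n_clicks": self.n_clicks,
            "minICI": self.min_ici,
            "maxICI": self.max_ici,
            "ICIr": self.ici_range,
            "ICIir": self.ici_increment_range,
            "slope": self.slope,
            "buzz_onset_index": self.buzz_onset_index,
        }


def compute_ici(train: ClickTrain) -> ICISeries:
    """Compute inter-click intervals (ms) and their increments.

    Raises
    ------
    DegenerateTrainError
        If the train has fewer than 2 clicks.
    InputOrderError
        If click times are not strictly increasing.
    """
    t = np.asarray(train.click_times, dtype=float)
    if len(t) < 2:
        raise DegenerateTrainError(
            f"train {train.train_id!r}: need >= 2 clicks to form an ICI, "
            f"got {len(t)}"
        )
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InputOrderError(
            f"train {train.train_id!r}: click times must be strictly increasing"
        )
    # round to 1e-12 ms (1e-15 s): absorbs representation noise from time
    # differencing, far below any instrument's clock resolution, so exact
    # threshold comparisons (e.g. the 9-ms onset boundary) behave as written
    ici = np.round(dt * 1000.0, 12)
    return ICISeries(ici=ici, increments=np.diff(ici))


def detect_buzz_onset(
    ici: ICISeries | Sequence[float] | np.ndarray,
    onset_threshold_ms: float = ONSET_THRESHOLD_MS,
) -> Optional[int]:
    """Index of the first ICI at or below the onset threshold, or ``None``.

    The threshold boundary is inclusive: an ICI of exactly 9 ms opens the
    terminal buzz.
    """
    values = ici.ici if isinstance(ici, ICISeries) else np.asarray(ici, float)
    if len(values) == 0:
        raise DegenerateTrainError("empty ICI series")
    idx = np.nonzero(values <= onset_threshold_ms)[0]
    return int(idx[0]) if len(idx) else None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    # centered form: exactly 0 for constant y, invariant to shifting x
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc, yc) / denom)


def extract_features(
    train: ClickTrain,
    onset_threshold_ms: float = ONSET_THRESHOLD_MS,
    context: Optional[str] = None,
    slope_regressor: str = "time",
) -> BuzzFeatureVector:
    """Compute the five acoustic variables of a click train.

    ``minICI``/``maxICI``/``ICIr``/``slope`` are computed over the full ICI
    series.  ``ICIir`` is computed over the buzz section only: for feeding
    and unknown trains the section starts at the first ICI at or below
    ``onset_threshold_ms``; a social buzz is buzzing throughout, so the
    whole train is its buzz section.  ``ICIir`` is the maximum increment
    within that section, and is absent (``None``) when the section does not
    exist or holds fewer than two ICIs.

    Parameters
    ----------
    train : ClickTrain
        At least 3 clicks (so at least one increment exists).
    context : str, optional
        Override the train's stored context (e.g. force ``"unknown"`` when
        classifying moored-recorder data).
    slope_regressor : {"time", "index"}
        Regress ICI on the opening click's peak time in seconds (default),
        or on the interval index.
    """
    if train.n_clicks < 3:
        raise DegenerateTrainError(
            f"train {train.train_id!r}: need >= 3 clicks for feature "
            f"extraction, got {train.n_clicks}"
        )
    ctx = train.context if context is None else context
    if ctx not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {ctx!r}")
    series = compute_ici(train)
    ici = series.ici

    if slope_regressor == "time":
        x = train.click_times[:-1] - train.click_times[0]
    elif slope_regressor == "index":
        x = np.arange(len(ici), dtype=float)
    else:
        raise ValueError("slope_regressor must be 'time' or 'index'")
    slope = _ols_slope(np.asarray(x, float), ici)

    if ctx == "social":
        onset: Optional[int] = None
        section = ici
    else:
        onset = detect_buzz_onset(series, onset_threshold_ms)
        section = ici[onset:] if onset is not None else ici[:0]

    if len(section) >= 2:
        iciir: Optional[float] = float(np.diff(section).max())
    else:
        iciir = None

    return BuzzFeatureVector(
        train_id=train.train_id,
        min_ici=float(ici.min()),
        max_ici=float(ici.max()),
        ici_range=float(ici.max() - ici.min()),
        ici_increment_range=iciir,
        slope=slope,
        buzz_onset_index=onset,
        n_clicks=train.n_clicks,
        context=ctx,
    )


def features_frame(features: Sequence[BuzzFeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table, one row per train."""
    return pd.DataFrame([f.as_dict() for f in features])
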