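"""Synthetic click trains, mooring streams, and weir seasons.

The generators emulate the statistical structure the analysis assumes so
that every stage of the pipeline can be exercised without field data:

* feeding click trains whose ICI decreases gradually into a terminal buzz
  (minimum ICI in the 2.3-8.92 ms band, all buzz increments negative,
  pre-buzz mean ICI two to five times the buzz mean);
* social buzzes with irregular, longer ICI (minimum ICI in the
  9.03-29.75 ms band, maximum increment in the 2.98-18.72 ms band);
* Poisson-timed mooring detection streams mixing both train types, with
  the planted feeding minutes kept as ground truth;
* weir-count seasons built from a Gaussian pulse of site arrivals, each
  fish delayed by an empirical travel-time lag.

All generators draw exclusively from the ``numpy.random.Generator`` passed
in, so a fixed seed reproduces every dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .buzzfeatures import ClickTrain, extract_features, features_frame
from .errors import GenerationError


@dataclass(frozen=True)
class FeedingBuzzParams:
    """Feeding click-train generator settings (ICI quantities in ms).

    The minICI and buzz-increment bands default to the observed feeding
    ranges; the pre-buzz/buzz mean-ICI ratio band reflects the two-to-five
    fold ICI drop into the buzz.  The buzz must start at or below 9 ms and
    descend by steps no smaller than the drawn increment magnitude, so the
    feasible (minICI, increment) pairs are drawn jointly.
    """

    buzz_min_ici: tuple = (2.3, 8.92)
    buzz_increment: tuple = (-8.82, -0.42)  # band for the maximum increment
    prebuzz_ratio: tuple = (2.2, 4.6)
    n_clicks: tuple = (30, 80)
    buzz_onset_band: tuple = (8.2, 8.99)  # first buzz ICI drawn here

    def __post_init__(self) -> None:
        if self.buzz_min_ici[1] >= 8.976:
            raise GenerationError("feeding minICI band must stay below 8.976 ms")
        if self.buzz_increment[1] >= 0:
            raise GenerationError("feeding buzz increments must be negative")
        if self.n_clicks[0] < 3:
            raise GenerationError("a click train needs at least 3 clicks")


@dataclass(frozen=True)
class SocialBuzzParams:
    """Social buzz generator settings (ICI quantities in ms)."""

    min_ici: tuple = (9.03, 29.75)
    max_increment: tuple = (2.98, 18.72)
    duration_multiplier: float = 2.0  # social buzzes run longer than feeding
    n_clicks: tuple = (30, 80)

    def __post_init__(self) -> None:
        if self.min_ici[0] <= 8.976:
            raise GenerationError("social minICI band must stay above 8.976 ms")
        if self.max_increment[0] <= 1.49:
            raise GenerationError(
                "social maximum increments must exceed 1.49 ms"
            )
        if self.n_clicks[0] < 3:
            raise GenerationError("a click train needs at least 3 clicks")


def _ici_to_times(ici_ms: np.ndarray, t0: float = 0.0) -> np.ndarray:
    return t0 + np.concatenate([[0.0], np.cumsum(ici_ms) / 1000.0])


def gen_feeding_train(
    params: FeedingBuzzParams = FeedingBuzzParams(),
    rng: Optional[np.random.Generator] = None,
    train_id: str = "feed",
    source_id: str = "synthetic",
    start_time: Optional[pd.Timestamp] = None,
    n_clicks: Optional[int] = None,
) -> ClickTrain:
    """One feeding click train ending in a strictly decreasing terminal buzz.

    The buzz opens at an ICI drawn just below 9 ms and descends to the
    drawn minimum ICI in steps no smaller than the drawn increment
    magnitude, so the realized maximum buzz increment lands inside the
    configured negative band.  The pre-buzz section is a decreasing ramp
    held strictly above 9 ms whose mean sits at the drawn multiple of the
    buzz mean.
    """
    rng = np.random.default_rng() if rng is None else rng
    total = int(
        n_clicks if n_clicks is not None else rng.integers(*params.n_clicks)
    )
    if total < 3:
        raise GenerationError(f"need at least 3 clicks, requested {total}")

    b0 = rng.uniform(*params.buzz_onset_band)
    min_ici = rng.uniform(params.buzz_min_ici[0], min(params.buzz_min_ici[1], b0 - 0.6))
    drop = b0 - min_ici
    step_mag = rng.uniform(
        max(-params.buzz_increment[1], 1e-3),
        min(-params.buzz_increment[0], drop),
    )

    n_ici_total = total - 1
    max_steps = max(1, min(n_ici_total - 3, int(drop // step_mag)))
    n_steps = int(rng.integers(1, max_steps + 1))
    steps = np.full(n_steps, step_mag)
    leftover = drop - steps.sum()
    if n_steps == 1:
        steps[0] = drop  # single step: the increment is the whole descent
    elif leftover > 0:
        # spread the leftover over all steps but one, keeping the smallest
        # step (the realized maximum increment) exactly at step_mag
        extra = rng.random(n_steps - 1)
        steps[1:] += leftover * extra / extra.sum()
    buzz = np.concatenate([[b0], b0 - np.cumsum(steps)])
    buzz[-1] = min_ici  # guard against round-off

    n_pre = max(3, n_ici_total - len(buzz))
    ratio = rng.uniform(*params.prebuzz_ratio)
    pre_end = rng.uniform(9.3, 10.5)
    target_mean = max(ratio * buzz.mean(), pre_end + 0.8)
    pre_start = 2 * target_mean - pre_end
    pre = np.linspace(pre_start, pre_end, n_pre)
    if n_pre > 2:
        jitter = rng.uniform(-0.08, 0.08, n_pre - 2)
        pre[1:-1] = np.maximum(pre[1:-1] + jitter, 9.05)
    ici = np.concatenate([pre, buzz])
    return ClickTrain(
        train_id=train_id,
        source_id=source_id,
        context="feeding",
        click_times=_ici_to_times(ici),
        start_time=start_time,
    )


def gen_social_buzz(
    params: SocialBuzzParams = SocialBuzzParams(),
    rng: Optional[np.random.Generator] = None,
    train_id: str = "soc",
    source_id: str = "synthetic",
    start_time: Optional[pd.Timestamp] = None,
    n_clicks: Optional[int] = None,
) -> ClickTrain:
    """One social buzz: irregular ICI with alternating-sign increments.

    The sequence starts at the drawn minimum ICI, immediately rises by the
    drawn maximum increment (so the realized increment range is exact),
    then alternates smaller rises and falls while never dipping below the
    minimum or rising faster than the planted maximum increment.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_clicks is None:
        base = rng.integers(*params.n_clicks)
        total = int(round(base * params.duration_multiplier))
    else:
        total = int(n_clicks)
    if total < 3:
        raise GenerationError(f"need at least 3 clicks, requested {total}")

    m0 = rng.uniform(*params.min_ici)
    g = rng.uniform(*params.max_increment)
    n_ici = total - 1
    ici = np.empty(n_ici)
    ici[0] = m0
    v = m0 + g  # first increment is the planted maximum
    for i in range(1, n_ici):
        ici[i] = v
        if i == n_ici - 1:
            break
        if i % 2 == 1:  # fall, staying at or above the minimum
            v -= rng.uniform(0.2, 1.0) * (v - m0)
        else:  # rise, strictly slower than the planted maximum
            v += rng.uniform(0.3, 0.95) * g
    return ClickTrain(
        train_id=train_id,
        source_id=source_id,
        context="social",
        click_times=_ici_to_times(ici),
        start_time=start_time,
    )


def gen_buzz_dataset(
    n_feeding: int = 18,
    n_social: int = 19,
    feeding_params: FeedingBuzzParams = FeedingBuzzParams(),
    social_params: SocialBuzzParams = SocialBuzzParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """A labeled buzz dataset sized like the tag study (18 feeding / 19 social).

    Returns ``(trains, features)`` where ``features`` is the per-train
    table of the five acoustic variables computed under the known context.
    """
    if n_feeding < 0 or n_social < 0 or n_feeding + n_social < 1:
        raise GenerationError("need at least one train")
    rng = np.random.default_rng() if rng is None else rng
    trains = [
        gen_feeding_train(feeding_params, rng, train_id=f"feed_{i + 1:02d}")
        for i in range(n_feeding)
    ] + [
        gen_social_buzz(social_params, rng, train_id=f"soc_{i + 1:02d}")
        for i in range(n_social)
    ]
    features = features_frame([extract_features(t) for t in trains])
    return trains, features


@dataclass
class MooringStream:
    """A simulated moored-recorder season with bookkeeping ground truth."""

    trains: list
    events: pd.DataFrame  # timestamp, signal_type, instrument
    planted_feeding_minutes: set = field(default_factory=set)

    def planted_fpm_per_day(self) -> pd.Series:
        """Daily count of planted feeding minutes (the FPM oracle)."""
        idx = pd.DatetimeIndex(sorted(self.planted_feeding_minutes))
        return idx.normalize().value_counts().sort_index()


def gen_mooring_stream(
    start_date: str | pd.Timestamp = "2018-05-01",
    days: int = 10,
    trains_per_day: float = 20.0,
    feeding_fraction: float = 0.3,
    calls_per_day: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> MooringStream:
    """Poisson-timed click trains plus matching detection events.

    Each train is timestamped uniformly within its day and generated by
    the feeding or social generator according to ``feeding_fraction``.
    Every train start also emits an echolocation detection event; call
    events arrive at an independent Poisson rate.  The clock minutes of
    feeding-train starts are recorded as ground truth for FPM recovery.
    """
    if trains_per_day < 0 or calls_per_day < 0:
        raise GenerationError("rates must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    day0 = pd.Timestamp(start_date).normalize()
    trains: list = []
    rows: list = []
    planted: set = set()
    counter = 0
    for d in range(days):
        day = day0 + pd.Timedelta(days=d)
        n_trains = rng.poisson(trains_per_day)
        seconds = np.sort(rng.uniform(0, 86400, n_trains))
        for s in seconds:
            counter += 1
            ts = day + pd.Timedelta(seconds=float(s))
            is_feeding = rng.random() < feeding_fraction
            gen = gen_feeding_train if is_feeding else gen_social_buzz
            train = gen(
                rng=rng,
                train_id=f"cp_{counter:05d}",
                source_id="mooring",
                start_time=ts,
            )
            trains.append(train)
            rows.append((ts, "echolocation", "click_logger"))
            if is_feeding:
                planted.add(ts.floor("min"))
        n_calls = rng.poisson(calls_per_day)
        for s in rng.uniform(0, 86400, n_calls):
            rows.append(
                (
                    day + pd.Timedelta(seconds=float(s)),
                    rng.choice(["call", "whistle"]),
                    "broadband_recorder",
                )
            )
    events = pd.DataFrame(rows, columns=["timestamp", "signal_type", "instrument"])
    events = events.sort_values("timestamp", ignore_index=True)
    return MooringStream(trains=trains, events=events, planted_feeding_minutes=planted)


@dataclass
class WeirSeason:
    """A simulated run season with the true site-arrival series retained."""

    weir: pd.Series  # daily counts at the weir
    travel_time_samples: np.ndarray  # individual lags (days)
    true_site: pd.Series  # daily counts at the site (ground truth)


def gen_weir_season(
    run_center: str | pd.Timestamp = "2018-06-07",
    run_sd_days: float = 5.0,
    total_fish: int = 10000,
    lag_samples: Optional[Sequence[int]] = None,
    species: str = "chinook",
    rng: Optional[np.random.Generator] = None,
) -> WeirSeason:
    """Fish arrive at the site on a Gaussian pulse, reach the weir lagged.

    Each fish's site-arrival date is a rounded normal draw around
    ``run_center``; its weir date adds a travel time drawn (with
    replacement) from ``lag_samples``.  Returns the weir series, the lag
    draws actually used, and the true site series for recovery testing.
    """
    if total_fish < 1:
        raise GenerationError("need at least one fish")
    rng = np.random.default_rng() if rng is None else rng
    center = pd.Timestamp(run_center).normalize()
    if lag_samples is None:
        # integer-day travel times spanning 3-33 days, median near 14
        lag_samples = np.clip(
            np.round(rng.gamma(shape=6.0, scale=2.5, size=200)), 3, 33
        ).astype(int)
    lag_samples = np.asarray(lag_samples, dtype=int)
    offsets = np.round(rng.normal(0.0, run_sd_days, total_fish)).astype(int)
    lags = rng.choice(lag_samples, size=total_fish, replace=True)

    site_days = pd.to_timedelta(offsets, unit="D") + center
    weir_days = site_days + pd.to_timedelta(lags, unit="D")

    def _daily(days: pd.DatetimeIndex) -> pd.Series:
        counts = pd.Series(days).value_counts().sort_index()
        full = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
        return counts.reindex(full, fill_value=0).rename(species)

    return WeirSeason(
        weir=_daily(pd.DatetimeIndex(weir_days)),
        travel_time_samples=lags,
        true_site=_daily(pd.DatetimeIndex(site_days)),
    )
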