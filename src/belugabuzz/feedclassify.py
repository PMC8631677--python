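"""Two-step threshold classification of click trains as feeding events.

A click train from a moored recorder is called a feeding event when its
minimum ICI is below 8.976 ms (the cut separating feeding from social
buzzes) AND the maximum ICI increment within its terminal-buzz section is
below 1.49 ms (confirming a consistently decreasing buzz rather than a
single fast interval).  Trains whose minimum ICI falls below 1 ms are
excluded outright: such intervals are almost always surface-reflection
multipath duplicates, not real click repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .buzzfeatures import BuzzFeatureVector, ClickTrain, extract_features
from .errors import BelugabuzzError

logger = logging.getLogger(__name__)

FEEDING = "feeding"
NOT_FEEDING = "not_feeding"
EXCLUDED_MULTIPATH = "excluded_multipath"

VERDICTS = (FEEDING, NOT_FEEDING, EXCLUDED_MULTIPATH)


@dataclass(frozen=True)
class ThresholdRuleSet:
    """The constants of the two-step classifier (all in milliseconds).

    ``min_ici_cut`` and ``ici_increment_cut`` are the published decision
    constants, not the stump midpoint re-derived from any particular
    sample.  ``multipath_floor`` removes sub-millisecond ICIs caused by
    surface-reflected duplicate arrivals.  ``onset_threshold`` defines
    where the terminal-buzz section starts when computing the increment
    range.
    """

    min_ici_cut: float = 8.976
    ici_increment_cut: float = 1.49
    multipath_floor: float = 1.0
    onset_threshold: float = 9.0

    def __post_init__(self) -> None:
        if not (0 < self.multipath_floor < self.min_ici_cut < self.onset_threshold):
            raise ValueError(
                "require 0 < multipath_floor < min_ici_cut < onset_threshold, "
                f"got {self.multipath_floor}, {self.min_ici_cut}, "
                f"{self.onset_threshold}"
            )
        if self.ici_increment_cut <= 0:
            raise ValueError("ici_increment_cut must be positive")


@dataclass(frozen=True)
class TrainVerdict:
    """Per-train classification outcome."""

    train_id: str
    verdict: str
    min_ici: float
    ici_increment_range: Optional[float]
    first_click_time: Optional[pd.Timestamp] = None


def classify_train(
    features: BuzzFeatureVector,
    rules: ThresholdRuleSet = ThresholdRuleSet(),
    first_click_time: Optional[pd.Timestamp] = None,
) -> TrainVerdict:
    """Apply the two-step rule to one train's features.

    Evaluation order: (1) a minimum ICI below the multipath floor excludes
    the train; (2) a minimum ICI at or above the minICI cut fails; (3) a
    missing increment range (no buzz section with two or more ICIs) fails;
    (4) an increment range below the cut passes.  All inequalities are
    strict.
    """
    if features.min_ici < rules.multipath_floor:
        verdict = EXCLUDED_MULTIPATH
    elif features.min_ici >= rules.min_ici_cut:
        verdict = NOT_FEEDING
    elif features.ici_increment_range is None:
        verdict = NOT_FEEDING
    elif features.ici_increment_range < rules.ici_increment_cut:
        verdict = FEEDING
    else:
        verdict = NOT_FEEDING
    return TrainVerdict(
        train_id=features.train_id,
        verdict=verdict,
        min_ici=features.min_ici,
        ici_increment_range=features.ici_increment_range,
        first_click_time=first_click_time,
    )


@dataclass
class StreamResult:
    """Verdicts for a stream of trains plus a report of skipped inputs."""

    verdicts: list
    skipped: list  # (train_id, reason) pairs

    @property
    def skip_count(self) -> int:
        return len(self.skipped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "train_id": [v.train_id for v in self.verdicts],
                "timestamp": [v.first_click_time for v in self.verdicts],
                "verdict": [v.verdict for v in self.verdicts],
                "minICI": [v.min_ici for v in self.verdicts],
                "ICIir": [v.ici_increment_range for v in self.verdicts],
            }
        )


def classify_stream(
    trains: Sequence[ClickTrain],
    rules: ThresholdRuleSet = ThresholdRuleSet(),
) -> StreamResult:
    """Classify each train in input order, skipping malformed ones.

    Features are computed with the behavioral context forced to unknown
    (the onset rule defines the buzz section), as on moored-recorder data.
    Trains that cannot yield features (fewer than 3 clicks, non-monotonic
    times) are skipped with a logged reason, never silently dropped.
    """
    verdicts: list = []
    skipped: list = []
    for train in trains:
        try:
            feats = extract_features(
                train, onset_threshold_ms=rules.onset_threshold, context="unknown"
            )
        except BelugabuzzError as exc:
            logger.warning("skipping train %s: %s", train.train_id, exc)
            skipped.append((train.train_id, str(exc)))
            continue
        verdicts.append(classify_train(feats, rules, train.start_time))
    logger.info(
        "classified %d trains (%d skipped)", len(verdicts), len(skipped)
    )
    return StreamResult(verdicts=verdicts, skipped=skipped)
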