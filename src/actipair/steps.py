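"""Minute-level step-count processing.

Turns raw minute-by-minute step counts from a wrist- or torso-worn tracker
into wear time, per-minute intensity classes, day summaries and weekly
activity measures.  The rules are cadence-based: minutes are classified by
their step count (sedentary 0-9, walking 10-100, moderate 101-130, vigorous
131-200 steps/min), implausible minutes (>200 steps) are recoded missing,
and nonwear is any run of at least 120 contiguous zero-step minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import IntEnum

import numpy as np

from .config import StepConfig

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440


class Label(IntEnum):
    """Per-minute classification codes."""

    NONWEAR = 0
    MISSING = 1
    SEDENTARY = 2
    WALKING = 3
    MODERATE = 4
    VIGOROUS = 5


@dataclass
class MinuteStepSeries:
    """One participant's minute-indexed step counts over whole calendar days.

    ``steps`` is a float array where ``NaN`` marks a missing minute (absent
    from the feed, or recoded as spurious).  Minute 0 of day *d* is
    ``1440 * d`` minutes after local midnight of ``start_date``.
    """

    participant_id: str
    start_date: date
    steps: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 1:
            raise ValueError("steps must be one-dimensional")
        if self.steps.size == 0 or self.steps.size % MINUTES_PER_DAY != 0:
            raise ValueError(
                "series length must be a positive multiple of 1440 minutes, "
                f"got {self.steps.size}"
            )
        present = self.steps[~np.isnan(self.steps)]
        if present.size and present.min() < 0:
            raise ValueError("step counts must be non-negative")

    @property
    def n_days(self) -> int:
        return self.steps.size // MINUTES_PER_DAY

    def day_date(self, day_index: int) -> date:
        return self.start_date + timedelta(days=day_index)


@dataclass
class MinuteClassification:
    """Per-minute labels aligned with a :class:`MinuteStepSeries`."""

    labels: np.ndarray  # int8 array of Label codes

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def minutes_of(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class DaySummary:
    """Wear and class-minute accounting for one calendar day.

    ``wear_minutes = 1440 - nonwear_minutes - missing_minutes``: a recoded
    artifact minute implies the device was worn but the value is unusable,
    so it counts toward neither wear nor nonwear.
    """

    participant_id: str
    date: date
    day_index: int
    wear_minutes: int
    nonwear_minutes: int
    missing_minutes: int
    steps_total: float
    minutes_by_class: dict[Label, int]
    adequate: bool


@dataclass
class FitbitWeekMeasures:
    """Device-derived weekly activity summary (the tracker side of Table-2
    style measures).

    Units mirror the questionnaire analogues: steps/d, hours per week for
    active / sedentary / walking time, minutes per week for moderate and
    vigorous activity, and mean daily wear in hours.
    """

    steps_per_day: float
    active_time_h: float
    sedentary_time_h: float
    walking_time_h: float
    moderate_time_min: float
    vigorous_time_min: float
    wear_time_h_per_day: float
    n_adequate_days: int

    @property
    def moderate_time_h(self) -> float:
        return self.moderate_time_min / 60.0

    @property
    def vigorous_time_h(self) -> float:
        return self.vigorous_time_min / 60.0


def recode_spurious_minutes(
    series: MinuteStepSeries, config: StepConfig = StepConfig()
) -> MinuteStepSeries:
    """Recode minutes with more than ``spurious_step_threshold`` steps as
    missing.  Pure and idempotent; the boundary value itself is kept."""
    steps = series.steps.copy()
    with np.errstate(invalid="ignore"):
        spurious = steps > config.spurious_step_threshold
    n = int(np.count_nonzero(spurious))
    if n:
        logger.debug(
            "participant %s: recoded %d spurious minutes", series.participant_id, n
        )
    steps[spurious] = np.nan
    return MinuteStepSeries(series.participant_id, series.start_date, steps)


def _zero_runs(steps: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exactly-zero minutes as half-open [start, end) pairs.
    Missing (NaN) minutes break runs."""
    zero = np.zeros(steps.size + 2, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        zero[1:-1] = steps == 0
    edges = np.flatnonzero(np.diff(zero))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_nonwear(
    series: MinuteStepSeries, config: StepConfig = StepConfig()
) -> list[tuple[int, int]]:
    """Find nonwear intervals: maximal runs of >= ``nonwear_min_run``
    contiguous zero-step minutes.

    Returns disjoint, sorted, half-open ``[start, end)`` minute intervals.
    Runs may span day boundaries; apportioning to days happens in
    :func:`summarize_day`.
    """
    return [
        (s, e) for s, e in _zero_runs(series.steps) if e - s >= config.nonwear_min_run
    ]


def classify_minutes(
    series: MinuteStepSeries, config: StepConfig = StepConfig()
) -> MinuteClassification:
    """Label every minute of an (already recoded) series.

    Minutes inside nonwear intervals are NONWEAR; absent minutes MISSING;
    the rest fall into the closed cadence bins.  A surviving value above the
    spurious threshold indicates :func:`recode_spurious_minutes` was not
    applied and raises ``ValueError``.
    """
    steps = series.steps
    present = ~np.isnan(steps)
    if present.any() and np.nanmax(steps) > config.spurious_step_threshold:
        raise ValueError(
            "series contains steps above the spurious threshold; run "
            "recode_spurious_minutes first"
        )
    labels = np.full(steps.size, Label.MISSING, dtype=np.int8)

    s = np.where(present, steps, -1.0)
    labels[(s >= 0) & (s <= config.sedentary_max_steps)] = Label.SEDENTARY
    for lab, (lo, hi) in (
        (Label.WALKING, config.walking_range),
        (Label.MODERATE, config.moderate_range),
        (Label.VIGOROUS, config.vigorous_range),
    ):
        labels[(s >= lo) & (s <= hi)] = lab

    for start, end in detect_nonwear(series, config):
        labels[start:end] = Label.NONWEAR

    if config.long_low_bouts == "nonwear":
        # alternative reading: runs of >=120 low-step minutes are nonwear too
        low = np.zeros(steps.size + 2, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            low[1:-1] = (steps >= 0) & (steps <= config.sedentary_max_steps)
        edges = np.flatnonzero(np.diff(low))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= config.nonwear_min_run:
                labels[start:end] = Label.NONWEAR

    return MinuteClassification(labels)


def summarize_day(
    series: MinuteStepSeries,
    classification: MinuteClassification,
    day_index: int,
    config: StepConfig = StepConfig(),
) -> DaySummary:
    """Aggregate one calendar day (minutes ``1440*d .. 1440*(d+1)``)."""
    if not 0 <= day_index < series.n_days:
        raise IndexError(f"day_index {day_index} out of range for {series.n_days} days")
    sl = slice(day_index * MINUTES_PER_DAY, (day_index + 1) * MINUTES_PER_DAY)
    labels = classification.labels[sl]
    counts = np.bincount(labels, minlength=len(Label))
    by_class = {lab: int(counts[lab]) for lab in Label}
    nonwear = by_class[Label.NONWEAR]
    missing = by_class[Label.MISSING]
    wear = MINUTES_PER_DAY - nonwear - missing
    return DaySummary(
        participant_id=series.participant_id,
        date=series.day_date(day_index),
        day_index=day_index,
        wear_minutes=wear,
        nonwear_minutes=nonwear,
        missing_minutes=missing,
        steps_total=float(np.nansum(series.steps[sl])),
        minutes_by_class=by_class,
        adequate=wear >= config.adequate_wear_minutes,
    )


def summarize_week(
    day_summaries: list[DaySummary],
    min_adequate_days: int = 7,
    rescale: bool = False,
) -> FitbitWeekMeasures:
    """Aggregate exactly 7 consecutive day summaries into weekly measures.

    By default every day must be adequate (>=10 h wear); callers gate weeks
    upstream.  With ``min_adequate_days < 7`` and ``rescale=True``, weekly
    sums are computed from the adequate days and rescaled by ``7/k``.
    """
    if len(day_summaries) != 7:
        raise ValueError(f"a week needs exactly 7 day summaries, got {len(day_summaries)}")
    for prev, cur in zip(day_summaries, day_summaries[1:]):
        if (cur.date - prev.date).days != 1:
            raise ValueError("day summaries must cover consecutive calendar days")
    adequate = [d for d in day_summaries if d.adequate]
    if len(adequate) < min_adequate_days:
        raise ValueError(
            f"only {len(adequate)} of 7 days adequate (need {min_adequate_days})"
        )
    used = day_summaries
    scale = 1.0
    if len(adequate) < 7:
        if not rescale:
            raise ValueError("inadequate days present and rescaling is disabled")
        used = adequate
        scale = 7.0 / len(adequate)

    def total(lab: Label) -> float:
        return scale * sum(d.minutes_by_class[lab] for d in used)

    walking_min = total(Label.WALKING)
    moderate_min = total(Label.MODERATE)
    vigorous_min = total(Label.VIGOROUS)
    return FitbitWeekMeasures(
        steps_per_day=float(np.mean([d.steps_total for d in used])),
        active_time_h=(walking_min + moderate_min + vigorous_min) / 60.0,
        sedentary_time_h=total(Label.SEDENTARY) / 60.0,
        walking_time_h=walking_min / 60.0,
        moderate_time_min=moderate_min,
        vigorous_time_min=vigorous_min,
        wear_time_h_per_day=float(np.mean([d.wear_minutes for d in used])) / 60.0,
        n_adequate_days=len(adequate),
    )


def process_series(
    series: MinuteStepSeries, config: StepConfig = StepConfig()
) -> list[DaySummary]:
    """Convenience path: recode, classify and summarize every day."""
    recoded = recode_spurious_minutes(series, config)
    classification = classify_minutes(recoded, config)
    return [
        summarize_day(recoded, classification, d, config)
        for d in range(recoded.n_days)
    ]
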