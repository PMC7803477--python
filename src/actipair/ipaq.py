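"""IPAQ short-form cleaning and scoring.

The IPAQ short form asks, for the last 7 days, on how many days and for how
many minutes per day the respondent was vigorously active, moderately
active, and walking, plus sitting minutes on a typical day.  Cleaning
follows the public IPAQ scoring-protocol rules (sub-10-minute episodes
recoded to zero, categories truncated at 180 min/day, responses invalidated
when summed daily activity exceeds 960 min); scoring converts to weekly
minutes per intensity and overall activity in MET-h/wk using the protocol
MET multipliers (walking 3.3, moderate 4.0, vigorous 8.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date

from .config import IpaqCleaningConfig, MetValues

_INTENSITIES = ("walking", "moderate", "vigorous")


@dataclass(frozen=True)
class IpaqRawResponse:
    """One IPAQ short-form response; ``None`` marks a missing/refused item."""

    participant_id: str
    response_date: date
    walking_days: float | None = None
    walking_min_per_day: float | None = None
    moderate_days: float | None = None
    moderate_min_per_day: float | None = None
    vigorous_days: float | None = None
    vigorous_min_per_day: float | None = None
    sitting_min_per_day: float | None = None

    def days(self, intensity: str) -> float | None:
        return getattr(self, f"{intensity}_days")

    def minutes(self, intensity: str) -> float | None:
        return getattr(self, f"{intensity}_min_per_day")


@dataclass
class CleanedIpaq:
    """A cleaned response with the original kept alongside and every applied
    rule recorded in ``cleaning_flags``."""

    response: IpaqRawResponse
    original: IpaqRawResponse
    cleaning_flags: tuple[str, ...]
    valid: bool


@dataclass
class IpaqMeasures:
    """Scored weekly self-report measures, unit-matched to the device side."""

    walking_time_h: float
    moderate_time_min: float
    vigorous_time_min: float
    sedentary_time_h: float  # NaN when sitting was not answered
    active_time_h: float
    met_hours: float
    valid: bool
    cleaning_flags: tuple[str, ...]

    @property
    def moderate_time_h(self) -> float:
        return self.moderate_time_min / 60.0

    @property
    def vigorous_time_h(self) -> float:
        return self.vigorous_time_min / 60.0


def _check_parseable(raw: IpaqRawResponse) -> None:
    for k in _INTENSITIES:
        d = raw.days(k)
        if d is not None:
            if not float(d).is_integer() or not 0 <= d <= 7:
                raise ValueError(
                    f"{raw.participant_id}: {k}_days must be an integer in 0..7, got {d}"
                )
        m = raw.minutes(k)
        if m is not None and (not math.isfinite(m) or m < 0):
            raise ValueError(
                f"{raw.participant_id}: {k}_min_per_day must be >= 0, got {m}"
            )
    s = raw.sitting_min_per_day
    if s is not None and (not math.isfinite(s) or s < 0):
        raise ValueError(f"{raw.participant_id}: sitting_min_per_day must be >= 0")


def clean_ipaq(
    raw: IpaqRawResponse, rules: IpaqCleaningConfig = IpaqCleaningConfig()
) -> CleanedIpaq:
    """Apply the cleaning rules, in order, recording each applied rule.

    Rule order: (1) per-category episodes below ``min_daily_minutes`` are
    recoded to 0; (2) the daily-total validity cap ``max_total_daily_minutes``
    is evaluated on the post-floor totals; (3) each category is truncated at
    ``max_daily_minutes``.  The validity cap is checked before truncation
    because truncated categories can never sum past it.

    A category answered with both items missing is taken as no activity
    (flagged); a half-answered category invalidates the response.  Raises
    ``ValueError`` for unparseable values (record-level rejection).
    """
    _check_parseable(raw)
    flags: list[str] = []
    valid = True
    updates: dict[str, float | None] = {}

    for k in _INTENSITIES:
        d, m = raw.days(k), raw.minutes(k)
        if d is None and m is None:
            updates[f"{k}_days"] = 0.0
            updates[f"{k}_min_per_day"] = 0.0
            flags.append(f"assume_zero_{k}")
        elif d is None or m is None:
            flags.append(f"incomplete_{k}")
            valid = False
    if raw.sitting_min_per_day is None:
        flags.append("missing_sitting")

    cleaned = replace(raw, **updates)

    # (1) 10-minute floor
    if rules.min_daily_minutes is not None:
        floored: dict[str, float] = {}
        for k in _INTENSITIES:
            m = cleaned.minutes(k)
            if m is not None and 0 < m < rules.min_daily_minutes:
                floored[f"{k}_min_per_day"] = 0.0
        if floored:
            cleaned = replace(cleaned, **floored)
            flags.append("min_10")

    # (2) daily-total validity cap, on pre-truncation minutes
    if rules.max_total_daily_minutes is not None:
        total = sum(cleaned.minutes(k) or 0.0 for k in _INTENSITIES)
        if total > rules.max_total_daily_minutes:
            flags.append("exceeds_960")
            valid = False

    # (3) 180-minute per-category truncation
    if rules.max_daily_minutes is not None:
        capped: dict[str, float] = {}
        for k in _INTENSITIES:
            m = cleaned.minutes(k)
            if m is not None and m > rules.max_daily_minutes:
                capped[f"{k}_min_per_day"] = float(rules.max_daily_minutes)
        if capped:
            cleaned = replace(cleaned, **capped)
            flags.append("truncate_180")

    return CleanedIpaq(
        response=cleaned, original=raw, cleaning_flags=tuple(flags), valid=valid
    )


def score_ipaq(cleaned: CleanedIpaq, met: MetValues = MetValues()) -> IpaqMeasures:
    """Score a cleaned, valid response into weekly measures.

    Weekly minutes per intensity are ``days_per_week x minutes_per_day``;
    overall activity is the MET-weighted sum of weekly hours; sedentary time
    is ``7 x sitting_minutes / 60`` hours per week.
    """
    if not cleaned.valid:
        raise ValueError(
            "cannot score an invalid response; cleaning flags: "
            + ", ".join(cleaned.cleaning_flags)
        )
    r = cleaned.response
    weekly_min = {k: float(r.days(k)) * float(r.minutes(k)) for k in _INTENSITIES}
    met_hours = (
        met.walking * weekly_min["walking"]
        + met.moderate * weekly_min["moderate"]
        + met.vigorous * weekly_min["vigorous"]
    ) / 60.0
    sitting = r.sitting_min_per_day
    return IpaqMeasures(
        walking_time_h=weekly_min["walking"] / 60.0,
        moderate_time_min=weekly_min["moderate"],
        vigorous_time_min=weekly_min["vigorous"],
        sedentary_time_h=(7.0 * sitting / 60.0) if sitting is not None else math.nan,
        active_time_h=sum(weekly_min.values()) / 60.0,
        met_hours=met_hours,
        valid=True,
        cleaning_flags=cleaned.cleaning_flags,
    )
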