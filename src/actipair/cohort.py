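"""Pair IPAQ recall windows with device weeks and attach outcomes.

An *activity observation* is a 7-day window that a participant recalled on
the IPAQ and for which the same 7 days have adequate device data.  The
recall window is anchored to the 7 days ending the day before the response
date.  BMI is attached from self-reported anthropometry using 90-day
(weight, BMI) and 365-day (height) windows around the window midpoint, with
calculated and self-reported BMI merged by their median; covariates come
from the closest questionnaire record within 365 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import CohortConfig
from .ipaq import IpaqMeasures
from .steps import DaySummary, FitbitWeekMeasures, summarize_week

logger = logging.getLogger(__name__)

DEMOGRAPHIC_FIELDS = ("age", "gender", "education", "income", "race", "ethnicity")
BEHAVIOR_FIELDS = ("smoking", "alcohol_drinks_wk")
CLINICAL_FIELDS = ("coronary_artery_disease", "diabetes", "hyperlipidemia", "hypertension")
COVARIATE_BLOCKS = {
    "demographics": DEMOGRAPHIC_FIELDS,
    "behaviors": BEHAVIOR_FIELDS,
    "clinical": CLINICAL_FIELDS,
}


@dataclass(frozen=True)
class AnthropometryReport:
    participant_id: str
    report_date: date
    height_m: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        for name in ("height_m", "weight_kg", "bmi"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class CovariateRecord:
    """Questionnaire covariates; any field may be missing (``None``)."""

    participant_id: str
    record_date: date
    age: float | None = None
    gender: str | None = None
    education: str | None = None
    income: str | None = None
    race: str | None = None
    ethnicity: str | None = None
    smoking: str | None = None
    alcohol_drinks_wk: float | None = None
    coronary_artery_disease: bool | None = None
    diabetes: bool | None = None
    hyperlipidemia: bool | None = None
    hypertension: bool | None = None


@dataclass(frozen=True)
class ScoredIpaq:
    """A scored IPAQ response with its recall anchor date."""

    participant_id: str
    response_date: date
    measures: IpaqMeasures


@dataclass
class ActivityObservation:
    """One paired 7-day window: device measures, self-report measures, and
    (optionally) BMI and covariates."""

    participant_id: str
    window_start: date
    fitbit: FitbitWeekMeasures
    ipaq: IpaqMeasures
    device_location: str | None = None  # "wrist" | "torso"
    data_source: str | None = None  # "tracker" | "mobiletrack"
    season: str | None = None
    bmi: float | None = None
    covariates: CovariateRecord | None = None
    observation_rank: int | None = None

    @property
    def window_end(self) -> date:
        """Last day of the window (inclusive)."""
        return self.window_start + timedelta(days=6)

    @property
    def window_midpoint(self) -> date:
        return self.window_start + timedelta(days=3)


def assign_season(window_start: date) -> str:
    """Meteorological season of the window midpoint month."""
    month = (window_start + timedelta(days=3)).month
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "fall"
    return "winter"


def build_observations(
    responses: list[ScoredIpaq],
    day_summaries: list[DaySummary],
    participant_meta: dict[str, dict] | None = None,
    config: CohortConfig = CohortConfig(),
) -> list[ActivityObservation]:
    """Emit an observation for every response whose 7-day recall window
    (the 7 days ending the day before the response date) has adequate
    device data on all 7 days.

    Duplicate responses from the same participant on the same date keep the
    first and log the rest.  ``observation_rank`` orders a participant's
    observations by window start date (1-based).
    """
    by_day: dict[tuple[str, date], DaySummary] = {}
    for d in day_summaries:
        by_day.setdefault((d.participant_id, d.date), d)

    seen: set[tuple[str, date]] = set()
    observations: list[ActivityObservation] = []
    for resp in responses:
        key = (resp.participant_id, resp.response_date)
        if key in seen:
            logger.info("duplicate IPAQ response dropped: %s %s", *key)
            continue
        seen.add(key)
        if not resp.measures.valid:
            continue
        window_start = resp.response_date - timedelta(days=7)
        days = [
            by_day.get((resp.participant_id, window_start + timedelta(days=i)))
            for i in range(7)
        ]
        if any(d is None for d in days):
            continue
        try:
            week = summarize_week(
                days,  # type: ignore[arg-type]
                min_adequate_days=config.min_adequate_days,
                rescale=config.rescale_partial_weeks,
            )
        except ValueError:
            continue
        meta = (participant_meta or {}).get(resp.participant_id, {})
        observations.append(
            ActivityObservation(
                participant_id=resp.participant_id,
                window_start=window_start,
                fitbit=week,
                ipaq=resp.measures,
                device_location=meta.get("device_location"),
                data_source=meta.get("data_source"),
                season=assign_season(window_start),
            )
        )

    observations.sort(key=lambda o: (o.participant_id, o.window_start))
    rank = 0
    prev_pid = None
    for obs in observations:
        rank = rank + 1 if obs.participant_id == prev_pid else 1
        obs.observation_rank = rank
        prev_pid = obs.participant_id
    return observations


def _mean_within(
    reports: list[AnthropometryReport],
    attr: str,
    reference: date,
    window_days: int,
) -> float | None:
    vals = [
        getattr(r, attr)
        for r in reports
        if getattr(r, attr) is not None
        and abs((r.report_date - reference).days) <= window_days
    ]
    return float(np.mean(vals)) if vals else None


def merge_bmi(
    obs: ActivityObservation,
    reports: list[AnthropometryReport],
    config: CohortConfig = CohortConfig(),
) -> float | None:
    """Attach BMI to an observation from anthropometry self-reports.

    Weights and directly reported BMI values within 90 days of the window
    midpoint are averaged; heights within 365 days are averaged.  A
    calculated BMI (weight / height^2) is merged with the averaged
    self-reported BMI by their median (for two values, the mean); if only
    one exists it is used; with neither, returns ``None``.
    """
    mine = [r for r in reports if r.participant_id == obs.participant_id]
    ref = obs.window_midpoint
    weight = _mean_within(mine, "weight_kg", ref, config.weight_window_days)
    height = _mean_within(mine, "height_m", ref, config.height_window_days)
    reported = _mean_within(mine, "bmi", ref, config.bmi_window_days)
    calculated = weight / height**2 if weight is not None and height is not None else None
    candidates = [v for v in (calculated, reported) if v is not None]
    if not candidates:
        return None
    return float(np.median(candidates))


def attach_covariates(
    obs: ActivityObservation,
    records: list[CovariateRecord],
    config: CohortConfig = CohortConfig(),
) -> ActivityObservation:
    """Attach covariates from questionnaire records near the observation.

    For each covariate block (demographics, behaviors, clinical) the record
    with all of the block's fields present and the smallest ``|record_date -
    window midpoint|`` within 365 days is chosen; equidistant ties go to the
    earlier record.  Absent data leave fields ``None``.
    """
    mine = [r for r in records if r.participant_id == obs.participant_id]
    ref = obs.window_midpoint
    merged: dict[str, object] = {}
    for block_fields in COVARIATE_BLOCKS.values():
        eligible = [
            r
            for r in mine
            if abs((r.record_date - ref).days) <= config.covariate_window_days
            and all(getattr(r, f) is not None for f in block_fields)
        ]
        if not eligible:
            continue
        best = min(
            eligible, key=lambda r: (abs((r.record_date - ref).days), r.record_date)
        )
        for f in block_fields:
            merged[f] = getattr(best, f)
    covariates = (
        CovariateRecord(participant_id=obs.participant_id, record_date=ref, **merged)
        if merged
        else None
    )
    obs.covariates = covariates
    return obs


def _covariates_complete(obs: ActivityObservation) -> bool:
    if obs.covariates is None:
        return False
    return all(
        getattr(obs.covariates, f) is not None
        for block in COVARIATE_BLOCKS.values()
        for f in block
    )


@dataclass
class AnalysisSets:
    """The two analysis datasets plus a first-observation view of the BMI set."""

    comparative: list[ActivityObservation]
    bmi_all: list[ActivityObservation]
    bmi_first: list[ActivityObservation]


def make_analysis_sets(observations: list[ActivityObservation]) -> AnalysisSets:
    """Split observations into the comparative set (first observation per
    participant) and the BMI set (every observation with BMI and complete
    covariates; participants may contribute several)."""
    comparative = [o for o in observations if o.observation_rank == 1]
    bmi_all = [o for o in observations if o.bmi is not None and _covariates_complete(o)]
    bmi_first = [o for o in bmi_all if o.observation_rank == 1]
    logger.info(
        "analysis sets: %d comparative, %d BMI observations (%d first)",
        len(comparative),
        len(bmi_all),
        len(bmi_first),
    )
    return AnalysisSets(comparative=comparative, bmi_all=bmi_all, bmi_first=bmi_first)


def observations_to_frame(observations: list[ActivityObservation]) -> pd.DataFrame:
    """Flatten observations into the analysis table the statistics modules
    consume (one row per observation)."""
    rows = []
    for o in observations:
        cov = o.covariates
        rows.append(
            {
                "participant_id": o.participant_id,
                "window_start": o.window_start,
                "observation_rank": o.observation_rank,
                "bmi": o.bmi,
                "wear_time": o.fitbit.wear_time_h_per_day,
                "device_location": o.device_location,
                "data_source": o.data_source,
                "season": o.season,
                "fitbit_steps_per_day": o.fitbit.steps_per_day,
                "fitbit_active_h": o.fitbit.active_time_h,
                "fitbit_sedentary_h": o.fitbit.sedentary_time_h,
                "fitbit_walking_h": o.fitbit.walking_time_h,
                "fitbit_moderate_h": o.fitbit.moderate_time_h,
                "fitbit_vigorous_h": o.fitbit.vigorous_time_h,
                "ipaq_met_h": o.ipaq.met_hours,
                "ipaq_active_h": o.ipaq.active_time_h,
                "ipaq_sedentary_h": o.ipaq.sedentary_time_h,
                "ipaq_walking_h": o.ipaq.walking_time_h,
                "ipaq_moderate_h": o.ipaq.moderate_time_h,
                "ipaq_vigorous_h": o.ipaq.vigorous_time_h,
                "age": cov.age if cov else None,
                "gender": cov.gender if cov else None,
                "education": cov.education if cov else None,
                "income": cov.income if cov else None,
                "race": cov.race if cov else None,
                "ethnicity": cov.ethnicity if cov else None,
                "smoking": cov.smoking if cov else None,
                "alcohol_drinks_wk": cov.alcohol_drinks_wk if cov else None,
                "coronary_artery_disease": cov.coronary_artery_disease if cov else None,
                "diabetes": cov.diabetes if cov else None,
                "hyperlipidemia": cov.hyperlipidemia if cov else None,
                "hypertension": cov.hypertension if cov else None,
            }
        )
    return pd.DataFrame(rows)
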