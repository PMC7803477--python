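"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: bout-structured
minute step traces with nonwear gaps and rare >200-step artifact minutes,
recall-biased IPAQ responses, Table-1-style covariates, anthropometry
reports, and a BMI outcome generated from configured per-intensity activity
effects.  Every draw flows from a single ``numpy.random.Generator`` so a
seed fully determines the output.

Two paths are provided:

* :func:`generate_cohort` builds full minute-level step series and the raw
  input tables the processing modules read — used for round-trip and
  calibration checks of the processing core.
* :func:`generate_weekly_cohort` draws the same weekly-level truth and
  measurement model directly into an analysis table — used for
  estimator-level simulation studies (parameter recovery, attenuation,
  error calibration) where re-synthesising millions of minutes would add
  nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import AnthropometryReport, CovariateRecord, assign_season
from .config import IpaqCleaningConfig, MetValues
from .ipaq import IpaqRawResponse, clean_ipaq, score_ipaq
from .steps import MINUTES_PER_DAY, Label, MinuteStepSeries

_WEEK = 7 * MINUTES_PER_DAY


def _default_recall_sd() -> dict[str, float]:
    return {"walking": 0.45, "moderate": 0.55, "vigorous": 0.55, "sitting": 0.40}


def _default_recall_bias() -> dict[str, float]:
    # reproduces the observed discrepancy direction: walking and sitting
    # under-reported, moderate and vigorous over-reported
    return {"walking": 0.17, "moderate": 1.2, "vigorous": 1.5, "sitting": 0.48}


def _default_recall_add() -> dict[str, float]:
    return {"walking": 0.0, "moderate": 0.0, "vigorous": 70.0, "sitting": 0.0}


def _default_bmi_effects() -> dict[str, float]:
    # kg/m2 per true hour/week at each intensity (fully adjusted scale)
    return {"sedentary": 0.08, "walking": -0.18, "moderate": -0.41, "vigorous": -0.84}


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the synthetic cohort.

    Defaults are calibrated to the printed activity distributions of the
    study population this pipeline targets: median overall activity near
    8600 steps/d with a between-participant SD near 3700, walking around
    20 h/wk, moderate activity around 75 min/wk, vigorous activity with a
    zero median, wear around 16 h/d, and self-report biased upward for
    moderate/vigorous and downward for walking/sitting.
    """

    n_participants: int = 586

    # --- weekly activity truth (minutes/week), lognormal between participants
    walking_median_min: float = 1212.0
    walking_log_sd: float = 0.30
    moderate_median_min: float = 75.0
    moderate_log_sd: float = 1.0
    vigorous_prob: float = 0.45
    vigorous_median_min: float = 14.0
    vigorous_log_sd: float = 1.4
    #: lognormal SD of a participant-level factor multiplying all intensities
    activity_factor_sd: float = 0.18
    #: lognormal SD of window-to-window jitter for repeat observations
    window_jitter_sd: float = 0.10

    # --- wear schedule (minutes/day)
    wear_mean_min: float = 960.0
    wear_between_sd: float = 55.0
    wear_within_sd: float = 25.0
    second_nonwear_prob: float = 0.35

    # --- cadence model: (mean, sd) of an in-bin truncated normal, steps/min
    walking_cadence: tuple[float, float] = (28.0, 18.0)
    moderate_cadence: tuple[float, float] = (115.0, 8.0)
    vigorous_cadence: tuple[float, float] = (150.0, 12.0)
    #: probability a worn sedentary minute registers exactly 0 steps
    sedentary_zero_prob: float = 0.55

    # --- bout structure (mean bout length in minutes)
    walking_bout_mean: float = 15.0
    moderate_bout_mean: float = 10.0
    vigorous_bout_mean: float = 8.0

    # --- device artifacts
    artifact_rate: float = 5e-4
    artifact_steps: tuple[int, int] = (201, 400)

    # --- recall (self-report) model
    recall_log_sd: dict[str, float] = field(default_factory=_default_recall_sd)
    recall_bias_mult: dict[str, float] = field(default_factory=_default_recall_bias)
    recall_bias_add: dict[str, float] = field(default_factory=_default_recall_add)
    #: discretize reports into days/week x integer minutes/day
    ipaq_discretize: bool = True

    #: lognormal SD of device measurement error in the weekly fast path
    #: (0 = device measures truth exactly, matching the minute-level path)
    device_log_sd: float = 0.0

    # --- BMI outcome model
    bmi_intercept: float = 24.0
    bmi_effects: dict[str, float] = field(default_factory=_default_bmi_effects)
    bmi_participant_sd: float = 3.0
    bmi_residual_sd: float = 3.3

    # --- cohort structure
    wrist_prob: float = 0.715
    mobiletrack_prob: float = 0.055
    repeat_obs_prob: float = 0.19

    # --- anthropometry reporting
    weight_report_sd: float = 0.7
    bmi_report_sd: float = 0.5
    bmi_selfreport_prob: float = 0.5

    #: cleaning rules used when scoring generated IPAQ responses
    ipaq_cleaning: IpaqCleaningConfig = field(default_factory=IpaqCleaningConfig)
    met_values: MetValues = field(default_factory=MetValues)


@dataclass
class SyntheticTruth:
    """Generator bookkeeping for one 7-day window (never fed to the
    pipeline; used by round-trip tests and sensitivity-count checks)."""

    participant_id: str
    window_start: date
    minute_labels: np.ndarray  # behaviour label of every minute (pre-artifact)
    weekly_min: dict[str, float]  # walking/moderate/vigorous/sedentary minutes
    wear_min_week: int
    nonwear_bouts: list[tuple[int, int]]
    artifact_indices: np.ndarray
    steps_total: float  # pre-artifact
    steps_per_day: float
    bmi: float | None = None
    device_location: str | None = None
    data_source: str | None = None

    @property
    def class_minutes(self) -> dict[Label, int]:
        counts = np.bincount(self.minute_labels, minlength=len(Label))
        return {lab: int(counts[lab]) for lab in Label}


@dataclass
class ParticipantTraits:
    """Participant-level latent quantities shared across repeat windows."""

    participant_id: str
    activity_factor: float
    walking_min: float
    moderate_min: float
    vigorous_min: float
    wear_mean: float
    device_location: str
    data_source: str
    height_m: float
    bmi_effect_u: float  # participant-level BMI residual
    covariates: dict


# ---------------------------------------------------------------------------
# participant traits and covariates
# ---------------------------------------------------------------------------

_EDUCATION = (["<bachelor", "bachelor", "postgraduate"], [0.25, 0.33, 0.42])
_INCOME = (["<50k", "50-100k", ">100k"], [0.17, 0.29, 0.54])
_RACE = (
    ["white", "asian", "black", "multiracial", "other"],
    [0.877, 0.032, 0.039, 0.029, 0.023],
)
_SMOKING = (["never", "past", "current"], [0.67, 0.29, 0.04])

_COVARIATE_BMI_EFFECTS = {
    "age_per_year": 0.03,  # centred at 52
    "female": -0.6,
    "smoking_past": 0.2,
    "smoking_current": 0.8,
    "alcohol_per_drink": -0.02,  # centred at 3
    "coronary_artery_disease": 0.5,
    "diabetes": 2.5,
    "hyperlipidemia": 0.4,
    "hypertension": 1.2,
}


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.clip(rng.normal(52.0, 13.6), 19, 92)),
        "gender": "female" if rng.random() < 0.60 else "male",
        "education": str(rng.choice(_EDUCATION[0], p=_EDUCATION[1])),
        "income": str(rng.choice(_INCOME[0], p=_INCOME[1])),
        "race": str(rng.choice(_RACE[0], p=_RACE[1])),
        "ethnicity": "hispanic" if rng.random() < 0.055 else "non-hispanic",
        "smoking": str(rng.choice(_SMOKING[0], p=_SMOKING[1])),
        "alcohol_drinks_wk": float(
            np.clip(np.round(rng.lognormal(np.log(3.0), 1.0)), 0, 40)
        ),
        "coronary_artery_disease": bool(rng.random() < 0.065),
        "diabetes": bool(rng.random() < 0.061),
        "hyperlipidemia": bool(rng.random() < 0.41),
        "hypertension": bool(rng.random() < 0.367),
    }


def _covariate_bmi_contribution(cov: dict) -> float:
    e = _COVARIATE_BMI_EFFECTS
    out = e["age_per_year"] * (cov["age"] - 52.0)
    out += e["female"] if cov["gender"] == "female" else 0.0
    out += {"never": 0.0, "past": e["smoking_past"], "current": e["smoking_current"]}[
        cov["smoking"]
    ]
    out += e["alcohol_per_drink"] * (cov["alcohol_drinks_wk"] - 3.0)
    for flag in ("coronary_artery_disease", "diabetes", "hyperlipidemia", "hypertension"):
        out += e[flag] if cov[flag] else 0.0
    return out


def draw_participant_traits(
    config: GeneratorConfig, rng: np.random.Generator, participant_id: str
) -> ParticipantTraits:
    factor = float(np.exp(rng.normal(0.0, config.activity_factor_sd)))
    walking = factor * rng.lognormal(np.log(config.walking_median_min), config.walking_log_sd)
    moderate = factor * rng.lognormal(
        np.log(config.moderate_median_min), config.moderate_log_sd
    )
    vigorous = 0.0
    if rng.random() < config.vigorous_prob:
        vigorous = factor * rng.lognormal(
            np.log(config.vigorous_median_min), config.vigorous_log_sd
        )
    return ParticipantTraits(
        participant_id=participant_id,
        activity_factor=factor,
        walking_min=float(walking),
        moderate_min=float(moderate),
        vigorous_min=float(vigorous),
        wear_mean=float(np.clip(rng.normal(config.wear_mean_min, config.wear_between_sd), 700, 1300)),
        device_location="wrist" if rng.random() < config.wrist_prob else "torso",
        data_source="mobiletrack" if rng.random() < config.mobiletrack_prob else "tracker",
        height_m=float(np.clip(rng.normal(1.70, 0.095), 1.45, 2.05)),
        bmi_effect_u=float(rng.normal(0.0, config.bmi_participant_sd)),
        covariates=_draw_covariates(rng),
    )


def _window_weekly_minutes(
    traits: ParticipantTraits, config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Integer weekly minute quotas for one window (participant base with
    window-level jitter, capped at feasible levels)."""
    j = config.window_jitter_sd

    def jitter(x: float) -> float:
        return x * np.exp(rng.normal(0.0, j)) if j > 0 else x

    # cap the lognormal tails at plausible weekly maxima (40 h walking,
    # 20 h moderate, ~6.7 h vigorous) so the linear BMI model stays in range
    walking = min(jitter(traits.walking_min), 2400.0)
    moderate = min(jitter(traits.moderate_min), 1200.0)
    vigorous = min(jitter(traits.vigorous_min), 400.0) if traits.vigorous_min > 0 else 0.0
    return {
        "walking": int(round(walking)),
        "moderate": int(round(moderate)),
        "vigorous": int(round(vigorous)),
    }


# ---------------------------------------------------------------------------
# minute-level assembly
# ---------------------------------------------------------------------------

def _split_over_days(total: int, rng: np.random.Generator) -> np.ndarray:
    base, rem = divmod(total, 7)
    out = np.full(7, base, dtype=int)
    if rem:
        out[rng.choice(7, size=rem, replace=False)] += 1
    return out


def _free_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.zeros(mask.size + 2, dtype=np.int8)
    padded[1:-1] = mask
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _place_bouts(
    labels: np.ndarray,
    label: Label,
    quota: int,
    mean_len: float,
    rng: np.random.Generator,
) -> int:
    """Carve activity bouts out of sedentary time; returns minutes placed."""
    placed = 0
    while placed < quota:
        runs = _free_runs(labels == Label.SEDENTARY)
        if not runs:
            break
        lengths = np.array([e - s for s, e in runs], dtype=float)
        run = runs[rng.choice(len(runs), p=lengths / lengths.sum())]
        want = min(quota - placed, max(1, int(rng.exponential(mean_len))))
        take = min(want, run[1] - run[0])
        start = run[0] + int(rng.integers(0, run[1] - run[0] - take + 1))
        labels[start : start + take] = label
        placed += take
    return placed


def generate_minute_series(
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_id: str,
    window_start: date,
    traits: ParticipantTraits | None = None,
) -> tuple[MinuteStepSeries, SyntheticTruth]:
    """Assemble one 7-day minute step series and its truth ledger.

    Each day gets a morning nonwear (sleep) block of at least 120 minutes,
    optionally a second one, activity bouts carved from the worn time, and a
    sedentary background of 0-9 step minutes.  The construction guarantees
    that the generated nonwear bouts are exactly the maximal zero runs of
    length >= 120 (sedentary zero-runs are broken below the threshold and
    bout flanks are forced nonzero), so processing recovers the truth ledger
    exactly when artifacts are disabled.
    """
    if traits is None:
        traits = draw_participant_traits(config, rng, participant_id)
    quotas = _window_weekly_minutes(traits, config, rng)

    labels = np.full(_WEEK, Label.SEDENTARY, dtype=np.int8)
    nonwear_bouts: list[tuple[int, int]] = []
    day_quota = {k: _split_over_days(v, rng) for k, v in quotas.items()}

    for d in range(7):
        off = d * MINUTES_PER_DAY
        wear = float(np.clip(rng.normal(traits.wear_mean, config.wear_within_sd), 620, 1440))
        nonwear_total = MINUTES_PER_DAY - int(round(wear))
        if nonwear_total < 120:
            nonwear_total = 0
        bouts: list[int] = []
        if nonwear_total:
            if nonwear_total >= 360 and rng.random() < config.second_nonwear_prob:
                b2 = int(rng.integers(120, nonwear_total - 240 + 1))
                bouts = [nonwear_total - b2, b2]
            else:
                bouts = [nonwear_total]
        day_labels = labels[off : off + MINUTES_PER_DAY]
        if bouts:
            day_labels[: bouts[0]] = Label.NONWEAR
            nonwear_bouts.append((off, off + bouts[0]))
            if len(bouts) == 2:
                b2 = bouts[1]
                s2 = int(rng.integers(bouts[0] + 30, MINUTES_PER_DAY - b2 - 30))
                day_labels[s2 : s2 + b2] = Label.NONWEAR
                nonwear_bouts.append((off + s2, off + s2 + b2))

        # keep a sliver of sedentary time so bouts never fill the day
        budget = int((day_labels == Label.SEDENTARY).sum()) - 20
        demand = sum(day_quota[k][d] for k in ("vigorous", "moderate", "walking"))
        if demand > budget > 0:
            scale = budget / demand
            for k in day_quota:
                day_quota[k][d] = int(day_quota[k][d] * scale)
        for k, lab, mean_len in (
            ("vigorous", Label.VIGOROUS, config.vigorous_bout_mean),
            ("moderate", Label.MODERATE, config.moderate_bout_mean),
            ("walking", Label.WALKING, config.walking_bout_mean),
        ):
            _place_bouts(day_labels, lab, day_quota[k][d], mean_len, rng)

    # --- assign steps
    steps = np.zeros(_WEEK, dtype=float)
    for lab, (mean, sd), (lo, hi) in (
        (Label.WALKING, config.walking_cadence, (10, 100)),
        (Label.MODERATE, config.moderate_cadence, (101, 130)),
        (Label.VIGOROUS, config.vigorous_cadence, (131, 200)),
    ):
        idx = np.flatnonzero(labels == lab)
        if idx.size:
            steps[idx] = np.clip(np.round(rng.normal(mean, sd, idx.size)), lo, hi)
    sed_idx = np.flatnonzero(labels == Label.SEDENTARY)
    sed_steps = rng.integers(1, 10, sed_idx.size).astype(float)
    sed_steps[rng.random(sed_idx.size) < config.sedentary_zero_prob] = 0.0
    steps[sed_idx] = sed_steps

    # --- guards: zero runs must be exactly the generated nonwear bouts
    for s, e in nonwear_bouts:
        if s > 0 and labels[s - 1] == Label.SEDENTARY and steps[s - 1] == 0:
            steps[s - 1] = 1.0
        if e < _WEEK and labels[e] == Label.SEDENTARY and steps[e] == 0:
            steps[e] = 1.0
    bout_set = set(nonwear_bouts)
    padded = np.zeros(_WEEK + 2, dtype=np.int8)
    padded[1:-1] = steps == 0
    edges = np.flatnonzero(np.diff(padded))
    for s, e in zip(edges[::2].tolist(), edges[1::2].tolist()):
        if (s, e) in bout_set or e - s < 120:
            continue
        steps[np.arange(s + 119, e, 120)] = 1.0

    steps_total = float(steps.sum())
    class_counts = np.bincount(labels, minlength=len(Label))
    weekly_min = {
        "walking": float(class_counts[Label.WALKING]),
        "moderate": float(class_counts[Label.MODERATE]),
        "vigorous": float(class_counts[Label.VIGOROUS]),
        "sedentary": float(class_counts[Label.SEDENTARY]),
    }

    # --- artifacts (recoded to missing downstream; applied to worn minutes)
    artifact_indices = np.array([], dtype=int)
    if config.artifact_rate > 0:
        worn = np.flatnonzero(labels != Label.NONWEAR)
        hit = worn[rng.random(worn.size) < config.artifact_rate]
        if hit.size:
            steps = steps.copy()
            lo, hi = config.artifact_steps
            steps[hit] = rng.integers(lo, hi + 1, hit.size).astype(float)
            artifact_indices = hit

    series = MinuteStepSeries(participant_id, window_start, steps)
    truth = SyntheticTruth(
        participant_id=participant_id,
        window_start=window_start,
        minute_labels=labels,
        weekly_min=weekly_min,
        wear_min_week=int(_WEEK - class_counts[Label.NONWEAR]),
        nonwear_bouts=nonwear_bouts,
        artifact_indices=artifact_indices,
        steps_total=steps_total,
        steps_per_day=steps_total / 7.0,
        device_location=traits.device_location,
        data_source=traits.data_source,
    )
    return series, truth


# ---------------------------------------------------------------------------
# self-report, outcome, covariates
# ---------------------------------------------------------------------------

def _reported_weekly(
    truth_weekly: float, key: str, config: GeneratorConfig, rng: np.random.Generator
) -> float:
    sd = config.recall_log_sd[key]
    noise = float(np.exp(rng.normal(-0.5 * sd**2, sd))) if sd > 0 else 1.0
    return max(
        0.0,
        (truth_weekly * config.recall_bias_mult[key] + config.recall_bias_add[key])
        * noise,
    )


def generate_ipaq(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    rng: np.random.Generator,
    response_date: date | None = None,
) -> IpaqRawResponse:
    """Produce a recall-biased IPAQ response for a window's truth.

    Reported weekly minutes are ``(truth x bias + additive bias) x
    mean-one lognormal noise``; with discretization on, reports are split
    into days/week and integer minutes/day as a respondent would give them.
    With all noise and bias at identity and discretization off, scoring the
    response returns the truth exactly.
    """
    if response_date is None:
        response_date = truth.window_start + timedelta(days=7)
    out: dict[str, float] = {}
    for key in ("walking", "moderate", "vigorous"):
        w = _reported_weekly(truth.weekly_min[key], key, config, rng)
        if config.ipaq_discretize:
            if w < 10.0:
                days, mins = 0.0, 0.0
            else:
                days = float(min(7, max(1, int(round(w / 45.0)))))
                mins = float(round(w / days))
        else:
            days, mins = 7.0, w / 7.0
        out[f"{key}_days"] = days
        out[f"{key}_min_per_day"] = mins
    sitting = _reported_weekly(truth.weekly_min["sedentary"], "sitting", config, rng) / 7.0
    if config.ipaq_discretize:
        sitting = float(round(sitting))
    return IpaqRawResponse(
        participant_id=truth.participant_id,
        response_date=response_date,
        sitting_min_per_day=sitting,
        **out,
    )


def generate_outcome_and_covariates(
    truth: SyntheticTruth,
    traits: ParticipantTraits,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float, CovariateRecord, list[AnthropometryReport]]:
    """BMI from the window's true activity plus covariate effects, the
    covariate questionnaire record, and anthropometry self-reports placed
    inside the attachment windows."""
    hours = {k: truth.weekly_min[k] / 60.0 for k in truth.weekly_min}
    bmi = config.bmi_intercept + sum(
        config.bmi_effects[k] * hours[k] for k in config.bmi_effects
    )
    bmi += _covariate_bmi_contribution(traits.covariates)
    # strictly linear (no censoring): parameter-recovery studies assume a
    # correctly specified outcome model; the capped activity tails keep
    # values in a plausible range
    bmi += traits.bmi_effect_u + float(rng.normal(0.0, config.bmi_residual_sd))
    truth.bmi = float(bmi)

    mid = truth.window_start + timedelta(days=3)
    cov = CovariateRecord(
        participant_id=truth.participant_id,
        record_date=mid - timedelta(days=int(rng.integers(0, 200))),
        **traits.covariates,
    )
    reports = [
        AnthropometryReport(
            participant_id=truth.participant_id,
            report_date=mid + timedelta(days=int(rng.integers(-300, 301))),
            height_m=float(traits.height_m + rng.normal(0.0, 0.005)),
        ),
        AnthropometryReport(
            participant_id=truth.participant_id,
            report_date=mid + timedelta(days=int(rng.integers(-60, 61))),
            weight_kg=float(
                max(30.0, bmi * traits.height_m**2 + rng.normal(0.0, config.weight_report_sd))
            ),
        ),
    ]
    if rng.random() < config.bmi_selfreport_prob:
        reports.append(
            AnthropometryReport(
                participant_id=truth.participant_id,
                report_date=mid + timedelta(days=int(rng.integers(-60, 61))),
                bmi=float(max(12.0, bmi + rng.normal(0.0, config.bmi_report_sd))),
            )
        )
    return bmi, cov, reports


# ---------------------------------------------------------------------------
# full bundles
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything the pipeline reads, plus the truth ledger kept apart."""

    series: list[MinuteStepSeries]
    ipaq_responses: list[IpaqRawResponse]
    anthropometry: list[AnthropometryReport]
    covariates: list[CovariateRecord]
    participant_meta: dict[str, dict]
    truths: list[SyntheticTruth]
    config: GeneratorConfig


def generate_cohort(config: GeneratorConfig, seed: int) -> CohortBundle:
    """Generate a full minute-level cohort, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    series: list[MinuteStepSeries] = []
    responses: list[IpaqRawResponse] = []
    anthropometry: list[AnthropometryReport] = []
    covariates: list[CovariateRecord] = []
    truths: list[SyntheticTruth] = []
    meta: dict[str, dict] = {}
    origin = date(2016, 1, 1)

    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        traits = draw_participant_traits(config, rng, pid)
        meta[pid] = {
            "device_location": traits.device_location,
            "data_source": traits.data_source,
        }
        n_windows = 1 + int(rng.random() < config.repeat_obs_prob)
        start = origin + timedelta(days=int(rng.integers(0, 1095)))
        for w in range(n_windows):
            s, truth = generate_minute_series(config, rng, pid, start, traits)
            series.append(s)
            truths.append(truth)
            responses.append(generate_ipaq(truth, config, rng))
            _, cov, reports = generate_outcome_and_covariates(truth, traits, config, rng)
            covariates.append(cov)
            anthropometry.extend(reports)
            start = start + timedelta(days=int(rng.integers(30, 121)))
    return CohortBundle(
        series=series,
        ipaq_responses=responses,
        anthropometry=anthropometry,
        covariates=covariates,
        participant_meta=meta,
        truths=truths,
        config=config,
    )


def generate_weekly_cohort(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Draw the weekly-level truth and measurement model directly into an
    analysis table (one row per observation).

    Columns match :func:`actipair.cohort.observations_to_frame`, plus
    ``truth_*`` columns carrying the generating quantities.  Device-side
    measures equal the truth times mean-one lognormal noise with SD
    ``device_log_sd`` (0 by default, mirroring the minute-level path where
    processing recovers truth exactly); self-report measures are produced by
    :func:`generate_ipaq` and scored through the real cleaning/scoring code.
    """
    rng = np.random.default_rng(seed)
    cadence_mean = {
        "walking": _clipped_normal_mean(*config.walking_cadence, 10, 100),
        "moderate": _clipped_normal_mean(*config.moderate_cadence, 101, 130),
        "vigorous": _clipped_normal_mean(*config.vigorous_cadence, 131, 200),
    }
    sed_mean_steps = (1.0 - config.sedentary_zero_prob) * 5.0
    origin = date(2016, 1, 1)
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        traits = draw_participant_traits(config, rng, pid)
        n_windows = 1 + int(rng.random() < config.repeat_obs_prob)
        start = origin + timedelta(days=int(rng.integers(0, 1095)))
        for w in range(n_windows):
            q = _window_weekly_minutes(traits, config, rng)
            wear_week = float(
                np.clip(
                    rng.normal(traits.wear_mean, config.wear_within_sd / np.sqrt(7)),
                    620,
                    1440,
                )
                * 7
            )
            sed_min = max(0.0, wear_week - sum(q.values()))
            weekly = {**{k: float(v) for k, v in q.items()}, "sedentary": sed_min}
            steps_day = (
                sum(weekly[k] * cadence_mean[k] for k in cadence_mean)
                + sed_min * sed_mean_steps
            ) / 7.0

            truth = SyntheticTruth(
                participant_id=pid,
                window_start=start,
                minute_labels=np.array([], dtype=np.int8),
                weekly_min=weekly,
                wear_min_week=int(wear_week),
                nonwear_bouts=[],
                artifact_indices=np.array([], dtype=int),
                steps_total=steps_day * 7,
                steps_per_day=steps_day,
                device_location=traits.device_location,
                data_source=traits.data_source,
            )
            bmi, cov, _ = generate_outcome_and_covariates(truth, traits, config, rng)

            def measured(x: float) -> float:
                sd = config.device_log_sd
                return x * float(np.exp(rng.normal(-0.5 * sd**2, sd))) if sd > 0 else x

            raw = generate_ipaq(truth, config, rng)
            cleaned = clean_ipaq(raw, config.ipaq_cleaning)
            scored = score_ipaq(cleaned, config.met_values) if cleaned.valid else None

            rows.append(
                {
                    "participant_id": pid,
                    "window_start": start,
                    "observation_rank": w + 1,
                    "bmi": bmi,
                    "wear_time": wear_week / 7.0 / 60.0,
                    "device_location": traits.device_location,
                    "data_source": traits.data_source,
                    "season": assign_season(start),
                    "fitbit_steps_per_day": measured(steps_day),
                    "fitbit_active_h": measured(
                        (weekly["walking"] + weekly["moderate"] + weekly["vigorous"]) / 60.0
                    ),
                    "fitbit_sedentary_h": measured(sed_min / 60.0),
                    "fitbit_walking_h": measured(weekly["walking"] / 60.0),
                    "fitbit_moderate_h": measured(weekly["moderate"] / 60.0),
                    "fitbit_vigorous_h": measured(weekly["vigorous"] / 60.0),
                    "ipaq_met_h": scored.met_hours if scored else np.nan,
                    "ipaq_active_h": scored.active_time_h if scored else np.nan,
                    "ipaq_sedentary_h": scored.sedentary_time_h if scored else np.nan,
                    "ipaq_walking_h": scored.walking_time_h if scored else np.nan,
                    "ipaq_moderate_h": scored.moderate_time_h if scored else np.nan,
                    "ipaq_vigorous_h": scored.vigorous_time_h if scored else np.nan,
                    **traits.covariates,
                    "truth_steps_per_day": steps_day,
                    "truth_walking_h": weekly["walking"] / 60.0,
                    "truth_moderate_h": weekly["moderate"] / 60.0,
                    "truth_vigorous_h": weekly["vigorous"] / 60.0,
                    "truth_sedentary_h": sed_min / 60.0,
                    "truth_active_h": (
                        weekly["walking"] + weekly["moderate"] + weekly["vigorous"]
                    )
                    / 60.0,
                }
            )
            start = start + timedelta(days=int(rng.integers(30, 121)))
    return pd.DataFrame(rows)


def _clipped_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of a normal draw clipped to [lo, hi] — the cadence model the
    minute-level path uses."""
    from scipy.stats import norm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mean * (norm.cdf(b) - norm.cdf(a))
        - sd * (norm.pdf(b) - norm.pdf(a))
    )
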