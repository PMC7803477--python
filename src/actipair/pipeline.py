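"""End-to-end convenience: raw inputs -> analysis table.

Chains minute-step processing, IPAQ cleaning/scoring, observation pairing,
and BMI/covariate attachment into a single call, so a full study run is::

    bundle = simulate.generate_cohort(config, seed)   # or io readers
    sets = pipeline.assemble(bundle.series, bundle.ipaq_responses,
                             bundle.anthropometry, bundle.covariates,
                             bundle.participant_meta)
    frame = cohort.observations_to_frame(sets.bmi_all)
"""

from __future__ import annotations

from .cohort import (
    ActivityObservation,
    AnalysisSets,
    AnthropometryReport,
    CovariateRecord,
    ScoredIpaq,
    attach_covariates,
    build_observations,
    make_analysis_sets,
    merge_bmi,
)
from .config import CohortConfig, IpaqCleaningConfig, MetValues, StepConfig
from .ipaq import IpaqRawResponse, clean_ipaq, score_ipaq
from .steps import DaySummary, MinuteStepSeries, process_series


def score_responses(
    responses: list[IpaqRawResponse],
    cleaning: IpaqCleaningConfig = IpaqCleaningConfig(),
    met: MetValues = MetValues(),
) -> list[ScoredIpaq]:
    """Clean and score raw IPAQ responses; invalid responses are kept with
    ``valid=False`` measures so observation building can drop them."""
    out = []
    for raw in responses:
        cleaned = clean_ipaq(raw, cleaning)
        if cleaned.valid:
            measures = score_ipaq(cleaned, met)
        else:
            from .ipaq import IpaqMeasures
            import math

            measures = IpaqMeasures(
                walking_time_h=math.nan,
                moderate_time_min=math.nan,
                vigorous_time_min=math.nan,
                sedentary_time_h=math.nan,
                active_time_h=math.nan,
                met_hours=math.nan,
                valid=False,
                cleaning_flags=cleaned.cleaning_flags,
            )
        out.append(ScoredIpaq(raw.participant_id, raw.response_date, measures))
    return out


def assemble(
    series: list[MinuteStepSeries],
    responses: list[IpaqRawResponse],
    anthropometry: list[AnthropometryReport],
    covariates: list[CovariateRecord],
    participant_meta: dict[str, dict] | None = None,
    step_config: StepConfig = StepConfig(),
    cleaning: IpaqCleaningConfig = IpaqCleaningConfig(),
    met: MetValues = MetValues(),
    cohort_config: CohortConfig = CohortConfig(),
) -> AnalysisSets:
    """Run the full assembly and return the analysis sets."""
    day_summaries: list[DaySummary] = []
    for s in series:
        day_summaries.extend(process_series(s, step_config))
    scored = score_responses(responses, cleaning, met)
    observations = build_observations(
        scored, day_summaries, participant_meta, cohort_config
    )
    for obs in observations:
        obs.bmi = merge_bmi(obs, anthropometry, cohort_config)
        attach_covariates(obs, covariates, cohort_config)
    return make_analysis_sets(observations)
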