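"""Configuration objects shared across the pipeline.

Every threshold the processing rules depend on lives here so that alternative
policies (different nonwear run lengths, cadence bins, IPAQ cleaning rules,
MET multipliers) can be swapped in without touching the algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StepConfig:
    """Thresholds for minute-level step processing.

    Parameters
    ----------
    spurious_step_threshold:
        Minutes with strictly more steps than this are recoded as missing
        (device artifact).  Default 200 steps/min.
    nonwear_min_run:
        Minimum length, in minutes, of a contiguous all-zero run that counts
        as nonwear.  Default 120.
    adequate_wear_minutes:
        Minimum daily wear time for the day to be analysable (default 600,
        i.e. 10 h).
    sedentary_max_steps, walking_range, moderate_range, vigorous_range:
        Closed integer cadence bins (steps/min) defining intensity classes.
    long_low_bouts:
        How to classify worn minutes with 0-9 steps that sit inside a run of
        low-step minutes lasting at least ``nonwear_min_run``:
        ``"sedentary"`` (default) labels every worn low-step minute sedentary
        and reserves the 120-min exclusion for all-zero runs; ``"nonwear"``
        treats such long low-step runs as nonwear as well.
    """

    spurious_step_threshold: int = 200
    nonwear_min_run: int = 120
    adequate_wear_minutes: int = 600
    sedentary_max_steps: int = 9
    walking_range: tuple[int, int] = (10, 100)
    moderate_range: tuple[int, int] = (101, 130)
    vigorous_range: tuple[int, int] = (131, 200)
    long_low_bouts: str = "sedentary"

    def __post_init__(self) -> None:
        if self.long_low_bouts not in ("sedentary", "nonwear"):
            raise ValueError(
                "long_low_bouts must be 'sedentary' or 'nonwear', got "
                f"{self.long_low_bouts!r}"
            )
        lo, hi = self.walking_range
        if not (self.sedentary_max_steps + 1 == lo <= hi):
            raise ValueError("walking_range must start just above sedentary_max_steps")


@dataclass(frozen=True)
class IpaqCleaningConfig:
    """IPAQ short-form cleaning rules (scoring-protocol defaults).

    ``min_daily_minutes`` recodes sub-threshold episodes to zero,
    ``max_daily_minutes`` truncates each category, and
    ``max_total_daily_minutes`` invalidates responses whose summed daily
    activity (walking + moderate + vigorous, evaluated before truncation)
    exceeds the cap.  Set a rule to ``None`` to disable it.
    """

    min_daily_minutes: float | None = 10.0
    max_daily_minutes: float | None = 180.0
    max_total_daily_minutes: float | None = 960.0


@dataclass(frozen=True)
class MetValues:
    """MET multipliers used to convert weekly hours to MET-h/wk."""

    walking: float = 3.3
    moderate: float = 4.0
    vigorous: float = 8.0


@dataclass(frozen=True)
class CohortConfig:
    """Rules for pairing recall windows with device data and attaching
    anthropometry and covariates."""

    #: number of adequate days (out of 7) required to emit an observation
    min_adequate_days: int = 7
    #: when fewer than 7 days are adequate but >= min_adequate_days, rescale
    #: weekly sums from the adequate days (off by default)
    rescale_partial_weeks: bool = False
    weight_window_days: int = 90
    bmi_window_days: int = 90
    height_window_days: int = 365
    covariate_window_days: int = 365
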