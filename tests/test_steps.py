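"""Minute-step processing: cadence bins, nonwear detection, day and week
summaries, checked against independent brute-force re-derivations."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actipair.config import StepConfig
from actipair.steps import (
    MINUTES_PER_DAY,
    Label,
    MinuteStepSeries,
    classify_minutes,
    detect_nonwear,
    process_series,
    recode_spurious_minutes,
    summarize_day,
    summarize_week,
)
from conftest import make_series, random_blocky_series

CFG = StepConfig()


# --- independent oracles ----------------------------------------------------

def brute_nonwear(steps, min_run=120):
    """O(n) scan over maximal zero runs, written independently of the
    vectorized implementation."""
    out, start = [], None
    for i, v in enumerate(steps):
        if v == 0:  # NaN compares False
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                out.append((start, i))
            start = None
    if start is not None and len(steps) - start >= min_run:
        out.append((start, len(steps)))
    return out


def brute_classify(steps, min_run=120):
    """Per-minute lookup after masking brute-force nonwear intervals."""
    labels = []
    nonwear = set()
    for s, e in brute_nonwear(steps, min_run):
        nonwear.update(range(s, e))
    for i, v in enumerate(steps):
        if i in nonwear:
            labels.append(Label.NONWEAR)
        elif np.isnan(v):
            labels.append(Label.MISSING)
        elif v <= 9:
            labels.append(Label.SEDENTARY)
        elif v <= 100:
            labels.append(Label.WALKING)
        elif v <= 130:
            labels.append(Label.MODERATE)
        else:
            labels.append(Label.VIGOROUS)
    return np.array(labels, dtype=np.int8)


# --- recoding ---------------------------------------------------------------

def test_recode_spurious_boundary():
    s = make_series([250, 200, 201, 199, 0])
    r = recode_spurious_minutes(s)
    assert np.isnan(r.steps[0])
    assert r.steps[1] == 200  # 200 is not "more than 200"
    assert np.isnan(r.steps[2])
    assert r.steps[3] == 199


def test_recode_identity_on_clean_series():
    s = make_series(np.zeros(MINUTES_PER_DAY))
    r = recode_spurious_minutes(s)
    assert np.array_equal(r.steps, s.steps)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=200))
def test_recode_idempotent(values):
    s = make_series(values)
    once = recode_spurious_minutes(s)
    twice = recode_spurious_minutes(once)
    assert np.array_equal(once.steps, twice.steps, equal_nan=True)


# --- nonwear ----------------------------------------------------------------

def test_run_of_119_zeros_is_not_nonwear():
    steps = np.ones(MINUTES_PER_DAY)
    steps[100:219] = 0  # 119 zeros flanked by nonzero
    assert detect_nonwear(make_series(steps)) == []


def test_run_of_120_zeros_is_one_interval():
    steps = np.ones(MINUTES_PER_DAY)
    steps[100:220] = 0
    assert detect_nonwear(make_series(steps)) == [(100, 220)]


def test_nonwear_run_spans_midnight():
    steps = np.ones(2 * MINUTES_PER_DAY)
    steps[1380:1500] = 0  # 60 min each side of midnight
    assert detect_nonwear(make_series(steps)) == [(1380, 1500)]


def test_nonwear_zero_insertion_monotone():
    steps = np.ones(MINUTES_PER_DAY)
    steps[100:230] = 0
    base = sum(e - s for s, e in detect_nonwear(make_series(steps)))
    steps2 = steps.copy()
    steps2[230:260] = 0  # extend the run
    grown = sum(e - s for s, e in detect_nonwear(make_series(steps2)))
    assert grown >= base


def test_nonwear_matches_bruteforce_on_random_series(rng):
    for _ in range(300):
        s = random_blocky_series(rng, n_days=3, missing=True)
        assert detect_nonwear(s) == brute_nonwear(s.steps)


# --- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "steps,label",
    [
        (9, Label.SEDENTARY),
        (10, Label.WALKING),
        (100, Label.WALKING),
        (101, Label.MODERATE),
        (130, Label.MODERATE),
        (131, Label.VIGOROUS),
        (200, Label.VIGOROUS),
        (201, Label.MISSING),
    ],
)
def test_cadence_bin_boundaries(steps, label):
    arr = np.ones(MINUTES_PER_DAY)
    arr[10] = steps
    s = recode_spurious_minutes(make_series(arr))
    assert classify_minutes(s).labels[10] == label


def test_low_steps_in_short_bout_are_sedentary():
    arr = np.ones(MINUTES_PER_DAY)
    arr[100:160] = 0
    arr[130] = 5  # 5 steps inside a 60-minute low bout
    labels = classify_minutes(make_series(arr)).labels
    assert labels[130] == Label.SEDENTARY
    assert labels[131] == Label.SEDENTARY


def test_unrecoded_spurious_value_raises():
    arr = np.ones(MINUTES_PER_DAY)
    arr[5] = 300
    with pytest.raises(ValueError, match="spurious"):
        classify_minutes(make_series(arr))


def test_classification_matches_bruteforce_on_random_series(rng):
    for _ in range(200):
        s = random_blocky_series(rng, n_days=2, missing=True, spurious=True)
        s = recode_spurious_minutes(s)
        assert np.array_equal(classify_minutes(s).labels, brute_classify(s.steps))


def test_long_low_bout_alternative_config():
    """With the alternative policy, a >=120-min run of 0-9 step minutes
    containing nonzero minutes becomes nonwear instead of sedentary."""
    arr = np.full(MINUTES_PER_DAY, 50.0)
    arr[100:230] = 3  # 130 min of low-but-nonzero steps
    default = classify_minutes(make_series(arr))
    assert default.labels[150] == Label.SEDENTARY
    alt = classify_minutes(make_series(arr), StepConfig(long_low_bouts="nonwear"))
    assert alt.labels[150] == Label.NONWEAR


# --- day and week summaries -------------------------------------------------

def _day_with_wear(wear_minutes):
    arr = np.ones(MINUTES_PER_DAY)
    arr[: MINUTES_PER_DAY - wear_minutes] = 0  # one long nonwear run
    s = make_series(arr)
    return summarize_day(s, classify_minutes(s), 0)


def test_day_adequacy_threshold():
    assert _day_with_wear(599).adequate is False
    assert _day_with_wear(600).adequate is True


def test_all_missing_day_is_empty_and_inadequate():
    s = MinuteStepSeries("P", date(2017, 1, 1), np.full(MINUTES_PER_DAY, np.nan))
    d = summarize_day(s, classify_minutes(s), 0)
    assert d.wear_minutes == 0 and not d.adequate
    assert d.steps_total == 0
    assert all(
        d.minutes_by_class[lab] == 0 for lab in Label if lab is not Label.MISSING
    )


def test_day_index_out_of_range():
    s = make_series(np.ones(MINUTES_PER_DAY))
    with pytest.raises(IndexError):
        summarize_day(s, classify_minutes(s), 1)


def test_week_of_constant_days():
    arr = np.zeros(7 * MINUTES_PER_DAY)
    for d in range(7):
        # 1000 active minutes of 10 steps each = 10,000 steps/day
        arr[d * MINUTES_PER_DAY : d * MINUTES_PER_DAY + 1000] = 10
    s = make_series(arr)
    days = process_series(s)
    wk = summarize_week(days)
    assert wk.steps_per_day == 10_000
    assert wk.n_adequate_days == 7


def test_week_minute_conservation(rng):
    s = random_blocky_series(rng, n_days=7, missing=True, spurious=True)
    s = recode_spurious_minutes(s)
    c = classify_minutes(s)
    total = sum(c.minutes_of(lab) for lab in Label)
    assert total == 7 * MINUTES_PER_DAY


def test_week_matches_direct_aggregation(rng):
    """Weekly measures equal an independent aggregation straight from the
    minute labels, bypassing DaySummary."""
    for _ in range(20):
        s = random_blocky_series(rng, n_days=7, missing=True)
        # force adequacy: add activity so wear >= 600 every day
        steps = s.steps.copy()
        for d in range(7):
            steps[d * MINUTES_PER_DAY : d * MINUTES_PER_DAY + 700] = rng.integers(
                10, 100, 700
            )
        s = MinuteStepSeries("R", s.start_date, steps)
        days = process_series(s)
        wk = summarize_week(days)
        labels = classify_minutes(s).labels
        assert wk.steps_per_day == pytest.approx(np.nansum(s.steps) / 7)
        assert wk.walking_time_h * 60 == pytest.approx(
            np.count_nonzero(labels == Label.WALKING)
        )
        assert wk.moderate_time_min == np.count_nonzero(labels == Label.MODERATE)
        assert wk.vigorous_time_min == np.count_nonzero(labels == Label.VIGOROUS)
        assert wk.sedentary_time_h * 60 == pytest.approx(
            np.count_nonzero(labels == Label.SEDENTARY)
        )
        assert wk.active_time_h * 60 == pytest.approx(
            wk.walking_time_h * 60 + wk.moderate_time_min + wk.vigorous_time_min
        )


def test_week_requires_seven_adequate_days():
    arr = np.ones(7 * MINUTES_PER_DAY)
    arr[:900] = 0  # day 0 wear = 540 < 600
    days = process_series(make_series(arr))
    assert not days[0].adequate
    with pytest.raises(ValueError):
        summarize_week(days)
    with pytest.raises(ValueError):
        summarize_week(days[:6])
    # rescaling path: 6 adequate days scaled by 7/6
    wk = summarize_week(days, min_adequate_days=6, rescale=True)
    assert wk.n_adequate_days == 6
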