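from datetime import date

import numpy as np
import pytest

from actipair.steps import MINUTES_PER_DAY, MinuteStepSeries


def make_series(steps, participant_id="P1", start=date(2017, 5, 1)):
    """Pad a step vector with trailing zeros to whole days and wrap it."""
    steps = np.asarray(steps, dtype=float)
    pad = (-steps.size) % MINUTES_PER_DAY
    if pad:
        steps = np.concatenate([steps, np.zeros(pad)])
    return MinuteStepSeries(participant_id, start, steps)


def random_blocky_series(rng, n_days=3, missing=False, spurious=False):
    """Block-structured random series: alternating zero runs and active
    runs, so nonwear-length zero runs actually occur."""
    n = n_days * MINUTES_PER_DAY
    steps = np.empty(0)
    while steps.size < n:
        if rng.random() < 0.5:
            block = np.zeros(int(rng.integers(1, 300)))
        else:
            block = rng.integers(0, 201, int(rng.integers(1, 200))).astype(float)
        steps = np.concatenate([steps, block])
    steps = steps[:n]
    if missing:
        steps[rng.random(n) < 0.01] = np.nan
    if spurious:
        idx = rng.random(n) < 0.005
        steps[idx] = rng.integers(201, 500, int(idx.sum()))
    return MinuteStepSeries("R", date(2018, 1, 1), steps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
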