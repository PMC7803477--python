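"""Process one week of minute-level step counts into weekly activity measures.

Builds a synthetic 7-day minute trace, recodes artifact minutes, detects
nonwear, classifies each minute by cadence, and prints the day and week
summaries.
"""

from datetime import date

import numpy as np

from actipair import (
    GeneratorConfig,
    detect_nonwear,
    process_series,
    recode_spurious_minutes,
    summarize_week,
)
from actipair.simulate import generate_minute_series

rng = np.random.default_rng(7)
series, truth = generate_minute_series(
    GeneratorConfig(), rng, participant_id="demo", window_start=date(2018, 4, 2)
)

recoded = recode_spurious_minutes(series)
bouts = detect_nonwear(recoded)
print(f"nonwear bouts detected: {len(bouts)} "
      f"(total {sum(e - s for s, e in bouts)} min over the week)")

days = process_series(series)
for d in days:
    print(
        f"  {d.date}  wear {d.wear_minutes:4d} min  steps {d.steps_total:7.0f}  "
        f"adequate={d.adequate}"
    )

week = summarize_week(days)
print(
    f"\nweekly measures: {week.steps_per_day:.0f} steps/d | "
    f"active {week.active_time_h:.1f} h/wk | walking {week.walking_time_h:.1f} h/wk | "
    f"moderate {week.moderate_time_min:.0f} min/wk | vigorous {week.vigorous_time_min:.0f} min/wk | "
    f"sedentary {week.sedentary_time_h:.1f} h/wk | wear {week.wear_time_h_per_day:.1f} h/d"
)
print(
    "Each minute was classed by cadence (sedentary 0-9, walking 10-100, "
    "moderate 101-130, vigorous 131-200 steps/min); a day counts when worn >= 10 h."
)
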