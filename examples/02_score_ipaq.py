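"""Clean and score an IPAQ short-form response.

Shows the scoring-protocol cleaning rules (10-minute floor, 180-minute/day
truncation, 960-minute/day validity cap) and the MET-weighted weekly
summary.
"""

from datetime import date

from actipair import IpaqRawResponse, clean_ipaq, score_ipaq

raw = IpaqRawResponse(
    participant_id="demo",
    response_date=date(2018, 4, 9),
    vigorous_days=3,
    vigorous_min_per_day=60,
    moderate_days=5,
    moderate_min_per_day=30,
    walking_days=7,
    walking_min_per_day=250,  # implausibly high; truncated to 180
    sitting_min_per_day=420,
)

cleaned = clean_ipaq(raw)
print("cleaning flags:", cleaned.cleaning_flags)
print("walking min/day:", raw.walking_min_per_day, "->", cleaned.response.walking_min_per_day)

m = score_ipaq(cleaned)
print(
    f"\nscored: walking {m.walking_time_h:.1f} h/wk | moderate {m.moderate_time_min:.0f} min/wk | "
    f"vigorous {m.vigorous_time_min:.0f} min/wk | sitting {m.sedentary_time_h:.0f} h/wk"
)
print(f"overall activity: {m.met_hours:.1f} MET-h/wk "
      "(3.3 MET walking, 4.0 moderate, 8.0 vigorous, per weekly hour)")
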