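"""Delimited-text readers and writers for the pipeline's external formats.

All inputs and outputs are plain CSV: minute-step tables
(``participant_id,timestamp,steps``), IPAQ responses, anthropometry
reports, covariate questionnaires, and the assembled analysis tables.
Step-table gaps are pre-filled with missing minutes so every series covers
whole calendar days on a strict 1-minute grid.
"""

from __future__ import annotations

from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ActivityObservation, AnthropometryReport, CovariateRecord
from .ipaq import IpaqRawResponse
from .steps import MINUTES_PER_DAY, MinuteStepSeries

IPAQ_COLUMNS = [
    "participant_id",
    "response_date",
    "walking_days",
    "walking_min_per_day",
    "moderate_days",
    "moderate_min_per_day",
    "vigorous_days",
    "vigorous_min_per_day",
    "sitting_min_per_day",
]


def read_step_table(path: str | Path) -> list[MinuteStepSeries]:
    """Read a minute-step table; one series per participant, padded to whole
    calendar days with missing minutes filling feed gaps."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out: list[MinuteStepSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = grp["timestamp"].dt.floor("min")
        if ts.duplicated().any():
            raise ValueError(f"{pid}: duplicate timestamps in step table")
        start = ts.iloc[0].normalize()
        end = (ts.iloc[-1].normalize() + pd.Timedelta(days=1))
        index = pd.date_range(start, end, freq="min", inclusive="left")
        steps = grp.set_index(ts)["steps"].astype(float).reindex(index)
        assert steps.size % MINUTES_PER_DAY == 0
        out.append(MinuteStepSeries(str(pid), start.date(), steps.to_numpy()))
    return out


def write_step_table(series_list: list[MinuteStepSeries], path: str | Path) -> None:
    """Write series as long-format CSV, omitting missing minutes (readers
    restore them as gaps)."""
    frames = []
    for s in series_list:
        index = pd.date_range(
            datetime.combine(s.start_date, datetime.min.time()),
            periods=s.steps.size,
            freq="min",
        )
        present = ~np.isnan(s.steps)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": index[present],
                    "steps": s.steps[present].astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ipaq_table(path: str | Path) -> list[IpaqRawResponse]:
    df = pd.read_csv(path, parse_dates=["response_date"])
    out = []
    for _, row in df.iterrows():
        kwargs = {
            c: (None if pd.isna(row[c]) else float(row[c]))
            for c in IPAQ_COLUMNS[2:]
        }
        out.append(
            IpaqRawResponse(
                participant_id=str(row["participant_id"]),
                response_date=row["response_date"].date(),
                **kwargs,
            )
        )
    return out


def write_ipaq_table(responses: list[IpaqRawResponse], path: str | Path) -> None:
    pd.DataFrame(
        [
            {c: getattr(r, c) for c in IPAQ_COLUMNS}
            for r in responses
        ]
    ).to_csv(path, index=False)


def read_anthropometry_table(path: str | Path) -> list[AnthropometryReport]:
    df = pd.read_csv(path, parse_dates=["report_date"])
    return [
        AnthropometryReport(
            participant_id=str(r["participant_id"]),
            report_date=r["report_date"].date(),
            height_m=None if pd.isna(r.get("height_m")) else float(r["height_m"]),
            weight_kg=None if pd.isna(r.get("weight_kg")) else float(r["weight_kg"]),
            bmi=None if pd.isna(r.get("bmi")) else float(r["bmi"]),
        )
        for _, r in df.iterrows()
    ]


def write_anthropometry_table(
    reports: list[AnthropometryReport], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "report_date": r.report_date,
                "height_m": r.height_m,
                "weight_kg": r.weight_kg,
                "bmi": r.bmi,
            }
            for r in reports
        ]
    ).to_csv(path, index=False)


_COVARIATE_COLS = [
    "participant_id",
    "record_date",
    "age",
    "gender",
    "education",
    "income",
    "race",
    "ethnicity",
    "smoking",
    "alcohol_drinks_wk",
    "coronary_artery_disease",
    "diabetes",
    "hyperlipidemia",
    "hypertension",
]


def read_covariate_table(path: str | Path) -> list[CovariateRecord]:
    df = pd.read_csv(path, parse_dates=["record_date"])
    out = []
    for _, r in df.iterrows():
        kwargs = {}
        for c in _COVARIATE_COLS[2:]:
            v = r.get(c)
            kwargs[c] = None if pd.isna(v) else v
        for flag in ("coronary_artery_disease", "diabetes", "hyperlipidemia", "hypertension"):
            if kwargs[flag] is not None:
                kwargs[flag] = bool(kwargs[flag])
        out.append(
            CovariateRecord(
                participant_id=str(r["participant_id"]),
                record_date=r["record_date"].date(),
                **kwargs,
            )
        )
    return out


def write_covariate_table(records: list[CovariateRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in _COVARIATE_COLS} for r in records]
    ).to_csv(path, index=False)


def write_analysis_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
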