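"""Readers for the four input CSV dialects.

``epochs.csv``     participant_id, timestamp (ISO-8601, minute epochs), counts
``responses.csv``  participant_id, day_index, work_answer, leisure_answer
``ipaq.csv``       participant_id, category, days_per_week, minutes_per_day
``covariates.csv`` participant_id, age, sex, six_mwt_m

Epoch files exported by Actigraph-era software sometimes carry a 10-line
device header; it is skipped when the file opens with a ``---`` banner.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import EpochSeries, MINUTES_PER_DAY
from .errors import ValidationError
from .ipaq import CATEGORIES, IPAQRecord
from .mobilepal import DailyResponse

ACTIGRAPH_HEADER_LINES = 10


def load_epochs(path: str | Path) -> dict[str, EpochSeries]:
    """Read minute-epoch counts into one EpochSeries per participant.

    Every represented calendar day must be complete (all 1440 minutes) and
    each participant's days contiguous.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = ACTIGRAPH_HEADER_LINES if first.startswith("---") else 0
    df = pd.read_csv(path, skiprows=skip)
    required = {"participant_id", "timestamp", "counts"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    if df.empty:
        return {}
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(_date=ts.dt.normalize(), _minute=ts.dt.hour * 60 + ts.dt.minute)
    out: dict[str, EpochSeries] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        days = pd.DatetimeIndex(np.sort(grp["_date"].unique()))
        n_days = len(days)
        span = (days[-1] - days[0]).days + 1
        if span != n_days:
            raise ValidationError(f"{path}: participant {pid} has non-contiguous days")
        counts = np.full((n_days, MINUTES_PER_DAY), -1, dtype=np.int64)
        day_idx = (grp["_date"] - days[0]).dt.days.to_numpy()
        counts[day_idx, grp["_minute"].to_numpy()] = grp["counts"].to_numpy()
        if np.any(counts < 0):
            bad = int(np.argwhere(counts < 0)[0][0])
            raise ValidationError(
                f"{path}: participant {pid} day {bad + 1} is missing minute epochs"
            )
        out[str(pid)] = EpochSeries(
            participant_id=str(pid),
            start_date=pd.Timestamp(days[0]).date(),
            counts=counts,
        )
    return out


def load_responses(path: str | Path) -> dict[str, list[DailyResponse]]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"participant_id", "day_index", "work_answer", "leisure_answer"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, list[DailyResponse]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.participant_id), []).append(
            DailyResponse(
                day_index=int(row.day_index),
                work_answer=str(row.work_answer),
                leisure_answer=str(row.leisure_answer),
            )
        )
    for responses in out.values():
        responses.sort(key=lambda r: r.day_index)
    return out


def load_ipaq(path: str | Path) -> dict[str, IPAQRecord]:
    """Read recall records; with a ``domain`` column, categories are summed
    across domains (minutes weighted by reported frequency are additive)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"participant_id", "category", "days_per_week", "minutes_per_day"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"{path}: unknown IPAQ categories {sorted(bad)}")
    out: dict[str, IPAQRecord] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        days: dict[str, int] = {}
        minutes: dict[str, float] = {}
        for cat, sub in grp.groupby("category"):
            d = int(sub["days_per_week"].max())
            # weekly minutes conserved when collapsing domains
            weekly = float((sub["minutes_per_day"] * sub["days_per_week"]).sum())
            days[cat] = d
            minutes[cat] = weekly / d if d else 0.0
        out[str(pid)] = IPAQRecord(days_per_week=days, minutes_per_day=minutes)
    return out


def load_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"participant_id", "age", "sex", "six_mwt_m"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df.set_index("participant_id", drop=False)
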