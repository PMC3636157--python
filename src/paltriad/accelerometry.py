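"""Minute-epoch accelerometer count processing.

Counts-per-minute (cpm) streams from a hip-worn activity monitor are turned
into the per-participant summary measures used by the validity analysis:

* non-wear detection — a minute is non-worn iff it lies in a maximal run of
  consecutive zero-count minutes at least 60 min long (runs of up to 59 zeros
  count as worn sedentary time);
* intensity classification — sedentary <=100 cpm, light 101-2020, moderate
  2021-5999, vigorous >=6000;
* counts-to-MET conversion — the Freedson adult regression
  MET = 1.439008 + 0.000795 x cpm;
* a valid monitoring day has >= 600 worn minutes (10 h); participant
  summaries average over valid days and require a minimum number of them
  (default 4).

Days are processed independently: zero runs are not merged across midnight.
Epoch length is fixed at 60 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .errors import QualityControlError, ValidationError

MINUTES_PER_DAY = 1440

#: Intensity category names, in increasing order.
INTENSITY_CATEGORIES: tuple[str, ...] = ("sedentary", "light", "moderate", "vigorous")
#: Upper cpm bound (inclusive) of each category but the last.
CUTPOINTS: tuple[int, ...] = (100, 2020, 5999)

#: Freedson adult counts-to-MET regression coefficients.
FREEDSON_INTERCEPT = 1.439008
FREEDSON_SLOPE = 0.000795

#: A zero run of at least this many minutes is non-wear.
NONWEAR_RUN_MINUTES = 60
#: Worn minutes needed for a valid monitoring day (10 h).
VALID_DAY_MINUTES = 600
#: Valid days needed for a participant summary.
MIN_VALID_DAYS = 4


@dataclass(frozen=True)
class EpochSeries:
    """Minute-level counts for one participant, as a (n_days, 1440) matrix.

    Row d holds the counts for calendar day ``start_date + d``, column m the
    count of minute-of-day m.
    """

    participant_id: str
    start_date: Date
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != MINUTES_PER_DAY:
            raise ValidationError(
                f"counts must be (n_days, {MINUTES_PER_DAY}), got shape {c.shape}"
            )
        if np.any(c < 0):
            raise ValidationError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    def dates(self) -> list[Date]:
        base = pd.Timestamp(self.start_date)
        return [(base + pd.Timedelta(days=d)).date() for d in range(self.n_days)]

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per minute epoch with an ISO timestamp."""
        n = self.n_days * MINUTES_PER_DAY
        ts = pd.Timestamp(self.start_date) + pd.to_timedelta(np.arange(n), unit="m")
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": ts,
                "counts": self.counts.reshape(-1),
            }
        )


@dataclass(frozen=True)
class WearMask:
    """Per-epoch worn flags aligned to an EpochSeries."""

    worn: np.ndarray  # bool, same shape as EpochSeries.counts


@dataclass(frozen=True)
class DayMetrics:
    date: Date
    valid: bool
    wear_minutes: int
    mean_cpm: float
    intensity_minutes: dict[str, int] = field(default_factory=dict)
    day_mets: float = float("nan")


@dataclass(frozen=True)
class AccelSummary:
    acc_cpm: float
    acc_mets: float
    acc_pamin: float
    n_valid_days: int


def nonwear_mask_2d(counts: np.ndarray, run_minutes: int = NONWEAR_RUN_MINUTES) -> np.ndarray:
    """Vectorised non-wear detection over a (n_days, 1440) count matrix.

    Returns a boolean matrix, True where the minute is non-worn.  Rows are
    independent days; a run never crosses a row boundary.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        return np.zeros_like(counts, dtype=bool)
    if np.any(counts < 0):
        raise ValidationError("counts must be nonnegative")
    n, m = counts.shape
    # Guard column of nonzeros between rows so runs cannot span days.
    z = np.ones((n, m + 1), dtype=np.int8)
    z[:, :m] = counts == 0
    z[:, m] = 0
    flat = z.reshape(-1)
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    is_zero_run = flat[starts] == 1
    long_run = is_zero_run & (lengths >= run_minutes)
    mask = np.zeros(flat.size, dtype=bool)
    for s, ln in zip(starts[long_run], lengths[long_run]):
        mask[s : s + ln] = True
    return mask.reshape(n, m + 1)[:, :m]


def detect_nonwear(series: EpochSeries, run_minutes: int = NONWEAR_RUN_MINUTES) -> WearMask:
    """Wear mask for a series: worn iff not in a >=60-min maximal zero run."""
    return WearMask(worn=~nonwear_mask_2d(series.counts, run_minutes))


def classify_intensity(cpm) -> str | np.ndarray:
    """Intensity category of a cpm value (or array of values)."""
    arr = np.asarray(cpm)
    if np.any(arr < 0):
        raise ValidationError("cpm must be nonnegative")
    idx = np.searchsorted(np.asarray(CUTPOINTS), arr, side="left")
    cats = np.asarray(INTENSITY_CATEGORIES)[idx]
    return cats if arr.ndim else str(cats)


def counts_to_mets(
    cpm,
    intercept: float = FREEDSON_INTERCEPT,
    slope: float = FREEDSON_SLOPE,
):
    """Freedson counts-to-MET conversion, MET = intercept + slope * cpm."""
    arr = np.asarray(cpm, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("cpm must be nonnegative")
    out = intercept + slope * arr
    return out if out.ndim else float(out)


def day_metrics_frame(
    counts: np.ndarray,
    worn: np.ndarray | None = None,
    valid_day_minutes: int = VALID_DAY_MINUTES,
    met_intercept: float = FREEDSON_INTERCEPT,
    met_slope: float = FREEDSON_SLOPE,
) -> pd.DataFrame:
    """Per-day metrics for a (n_days, 1440) count matrix, vectorised.

    Columns: wear_minutes, valid, mean_cpm, day_mets, sedentary/light/
    moderate/vigorous minutes, nonsedentary_minutes.  mean_cpm and day_mets
    are NaN for days with zero worn minutes.
    """
    counts = np.asarray(counts)
    if worn is None:
        worn = ~nonwear_mask_2d(counts)
    worn = np.asarray(worn, dtype=bool)
    if worn.shape != counts.shape:
        raise ValidationError("wear mask must align with the count matrix")
    wear_minutes = worn.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cpm = np.where(
            wear_minutes > 0,
            (counts * worn).sum(axis=1) / np.maximum(wear_minutes, 1),
            np.nan,
        )
    idx = np.searchsorted(np.asarray(CUTPOINTS), counts, side="left")
    out = pd.DataFrame(
        {
            "wear_minutes": wear_minutes,
            "valid": wear_minutes >= valid_day_minutes,
            "mean_cpm": mean_cpm,
            "day_mets": met_intercept + met_slope * mean_cpm,
        }
    )
    for k, cat in enumerate(INTENSITY_CATEGORIES):
        out[cat] = ((idx == k) & worn).sum(axis=1)
    out["nonsedentary_minutes"] = wear_minutes - out["sedentary"]
    return out


def summarize_day(
    series: EpochSeries,
    mask: WearMask,
    date: Date,
    valid_day_minutes: int = VALID_DAY_MINUTES,
) -> DayMetrics:
    """Metrics for one calendar day of a series.

    Worn minutes only enter the averages; intensity minutes partition the
    worn minutes.  A day with zero worn minutes has NaN mean_cpm/day_mets.
    """
    dates = series.dates()
    if date not in dates:
        raise ValidationError(f"{date} is not a day of this series")
    d = dates.index(date)
    if series.counts.shape[1] == 0:
        raise ValidationError("empty day")
    frame = day_metrics_frame(
        series.counts[d : d + 1],
        np.asarray(mask.worn, dtype=bool)[d : d + 1],
        valid_day_minutes=valid_day_minutes,
    )
    row = frame.iloc[0]
    return DayMetrics(
        date=date,
        valid=bool(row["valid"]),
        wear_minutes=int(row["wear_minutes"]),
        mean_cpm=float(row["mean_cpm"]),
        intensity_minutes={c: int(row[c]) for c in INTENSITY_CATEGORIES},
        day_mets=float(row["day_mets"]),
    )


def summarize_participant(
    day_metrics: list[DayMetrics] | pd.DataFrame,
    min_valid_days: int = MIN_VALID_DAYS,
) -> AccelSummary:
    """Average day metrics over valid days into the participant summary.

    Raises QualityControlError when fewer than ``min_valid_days`` days are
    valid (the inclusion floor for the analysis).
    """
    if isinstance(day_metrics, pd.DataFrame):
        frame = day_metrics
    else:
        if not day_metrics:
            raise ValidationError("summarize_participant requires at least one day")
        frame = pd.DataFrame(
            {
                "valid": [d.valid for d in day_metrics],
                "mean_cpm": [d.mean_cpm for d in day_metrics],
                "day_mets": [d.day_mets for d in day_metrics],
                "nonsedentary_minutes": [
                    d.wear_minutes - d.intensity_minutes.get("sedentary", 0)
                    for d in day_metrics
                ],
            }
        )
    valid = frame[frame["valid"].astype(bool)]
    if len(valid) < min_valid_days:
        raise QualityControlError(
            f"only {len(valid)} valid day(s); {min_valid_days} required"
        )
    return AccelSummary(
        acc_cpm=float(valid["mean_cpm"].mean()),
        acc_mets=float(valid["day_mets"].mean()),
        acc_pamin=float(valid["nonsedentary_minutes"].mean()),
        n_valid_days=int(len(valid)),
    )


def process_series(
    series: EpochSeries,
    min_valid_days: int = MIN_VALID_DAYS,
    valid_day_minutes: int = VALID_DAY_MINUTES,
    run_minutes: int = NONWEAR_RUN_MINUTES,
    met_intercept: float = FREEDSON_INTERCEPT,
    met_slope: float = FREEDSON_SLOPE,
) -> AccelSummary:
    """Full chain for one participant: non-wear -> day metrics -> summary."""
    worn = ~nonwear_mask_2d(series.counts, run_minutes)
    frame = day_metrics_frame(
        series.counts,
        worn,
        valid_day_minutes=valid_day_minutes,
        met_intercept=met_intercept,
        met_slope=met_slope,
    )
    return summarize_participant(frame, min_valid_days=min_valid_days)
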