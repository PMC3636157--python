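"""Scoring of the two-question daily smartphone physical-activity instrument.

Each evening the participant answers two questions — one about work/daytime
activity, one about leisure/evening activity.  The work answer maps to a base
physical activity level (PAL, the ratio of total to resting energy expenditure
over 24 h) and the leisure answer adds a fixed increment, giving a 4x4 grid of
16 possible daily PAL values between 1.55 and 2.49.  The weekly score
(MobilePAL) is the average of the daily values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

WORK_ANSWERS: tuple[str, ...] = (
    "Mostly sitting",
    "Sitting/standing/walking",
    "Standing/walking most of the time",
    "Heavy work",
)
LEISURE_ANSWERS: tuple[str, ...] = (
    "Mostly sitting",
    "Light/walking (30 min)",
    "Moderate/cycling (>30 min)",
    "Sport/cycling (>60 min)",
)

WORK_PAL: tuple[float, ...] = (1.55, 1.65, 1.85, 2.2)
LEISURE_INCREMENT: tuple[float, ...] = (0.0, 0.06, 0.15, 0.29)

PAL_MIN = WORK_PAL[0] + LEISURE_INCREMENT[0]  # 1.55
PAL_MAX = WORK_PAL[-1] + LEISURE_INCREMENT[-1]  # 2.49


def _normalize(answer: str) -> str:
    # case-insensitive, whitespace-collapsed matching for CSV robustness
    return " ".join(str(answer).split()).lower()


_WORK_LOOKUP = {_normalize(a): i for i, a in enumerate(WORK_ANSWERS)}
_LEISURE_LOOKUP = {_normalize(a): i for i, a in enumerate(LEISURE_ANSWERS)}


def work_index(answer: str) -> int:
    try:
        return _WORK_LOOKUP[_normalize(answer)]
    except KeyError:
        raise ValidationError(f"unrecognized work/daytime answer: {answer!r}") from None


def leisure_index(answer: str) -> int:
    try:
        return _LEISURE_LOOKUP[_normalize(answer)]
    except KeyError:
        raise ValidationError(f"unrecognized leisure/evening answer: {answer!r}") from None


@dataclass(frozen=True)
class DailyResponse:
    """One day's pair of categorical answers."""

    day_index: int
    work_answer: str
    leisure_answer: str


@dataclass(frozen=True)
class PalScore:
    """Daily PAL (dimensionless, in [1.55, 2.49])."""

    daily_pal: float


@dataclass(frozen=True)
class WeeklyPal:
    mobile_pal: float
    n_answered_days: int


def grid_value(work_idx: int, leisure_idx: int) -> float:
    """Daily PAL for a (work, leisure) category pair."""
    return WORK_PAL[work_idx] + LEISURE_INCREMENT[leisure_idx]


def pal_grid() -> list[float]:
    """All 16 daily PAL values of the scoring grid, row-major by work category."""
    return [grid_value(w, l) for w in range(4) for l in range(4)]


def score_day(response: DailyResponse) -> PalScore:
    """Score one day's two answers into a daily PAL.

    The work/daytime answer contributes the base PAL and the leisure/evening
    answer a fixed increment; the sum is the daily PAL.
    """
    w = work_index(response.work_answer)
    l = leisure_index(response.leisure_answer)
    return PalScore(grid_value(w, l))


def average_week(
    scores: Sequence[PalScore] | Iterable[PalScore],
    policy: str = "answered",
) -> WeeklyPal:
    """Average daily PAL scores into the weekly MobilePAL.

    policy="answered" divides by the number of answered days (no downward
    bias when prompts were missed); policy="fixed7" always divides by 7,
    the instrument's literal formula for a complete week.  The two agree
    whenever all 7 days were answered.
    """
    values = [s.daily_pal for s in scores]
    if not values:
        raise ValidationError("average_week requires at least one daily score")
    if len(values) > 7:
        raise ValidationError(f"at most 7 daily scores expected, got {len(values)}")
    if policy == "answered":
        denom = len(values)
    elif policy == "fixed7":
        denom = 7
    else:
        raise ValidationError(f"unknown denominator policy: {policy!r}")
    return WeeklyPal(mobile_pal=sum(values) / denom, n_answered_days=len(values))
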