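"""IPAQ (International Physical Activity Questionnaire) 7-day recall scoring.

The short-form record holds, per activity category (walking, moderate,
vigorous), the number of days in the past week the activity was done and the
usual minutes per day.  Scoring weights each category's weekly minutes by its
MET intensity (official continuous-score weights: walking 3.3, moderate 4.0,
vigorous 8.0) and reports two daily summaries:

* ``ipaq_met``   — MET-minutes per day (weekly MET-minutes / 7)
* ``ipaq_pamin`` — active minutes per day (weekly active minutes / 7)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError

CATEGORIES: tuple[str, ...] = ("walking", "moderate", "vigorous")

#: Official IPAQ continuous-score MET weights per category.
DEFAULT_MET_WEIGHTS: dict[str, float] = {"walking": 3.3, "moderate": 4.0, "vigorous": 8.0}

#: Per-category daily-minutes cap used by the official cleaning protocol.
PROTOCOL_TRUNCATION_MIN = 180.0
#: Minimum bout length recognised by the official cleaning protocol.
PROTOCOL_MIN_BOUT_MIN = 10.0


@dataclass(frozen=True)
class IPAQRecord:
    """One participant's recall: per category, days/week and minutes/day."""

    days_per_week: Mapping[str, int] = field(default_factory=dict)
    minutes_per_day: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            d = self.days_per_week.get(cat, 0)
            m = self.minutes_per_day.get(cat, 0.0)
            if not 0 <= d <= 7 or int(d) != d:
                raise ValidationError(f"days_per_week[{cat!r}] must be an integer in [0, 7], got {d}")
            if m < 0:
                raise ValidationError(f"minutes_per_day[{cat!r}] must be nonnegative, got {m}")

    def days(self, cat: str) -> int:
        return int(self.days_per_week.get(cat, 0))

    def minutes(self, cat: str) -> float:
        return float(self.minutes_per_day.get(cat, 0.0))


@dataclass(frozen=True)
class IpaqSummary:
    ipaq_met: float  # MET-minutes per day
    ipaq_pamin: float  # active minutes per day


def _check_weights(met_weights: Mapping[str, float]) -> None:
    for cat in CATEGORIES:
        if met_weights.get(cat, 0.0) <= 0:
            raise ValidationError(f"MET weight for {cat!r} must be positive")


def _cleaned(record: IPAQRecord, clean: str | None) -> IPAQRecord:
    if clean is None:
        return record
    if clean != "ipaq_protocol":
        raise ValidationError(f"unknown cleaning mode: {clean!r}")
    days = {}
    minutes = {}
    for cat in CATEGORIES:
        m = record.minutes(cat)
        if m < PROTOCOL_MIN_BOUT_MIN:
            m = 0.0
        days[cat] = record.days(cat)
        minutes[cat] = min(m, PROTOCOL_TRUNCATION_MIN)
    return IPAQRecord(days, minutes)


def met_minutes_week(
    record: IPAQRecord,
    met_weights: Mapping[str, float] = DEFAULT_MET_WEIGHTS,
    clean: str | None = None,
) -> float:
    """Weekly MET-minutes: sum over categories of minutes/day x days/week x MET weight."""
    _check_weights(met_weights)
    rec = _cleaned(record, clean)
    return sum(rec.minutes(c) * rec.days(c) * met_weights[c] for c in CATEGORIES)


def active_minutes_week(record: IPAQRecord, clean: str | None = None) -> float:
    """Weekly active minutes: sum over categories of minutes/day x days/week."""
    rec = _cleaned(record, clean)
    return sum(rec.minutes(c) * rec.days(c) for c in CATEGORIES)


def derive_daily(
    record: IPAQRecord,
    met_weights: Mapping[str, float] = DEFAULT_MET_WEIGHTS,
    clean: str | None = None,
) -> IpaqSummary:
    """Daily IPAQ summaries: weekly totals divided by 7 days."""
    return IpaqSummary(
        ipaq_met=met_minutes_week(record, met_weights, clean) / 7.0,
        ipaq_pamin=active_minutes_week(record, clean) / 7.0,
    )
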