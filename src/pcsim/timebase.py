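"""Temporal algebra: decimal time, half-day sessions, weekly session classes.

Simulated time is a continuum of days. A time object ``(day, frac)`` encodes
either a point in time or a duration; ``frac`` is the *decimal time*, the
elapsed fraction of the day, so ``(38, 0.55)`` is day 38 at
``24*60*0.55 = 792`` minutes past midnight (13:12).  Each day splits into a
morning and an afternoon clinical session; sessions recur weekly, giving 14
weekly session classes (Monday morning .. Sunday afternoon).  Day 0 is a
Monday.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

#: Comparison tolerance on scalar day values (~0.1 ms).
TIME_EPS = 1e-9

MINUTES_PER_DAY = 24 * 60

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass(frozen=True, order=True)
class TimePoint:
    """A point in time or a duration: non-negative day plus decimal time.

    The lexicographic dataclass order coincides with the order of the scalar
    value ``day + frac`` because ``0 <= frac < 1``.
    """

    day: int
    frac: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be non-negative, got {self.day}")
        if not 0.0 <= self.frac < 1.0:
            raise ValueError(f"frac must lie in [0, 1), got {self.frac}")

    @property
    def scalar(self) -> float:
        """Non-negative scalar value ``day + frac`` (days)."""
        return self.day + self.frac

    @classmethod
    def from_scalar(cls, value: float) -> "TimePoint":
        if value < 0:
            raise ValueError(f"time scalar must be non-negative, got {value}")
        day = int(math.floor(value))
        frac = value - day
        if frac >= 1.0:  # floating artefact at day boundaries
            day, frac = day + 1, 0.0
        return cls(day, frac)

    def __str__(self) -> str:
        minutes = round(self.frac * MINUTES_PER_DAY)
        return f"d{self.day} {minutes // 60:02d}:{minutes % 60:02d}"


#: Durations share the encoding of time points; context disambiguates.
Duration = TimePoint

TimeLike = Union[TimePoint, float]


def as_scalar(t: TimeLike) -> float:
    """Scalar day value of a time point/duration (floats pass through)."""
    return t.scalar if isinstance(t, TimePoint) else float(t)


def decode_time(t: TimePoint) -> tuple[int, float]:
    """Split a time point into (day, minutes past midnight)."""
    return t.day, t.frac * MINUTES_PER_DAY


def encode_time(day: int, minutes: float) -> TimePoint:
    """Inverse of :func:`decode_time`."""
    return TimePoint(day, minutes / MINUTES_PER_DAY)


@dataclass(frozen=True, order=True)
class Session:
    """Half-day clinical session: day plus morning (0) / afternoon (1) flag."""

    day: int
    half: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be non-negative, got {self.day}")
        if self.half not in (0, 1):
            raise ValueError(f"half must be 0 or 1, got {self.half}")


@dataclass(frozen=True, order=True)
class WeeklySessionClass:
    """Weekly equivalence class of sessions: weekday (0 = Monday) plus half."""

    weekday: int
    half: int

    def __post_init__(self) -> None:
        if not 0 <= self.weekday <= 6:
            raise ValueError(f"weekday must lie in [0, 6], got {self.weekday}")
        if self.half not in (0, 1):
            raise ValueError(f"half must be 0 or 1, got {self.half}")

    @property
    def index(self) -> int:
        """Dense index in [0, 14): ``2 * weekday + half``."""
        return 2 * self.weekday + self.half

    @classmethod
    def from_index(cls, index: int) -> "WeeklySessionClass":
        return cls(index // 2, index % 2)

    def __str__(self) -> str:
        return f"{WEEKDAY_NAMES[self.weekday]}-{'AM' if self.half == 0 else 'PM'}"


#: All 14 weekly session classes in dense-index order.
ALL_WEEKLY_CLASSES: tuple[WeeklySessionClass, ...] = tuple(
    WeeklySessionClass.from_index(i) for i in range(14)
)


def weekly_class(s: Session) -> WeeklySessionClass:
    """Weekly class of a session: two sessions are equivalent iff their days
    agree modulo 7 and they fall in the same half of the day."""
    return WeeklySessionClass(s.day % 7, s.half)


def scalar(t: TimeLike) -> float:
    """Scalar day value associated with a time point or duration."""
    return as_scalar(t)
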