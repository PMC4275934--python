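"""Core temporal types and granularity-aware calendar arithmetic.

Clinical narratives state time at mixed resolutions: a stent implantation may
carry a full date, the start of antiplatelet therapy only a month ("May
2006"), and a delay between events an explicit count of days.  Every value in
this module therefore carries an explicit :class:`Granularity`, and all
arithmetic is defined so that it never manufactures precision the narrative
did not contain.

Conventions (fixed, documented, and used consistently everywhere):

* proleptic Gregorian calendar; month/year arithmetic clamps the day of month
  (Jan 31 + 1 month = Feb 28/29);
* unit conversion uses 1 year = 12 months, 1 month = 30 days, 1 day =
  24 hours, 1 hour = 60 minutes, rounding to the nearest integer with ties
  rounded up when converting to a coarser unit;
* adding a duration to a timestamp yields a result at the *coarser* of the two
  granularities;
* range durations ("2-3 months") are representable but excluded from
  arithmetic.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Dict, List, Optional, Tuple, Union

from .errors import CannotRefineError, RangeDurationError, SchemaError

__all__ = [
    "Granularity",
    "TimeStamp",
    "Duration",
    "Event",
    "Relation",
    "TemporalAssertion",
    "EventTimes",
    "AnnotatedDocument",
    "EVENT_TYPES",
    "truncate",
    "add_duration",
    "timestamp_difference",
    "convert_duration",
]


class Granularity(IntEnum):
    """Time resolution; larger values are coarser (MINUTE < ... < YEAR)."""

    MINUTE = 1
    HOUR = 2
    DAY = 3
    MONTH = 4
    YEAR = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, text: str) -> "Granularity":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown granularity: {text!r}") from None

    def is_coarser_than(self, other: "Granularity") -> bool:
        return self > other

    def is_finer_than(self, other: "Granularity") -> bool:
        return self < other


#: Exact minute equivalents of each unit under the fixed conventions.
MINUTES_PER_UNIT: Dict[Granularity, int] = {
    Granularity.MINUTE: 1,
    Granularity.HOUR: 60,
    Granularity.DAY: 24 * 60,
    Granularity.MONTH: 30 * 24 * 60,
    Granularity.YEAR: 12 * 30 * 24 * 60,
}

_FIELD_GRAN = {
    "year": Granularity.YEAR,
    "month": Granularity.MONTH,
    "day": Granularity.DAY,
    "hour": Granularity.HOUR,
    "minute": Granularity.MINUTE,
}


@dataclass(frozen=True)
class TimeStamp:
    """A calendar position carrying an explicit granularity.

    Fields finer than ``granularity`` are absent (``None``); fields at or
    coarser than it are present and calendar-valid.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None
    hour: Optional[int] = None
    minute: Optional[int] = None
    granularity: Granularity = Granularity.DAY

    def __post_init__(self) -> None:
        for name, g in _FIELD_GRAN.items():
            value = getattr(self, name)
            if g >= self.granularity:
                if value is None:
                    raise ValueError(
                        f"field {name!r} required at granularity {self.granularity.label}"
                    )
            elif value is not None:
                raise ValueError(
                    f"field {name!r} must be absent at granularity {self.granularity.label}"
                )
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            n_days = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= n_days:
                raise ValueError(f"day out of range for {self.year}-{self.month:02d}: {self.day}")
        if self.hour is not None and not 0 <= self.hour <= 23:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.minute is not None and not 0 <= self.minute <= 59:
            raise ValueError(f"minute out of range: {self.minute}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_datetime(cls, dt: _dt.datetime, granularity: Granularity) -> "TimeStamp":
        """Build a stamp from a datetime, discarding fields finer than ``granularity``."""
        g = granularity
        return cls(
            year=dt.year,
            month=dt.month if g <= Granularity.MONTH else None,
            day=dt.day if g <= Granularity.DAY else None,
            hour=dt.hour if g <= Granularity.HOUR else None,
            minute=dt.minute if g <= Granularity.MINUTE else None,
            granularity=g,
        )

    def to_datetime(self) -> _dt.datetime:
        """Internal anchor: absent fields are filled with their minimum value."""
        return _dt.datetime(
            self.year,
            self.month or 1,
            self.day or 1,
            self.hour or 0,
            self.minute or 0,
        )

    # -- rendering ------------------------------------------------------------

    def isoformat(self) -> str:
        """Canonical ISO-like text, truncated to the stamp's granularity."""
        g = self.granularity
        if g == Granularity.YEAR:
            return f"{self.year:04d}"
        if g == Granularity.MONTH:
            return f"{self.year:04d}-{self.month:02d}"
        if g == Granularity.DAY:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if g == Granularity.HOUR:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}T{self.hour:02d}"
        return (
            f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
            f"T{self.hour:02d}:{self.minute:02d}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


@dataclass(frozen=True)
class Duration:
    """A non-negative temporal extent in a single unit.

    ``is_range`` marks narrated ranges such as "2-3 months"; range durations
    are preserved faithfully but rejected by all arithmetic.
    """

    magnitude: int
    unit: Granularity
    is_range: bool = False
    range_high: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.magnitude, int) or self.magnitude < 0:
            raise ValueError(f"magnitude must be a non-negative integer: {self.magnitude!r}")
        if self.is_range:
            if self.range_high is None or self.range_high <= self.magnitude:
                raise ValueError("range_high must exceed magnitude for range durations")
        elif self.range_high is not None:
            raise ValueError("range_high only permitted on range durations")

    def in_minutes(self) -> int:
        """Exact minute equivalent under the fixed conventions (non-range only)."""
        if self.is_range:
            raise RangeDurationError("range duration has no single minute equivalent")
        return self.magnitude * MINUTES_PER_UNIT[self.unit]

    def canonical_text(self) -> str:
        """Canonical string that the normalizer parses back to an equal value."""
        word = self.unit.label
        if self.is_range:
            plural = "" if self.range_high == 1 else "s"
            return f"{self.magnitude}-{self.range_high} {word}{plural}"
        plural = "" if self.magnitude == 1 else "s"
        return f"{self.magnitude} {word}{plural}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_text()


# ---------------------------------------------------------------------------
# Granularity-aware operations
# ---------------------------------------------------------------------------


def truncate(ts: TimeStamp, g: Granularity) -> TimeStamp:
    """Coarsen ``ts`` to granularity ``g`` by removing finer fields.

    Idempotent.  Requesting a granularity finer than the stamp carries raises
    :class:`CannotRefineError` — truncation can only discard precision.
    """
    if g < ts.granularity:
        raise CannotRefineError(
            f"cannot refine {ts.isoformat()} ({ts.granularity.label}) to {g.label}"
        )
    if g == ts.granularity:
        return ts
    return TimeStamp(
        year=ts.year,
        month=ts.month if g <= Granularity.MONTH else None,
        day=ts.day if g <= Granularity.DAY else None,
        hour=ts.hour if g <= Granularity.HOUR else None,
        minute=ts.minute if g <= Granularity.MINUTE else None,
        granularity=g,
    )


def _clamped(ts: TimeStamp, year: int, month: Optional[int]) -> TimeStamp:
    day = ts.day
    if day is not None and month is not None:
        day = min(day, calendar.monthrange(year, month)[1])
    return dataclasses.replace(ts, year=year, month=month, day=day)


_TIMEDELTA_FIELD = {
    Granularity.DAY: "days",
    Granularity.HOUR: "hours",
    Granularity.MINUTE: "minutes",
}


def _shift(ts: TimeStamp, unit: Granularity, amount: int) -> TimeStamp:
    """Shift ``ts`` by ``amount`` whole units, keeping its granularity."""
    if amount == 0:
        return ts
    if unit == Granularity.YEAR:
        return _clamped(ts, ts.year + amount, ts.month)
    if unit == Granularity.MONTH:
        total = ts.year * 12 + (ts.month - 1) + amount
        year, month0 = divmod(total, 12)
        return _clamped(ts, year, month0 + 1)
    dt = ts.to_datetime() + _dt.timedelta(**{_TIMEDELTA_FIELD[unit]: amount})
    return TimeStamp.from_datetime(dt, ts.granularity)


def add_duration(ts: TimeStamp, d: Duration, sign: int = 1) -> TimeStamp:
    """Calendar-correct ``ts + sign*d`` at the coarser of the two granularities.

    A day-unit offset applied to a month-granularity stamp is first converted
    to months (30-day convention, rounded); a month-unit offset applied to a
    day-granularity stamp is applied exactly and the result truncated to
    months.  Either way the result never pretends to more precision than the
    inputs carried.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    if d.is_range:
        raise RangeDurationError("range duration not addable")
    coarser = Granularity(max(ts.granularity, d.unit))
    if d.unit >= ts.granularity:
        shifted = _shift(ts, d.unit, sign * d.magnitude)
        return truncate(shifted, coarser)
    converted = convert_duration(d, ts.granularity)
    return _shift(ts, ts.granularity, sign * converted.magnitude)


def timestamp_difference(
    a: TimeStamp, b: TimeStamp, g: Optional[Granularity] = None
) -> Duration:
    """Non-negative calendar distance between two stamps, in unit ``g``.

    ``g`` defaults to, and may not be finer than, the coarser of the two input
    granularities.  Both stamps are truncated to ``g`` first: month/year
    differences are calendar differences, day and finer are exact counts.
    """
    coarsest_input = Granularity(max(a.granularity, b.granularity))
    if g is None:
        g = coarsest_input
    if g < coarsest_input:
        raise CannotRefineError(
            f"difference granularity {g.label} finer than inputs ({coarsest_input.label})"
        )
    ta, tb = truncate(a, g), truncate(b, g)
    if g == Granularity.YEAR:
        n = abs(ta.year - tb.year)
    elif g == Granularity.MONTH:
        n = abs((ta.year * 12 + ta.month) - (tb.year * 12 + tb.month))
    elif g == Granularity.DAY:
        n = abs((ta.to_datetime() - tb.to_datetime()).days)
    else:
        seconds = abs((ta.to_datetime() - tb.to_datetime()).total_seconds())
        n = int(seconds // (3600 if g == Granularity.HOUR else 60))
    return Duration(n, g)


def convert_duration(d: Duration, g: Granularity) -> Duration:
    """Deterministic unit conversion under the fixed conventions.

    Converting to a coarser unit rounds to the nearest integer (ties up);
    converting to a finer unit is exact.  Ranges must be resolved upstream.
    """
    if d.is_range:
        raise RangeDurationError("normalize ranges upstream")
    if d.unit == g:
        return d
    num = d.magnitude * MINUTES_PER_UNIT[d.unit]
    den = MINUTES_PER_UNIT[g]
    magnitude = (2 * num + den) // (2 * den)  # floor(num/den + 1/2)
    return Duration(magnitude, g)


# ---------------------------------------------------------------------------
# Domain types: events, assertions, documents
# ---------------------------------------------------------------------------

#: Closed vocabulary of the late-stent-thrombosis adverse-event domain,
#: plus ``other`` for events outside it.
EVENT_TYPES = frozenset(
    {
        "stent_implantation",
        "followup_stent_implantation",
        "antiplatelet_start",
        "antiplatelet_stop",
        "antiplatelet_therapy",
        "unrelated_surgery",
        "late_stent_thrombosis",
        "myocardial_infarction",
        "er_admission",
        "death",
        "other",
    }
)


class Relation(str, Enum):
    """Interval relations supported by annotation.

    BEFORE/AFTER/EQUAL/STARTS/FINISHES are the relations the annotation
    workflow uses; CONTAINS/DURING are accepted for completeness.
    """

    BEFORE = "BEFORE"
    AFTER = "AFTER"
    EQUAL = "EQUAL"
    STARTS = "STARTS"
    FINISHES = "FINISHES"
    CONTAINS = "CONTAINS"
    DURING = "DURING"


@dataclass(frozen=True)
class Event:
    """One annotated clinical event."""

    id: str
    event_type: str
    label: str = ""
    text_span: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("event id must be non-empty")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type: {self.event_type!r}")
        if self.text_span is not None:
            start, end = self.text_span
            if start < 0 or end < start:
                raise ValueError(f"invalid text span: {self.text_span}")


@dataclass(frozen=True)
class TemporalAssertion:
    """A subject–relation–object statement between events (or an event and a time).

    ``offset`` quantifies the distance for BEFORE/AFTER ("60 days after");
    ``relation_granularity`` records the resolution at which the relation was
    asserted ("event1 before event2 at day granularity" — they may share the
    day).  ``asserted`` distinguishes annotated statements from inferred ones.
    """

    subject: str
    relation: Relation
    object: Union[str, TimeStamp]
    offset: Optional[Duration] = None
    relation_granularity: Optional[Granularity] = None
    asserted: bool = True

    def __post_init__(self) -> None:
        if self.offset is not None and self.relation not in (Relation.BEFORE, Relation.AFTER):
            raise ValueError("offset only permitted with BEFORE/AFTER")
        if isinstance(self.object, str) and self.object == self.subject:
            raise ValueError(f"assertion relates event {self.subject!r} to itself")


@dataclass(frozen=True)
class EventTimes:
    """Annotated start (and optionally end) timestamps of one event."""

    start: Optional[TimeStamp] = None
    end: Optional[TimeStamp] = None


@dataclass
class AnnotatedDocument:
    """One narrative's events, temporal assertions, timestamps and durations."""

    doc_id: str
    events: List[Event] = field(default_factory=list)
    assertions: List[TemporalAssertion] = field(default_factory=list)
    event_timestamps: Dict[str, EventTimes] = field(default_factory=dict)
    event_durations: Dict[str, Duration] = field(default_factory=dict)
    narrative_text: Optional[str] = None
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def event_index(self) -> Dict[str, Event]:
        return {e.id: e for e in self.events}

    def validate(self) -> None:
        """Raise :class:`SchemaError` on duplicate ids or dangling references."""
        ids = [e.id for e in self.events]
        seen = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        if dupes:
            raise SchemaError(f"duplicate event ids: {dupes}")
        known = set(ids)
        dangling = []
        for a in self.assertions:
            if a.subject not in known:
                dangling.append(a.subject)
            if isinstance(a.object, str) and a.object not in known:
                dangling.append(a.object)
        dangling.extend(k for k in self.event_timestamps if k not in known)
        dangling.extend(k for k in self.event_durations if k not in known)
        if dangling:
            raise SchemaError(f"references to unknown event ids: {sorted(set(dangling))}")
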