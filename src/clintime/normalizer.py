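"""Rule-based normalization of free-text temporal expressions.

Converts expressions like "May 2006", "2006-07-14", "two months" or
"2-3 months" into :class:`~clintime.temporal_model.TimeStamp` /
:class:`~clintime.temporal_model.Duration` values with explicit granularity.
Anything outside the rule inventory yields ``kind="unsupported"`` with an
explanatory note — normalization is total and never raises on arbitrary text.

Mixed-granularity compounds ("two month and ten days") are deliberately
flagged unsupported rather than silently resolved; pass ``resolve_mixed=True``
to convert them to the finer unit under the 30-day-month convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .errors import SchemaError
from .temporal_model import (
    Duration,
    Granularity,
    TimeStamp,
    convert_duration,
)

__all__ = [
    "NormalizationResult",
    "normalize_time_expression",
    "normalize_duration_expression",
    "parse_timestamp",
    "parse_duration",
]


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of one normalization attempt.

    ``kind`` is one of ``timestamp``, ``duration`` or ``unsupported``;
    unsupported results carry no value and a non-empty note.
    """

    kind: str
    value: Union[TimeStamp, Duration, None]
    source_text: str
    note: str = ""

    def __post_init__(self) -> None:
        if (self.kind == "unsupported") != (self.value is None):
            raise ValueError("unsupported results and only they carry no value")
        if self.kind == "unsupported" and not self.note:
            raise ValueError("unsupported results require a note")


_MONTH_NAMES = {}
for _i, (_full, _abbr) in enumerate(
    [
        ("january", "jan"),
        ("february", "feb"),
        ("march", "mar"),
        ("april", "apr"),
        ("may", "may"),
        ("june", "jun"),
        ("july", "jul"),
        ("august", "aug"),
        ("september", "sep"),
        ("october", "oct"),
        ("november", "nov"),
        ("december", "dec"),
    ],
    start=1,
):
    _MONTH_NAMES[_full] = _i
    _MONTH_NAMES[_abbr] = _i
_MONTH_NAMES["sept"] = 9

# Number words zero through twelve; larger word numbers are unsupported.
_NUMBER_WORDS = {
    w: i
    for i, w in enumerate(
        "zero one two three four five six seven eight nine ten eleven twelve".split()
    )
}

_UNIT_WORDS = {
    "minute": Granularity.MINUTE,
    "hour": Granularity.HOUR,
    "day": Granularity.DAY,
    "month": Granularity.MONTH,
    "year": Granularity.YEAR,
}

_RE_ISO_MINUTE = re.compile(r"(\d{4})-(\d{1,2})-(\d{1,2})[T ](\d{1,2}):(\d{1,2})$")
_RE_ISO_HOUR = re.compile(r"(\d{4})-(\d{1,2})-(\d{1,2})[T ](\d{1,2})$")
_RE_ISO_DAY = re.compile(r"(\d{4})-(\d{1,2})-(\d{1,2})$")
_RE_ISO_MONTH = re.compile(r"(\d{4})-(\d{1,2})$")
_RE_YEAR = re.compile(r"(\d{4})$")
_RE_NAME_MONTH_YEAR = re.compile(r"([A-Za-z]+)\.?,?\s+(\d{4})$")
_RE_SLASH_DATE = re.compile(r"(\d{1,2})/(\d{1,2})/(\d{4})$")

_RE_RANGE = re.compile(r"(\d+)\s*-\s*(\d+)\s*([A-Za-z]+?)s?$")
_RE_AMOUNT_UNIT = re.compile(r"([A-Za-z]+|\d+)\s+([A-Za-z]+?)s?$")


def _unsupported(text: str, note: str) -> NormalizationResult:
    return NormalizationResult("unsupported", None, text, note)


def normalize_time_expression(text: str, dialect: str = "us") -> NormalizationResult:
    """Parse a point-in-time expression into a granular :class:`TimeStamp`.

    Recognizes ISO forms at every supported granularity ("2006",
    "2006-05", "2006-05-01", "2006-05-01T09", "2006-05-01T09:30"),
    English month-name + year ("May 2006"), and slash dates.  ``dialect``
    resolves the ambiguous slash form: ``"us"`` reads MM/DD/YYYY,
    ``"intl"`` reads DD/MM/YYYY.
    """
    try:
        return _normalize_time(text, dialect)
    except Exception:
        return _unsupported(text, "no parse rule")


def _normalize_time(text: str, dialect: str) -> NormalizationResult:
    raw = text
    s = text.strip()
    if not s:
        return _unsupported(raw, "empty expression")

    def build(g: Granularity, **fields: int) -> NormalizationResult:
        try:
            ts = TimeStamp(granularity=g, **fields)
        except ValueError as exc:
            return _unsupported(raw, f"invalid calendar value: {exc}")
        return NormalizationResult("timestamp", ts, raw)

    m = _RE_ISO_MINUTE.match(s)
    if m:
        y, mo, d, h, mi = map(int, m.groups())
        return build(Granularity.MINUTE, year=y, month=mo, day=d, hour=h, minute=mi)
    m = _RE_ISO_HOUR.match(s)
    if m:
        y, mo, d, h = map(int, m.groups())
        return build(Granularity.HOUR, year=y, month=mo, day=d, hour=h)
    m = _RE_ISO_DAY.match(s)
    if m:
        y, mo, d = map(int, m.groups())
        return build(Granularity.DAY, year=y, month=mo, day=d)
    m = _RE_ISO_MONTH.match(s)
    if m:
        y, mo = map(int, m.groups())
        return build(Granularity.MONTH, year=y, month=mo)
    m = _RE_YEAR.match(s)
    if m:
        return build(Granularity.YEAR, year=int(m.group(1)))
    m = _RE_NAME_MONTH_YEAR.match(s)
    if m:
        name, year = m.group(1).lower(), int(m.group(2))
        if name in _MONTH_NAMES:
            return build(Granularity.MONTH, year=year, month=_MONTH_NAMES[name])
        return _unsupported(raw, f"unknown month name: {m.group(1)!r}")
    m = _RE_SLASH_DATE.match(s)
    if m:
        a, b, y = map(int, m.groups())
        mo, d = (a, b) if dialect == "us" else (b, a)
        return build(Granularity.DAY, year=y, month=mo, day=d)
    return _unsupported(raw, "no parse rule")


def normalize_duration_expression(
    text: str, resolve_mixed: bool = False
) -> NormalizationResult:
    """Parse a duration expression into a granular :class:`Duration`.

    Recognizes digit and English-word magnitudes (zero through twelve) with
    units minute/hour/day/month/year, singular or plural, and "N-M unit"
    ranges.  Compounds like "two month and ten days" are flagged as mixed
    granularity unless ``resolve_mixed`` converts them to the finer unit.
    """
    try:
        return _normalize_duration(text, resolve_mixed)
    except Exception:
        return _unsupported(text, "no parse rule")


def _parse_amount_unit(s: str) -> Optional[Duration]:
    m = _RE_AMOUNT_UNIT.match(s)
    if not m:
        return None
    amount_text, unit_text = m.group(1), m.group(2).lower()
    if unit_text not in _UNIT_WORDS:
        return None
    if amount_text.isdigit():
        magnitude = int(amount_text)
    elif amount_text.lower() in _NUMBER_WORDS:
        magnitude = _NUMBER_WORDS[amount_text.lower()]
    else:
        raise LookupError(amount_text)
    return Duration(magnitude, _UNIT_WORDS[unit_text])


def _normalize_duration(text: str, resolve_mixed: bool) -> NormalizationResult:
    raw = text
    s = text.strip()
    if not s:
        return _unsupported(raw, "empty expression")

    parts = re.split(r"\s+and\s+|\s*,\s*", s)
    if len(parts) > 1:
        parsed = []
        for part in parts:
            try:
                d = _parse_amount_unit(part)
            except LookupError:
                d = None
            if d is None:
                return _unsupported(raw, "no parse rule")
            parsed.append(d)
        units = {d.unit for d in parsed}
        if not resolve_mixed:
            return _unsupported(raw, "mixed granularity")
        finest = Granularity(min(units))
        total = sum(convert_duration(d, finest).magnitude for d in parsed)
        return NormalizationResult("duration", Duration(total, finest), raw)

    m = _RE_RANGE.match(s)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        unit_text = m.group(3).lower()
        if unit_text not in _UNIT_WORDS:
            return _unsupported(raw, "no parse rule")
        if hi <= lo:
            return _unsupported(raw, f"degenerate range: {lo}-{hi}")
        d = Duration(lo, _UNIT_WORDS[unit_text], is_range=True, range_high=hi)
        return NormalizationResult("duration", d, raw)

    try:
        d = _parse_amount_unit(s)
    except LookupError as exc:
        return _unsupported(raw, f"unsupported number word: {exc.args[0]!r}")
    if d is None:
        return _unsupported(raw, "no parse rule")
    return NormalizationResult("duration", d, raw)


# -- strict variants used by annotation I/O ---------------------------------


def parse_timestamp(text: str, dialect: str = "us") -> TimeStamp:
    """Like :func:`normalize_time_expression` but raises on failure."""
    result = normalize_time_expression(text, dialect=dialect)
    if result.kind != "timestamp":
        raise SchemaError(f"unparseable timestamp {text!r}: {result.note}")
    return result.value


def parse_duration(text: str) -> Duration:
    """Like :func:`normalize_duration_expression` but raises on failure."""
    result = normalize_duration_expression(text)
    if result.kind != "duration":
        raise SchemaError(f"unparseable duration {text!r}: {result.note}")
    return result.value
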