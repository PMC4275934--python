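"""Read/write annotation documents and gold standards; Turtle export; relation matrix.

The primary interchange format is JSON (schema published in
``clintime/schemas/``); RDF/Turtle export is provided for interoperability
with ontology tooling.  All temporal fields are strings run through the
rule-based normalizer on ingestion, so hand-written documents may use any
recognized expression ("May 2006", "two months") while the writer always
emits canonical forms, making write∘read byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import pandas as pd
from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .errors import SchemaError
from .normalizer import parse_duration, parse_timestamp
from .temporal_model import (
    AnnotatedDocument,
    Duration,
    Event,
    EventTimes,
    Granularity,
    Relation,
    TemporalAssertion,
    TimeStamp,
)

__all__ = [
    "GoldStandard",
    "read_document",
    "write_document",
    "document_to_dict",
    "document_from_dict",
    "read_gold",
    "write_gold",
    "export_turtle",
    "relation_matrix",
    "CT",
]

#: Fixed namespace for Turtle export.
CT = Namespace("https://w3id.org/clintime#")


@dataclass
class GoldStandard:
    """Manually recorded truth for one document.

    ``ordered_events`` lists timeline buckets earliest-first; every event id
    appears in exactly one bucket.  ``pair_durations`` keys are (earlier,
    later) event-id pairs.
    """

    doc_id: str
    ordered_events: List[List[str]] = field(default_factory=list)
    event_durations: Dict[str, Duration] = field(default_factory=dict)
    pair_durations: Dict[Tuple[str, str], Duration] = field(default_factory=dict)

    def validate(self) -> None:
        seen = set()
        for bucket in self.ordered_events:
            if not bucket:
                raise SchemaError("empty gold bucket")
            for eid in bucket:
                if eid in seen:
                    raise SchemaError(f"event {eid!r} appears in more than one gold bucket")
                seen.add(eid)

    @property
    def all_ids(self) -> set:
        return {eid for bucket in self.ordered_events for eid in bucket}


# ---------------------------------------------------------------------------
# JSON document serialization
# ---------------------------------------------------------------------------


def _require(mapping: dict, key: str, typ, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field {key!r} in {where}")
    value = mapping[key]
    if not isinstance(value, typ):
        raise SchemaError(f"field {key!r} in {where} has wrong type {type(value).__name__}")
    return value


def _event_from_dict(d: dict) -> Event:
    if not isinstance(d, dict):
        raise SchemaError("each entry of 'events' must be an object")
    eid = _require(d, "id", str, "event")
    etype = _require(d, "event_type", str, f"event {eid!r}")
    span = d.get("text_span")
    if span is not None:
        if not (isinstance(span, (list, tuple)) and len(span) == 2):
            raise SchemaError(f"field 'text_span' in event {eid!r} must be a [start, end] pair")
        span = (int(span[0]), int(span[1]))
    try:
        return Event(id=eid, event_type=etype, label=d.get("label", ""), text_span=span)
    except ValueError as exc:
        raise SchemaError(f"event {eid!r}: {exc}") from exc


def _assertion_from_dict(d: dict, dialect: str) -> TemporalAssertion:
    if not isinstance(d, dict):
        raise SchemaError("each entry of 'assertions' must be an object")
    subject = _require(d, "subject", str, "assertion")
    where = f"assertion with subject {subject!r}"
    rel_text = _require(d, "relation", str, where)
    try:
        relation = Relation(rel_text.upper())
    except ValueError:
        raise SchemaError(f"unknown relation {rel_text!r} in {where}") from None
    obj = _require(d, "object", dict, where)
    if "event" in obj:
        target: Union[str, TimeStamp] = str(obj["event"])
    elif "time" in obj:
        target = parse_timestamp(str(obj["time"]), dialect=dialect)
    else:
        raise SchemaError(f"field 'object' in {where} needs an 'event' or 'time' key")
    offset = parse_duration(str(d["offset"])) if d.get("offset") is not None else None
    rel_g = (
        Granularity.parse(str(d["relation_granularity"]))
        if d.get("relation_granularity") is not None
        else None
    )
    try:
        return TemporalAssertion(
            subject=subject,
            relation=relation,
            object=target,
            offset=offset,
            relation_granularity=rel_g,
            asserted=bool(d.get("asserted", True)),
        )
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def document_from_dict(data: dict, dialect: str = "us") -> AnnotatedDocument:
    """Build and validate a document from its JSON object form."""
    if not isinstance(data, dict):
        raise SchemaError("document must be a JSON object")
    doc_id = _require(data, "doc_id", str, "document")
    events = [_event_from_dict(e) for e in _require(data, "events", list, "document")]
    assertions = [
        _assertion_from_dict(a, dialect)
        for a in _require(data, "assertions", list, "document")
    ]
    timestamps: Dict[str, EventTimes] = {}
    for eid, value in (data.get("timestamps") or {}).items():
        if isinstance(value, str):
            timestamps[eid] = EventTimes(start=parse_timestamp(value, dialect=dialect))
        elif isinstance(value, dict):
            start = value.get("start")
            end = value.get("end")
            timestamps[eid] = EventTimes(
                start=parse_timestamp(str(start), dialect=dialect) if start else None,
                end=parse_timestamp(str(end), dialect=dialect) if end else None,
            )
        else:
            raise SchemaError(f"field 'timestamps' entry for {eid!r} has wrong type")
    durations = {
        eid: parse_duration(str(text)) for eid, text in (data.get("durations") or {}).items()
    }
    doc = AnnotatedDocument(
        doc_id=doc_id,
        events=events,
        assertions=assertions,
        event_timestamps=timestamps,
        event_durations=durations,
        narrative_text=data.get("narrative_text"),
        metadata=dict(data.get("metadata") or {}),
    )
    doc.validate()
    return doc


def document_to_dict(doc: AnnotatedDocument) -> dict:
    """Canonical JSON object form (temporal values as canonical strings)."""
    out: dict = {
        "doc_id": doc.doc_id,
        "events": [
            {
                "id": e.id,
                "event_type": e.event_type,
                **({"label": e.label} if e.label else {}),
                **({"text_span": list(e.text_span)} if e.text_span else {}),
            }
            for e in doc.events
        ],
        "assertions": [
            {
                "subject": a.subject,
                "relation": a.relation.value,
                "object": (
                    {"event": a.object}
                    if isinstance(a.object, str)
                    else {"time": a.object.isoformat()}
                ),
                **({"offset": a.offset.canonical_text()} if a.offset else {}),
                **(
                    {"relation_granularity": a.relation_granularity.label}
                    if a.relation_granularity
                    else {}
                ),
                "asserted": a.asserted,
            }
            for a in doc.assertions
        ],
        "timestamps": {
            eid: {
                **({"start": t.start.isoformat()} if t.start else {}),
                **({"end": t.end.isoformat()} if t.end else {}),
            }
            for eid, t in sorted(doc.event_timestamps.items())
            if t.start or t.end
        },
        "durations": {
            eid: d.canonical_text() for eid, d in sorted(doc.event_durations.items())
        },
    }
    if doc.narrative_text is not None:
        out["narrative_text"] = doc.narrative_text
    if doc.metadata:
        out["metadata"] = doc.metadata
    return out


def read_document(path, dialect: str = "us") -> AnnotatedDocument:
    """Read and validate one annotation document from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return document_from_dict(data, dialect=dialect)


def write_document(doc: AnnotatedDocument, path) -> None:
    """Write canonical, byte-stable JSON (sorted keys, fixed indentation)."""
    doc.validate()
    text = json.dumps(document_to_dict(doc), indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Gold standards
# ---------------------------------------------------------------------------


def gold_from_dict(data: dict) -> GoldStandard:
    doc_id = _require(data, "doc_id", str, "gold standard")
    buckets = _require(data, "ordered_events", list, "gold standard")
    ordered = [[str(eid) for eid in bucket] for bucket in buckets]
    event_durations = {
        eid: parse_duration(str(text))
        for eid, text in (data.get("event_durations") or {}).items()
    }
    pair_durations = {}
    for key, text in (data.get("pair_durations") or {}).items():
        a, sep, b = key.partition("|")
        if not sep:
            raise SchemaError(f"pair_durations key {key!r} must be 'id1|id2'")
        pair_durations[(a, b)] = parse_duration(str(text))
    gold = GoldStandard(
        doc_id=doc_id,
        ordered_events=ordered,
        event_durations=event_durations,
        pair_durations=pair_durations,
    )
    gold.validate()
    return gold


def gold_to_dict(gold: GoldStandard) -> dict:
    return {
        "doc_id": gold.doc_id,
        "ordered_events": gold.ordered_events,
        "event_durations": {
            eid: d.canonical_text() for eid, d in sorted(gold.event_durations.items())
        },
        "pair_durations": {
            f"{a}|{b}": d.canonical_text()
            for (a, b), d in sorted(gold.pair_durations.items())
        },
    }


def read_gold(path) -> GoldStandard:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return gold_from_dict(data)


def write_gold(gold: GoldStandard, path) -> None:
    gold.validate()
    text = json.dumps(gold_to_dict(gold), indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# RDF/Turtle export
# ---------------------------------------------------------------------------

_XSD_BY_GRANULARITY = {
    Granularity.YEAR: XSD.gYear,
    Granularity.MONTH: XSD.gYearMonth,
    Granularity.DAY: XSD.date,
    Granularity.HOUR: XSD.dateTime,
    Granularity.MINUTE: XSD.dateTime,
}


def _timestamp_literal(ts: TimeStamp) -> Literal:
    text = ts.isoformat()
    if ts.granularity == Granularity.HOUR:
        text += ":00:00"
    elif ts.granularity == Granularity.MINUTE:
        text += ":00"
    return Literal(text, datatype=_XSD_BY_GRANULARITY[ts.granularity])


_XSD_DURATION_CODE = {
    Granularity.YEAR: ("P", "Y"),
    Granularity.MONTH: ("P", "M"),
    Granularity.DAY: ("P", "D"),
    Granularity.HOUR: ("PT", "H"),
    Granularity.MINUTE: ("PT", "M"),
}


def _duration_literal(d: Duration) -> Literal:
    if d.is_range:
        return Literal(d.canonical_text())
    prefix, code = _XSD_DURATION_CODE[d.unit]
    return Literal(f"{prefix}{d.magnitude}{code}", datatype=XSD.duration)


def export_turtle(doc: AnnotatedDocument, path) -> None:
    """Serialize a document as RDF/Turtle under the fixed ``ct:`` namespace.

    Triple count = (#assertions) + Σ over events of [2 type/eventType triples
    + 1 if labelled] + (#start stamps) + (#end stamps) + (#event durations).
    """
    doc.validate()
    g = Graph()
    g.bind("ct", CT)
    g.bind("xsd", XSD)
    base = Namespace(f"https://w3id.org/clintime/doc/{doc.doc_id}/")

    def uri(eid: str) -> URIRef:
        return base[eid]

    for e in doc.events:
        g.add((uri(e.id), RDF.type, CT.Event))
        g.add((uri(e.id), CT.eventType, Literal(e.event_type)))
        if e.label:
            g.add((uri(e.id), CT.label, Literal(e.label)))
    for eid, times in doc.event_timestamps.items():
        if times.start:
            g.add((uri(eid), CT.hasStartTime, _timestamp_literal(times.start)))
        if times.end:
            g.add((uri(eid), CT.hasEndTime, _timestamp_literal(times.end)))
    for eid, d in doc.event_durations.items():
        g.add((uri(eid), CT.hasDuration, _duration_literal(d)))
    for a in doc.assertions:
        predicate = CT[a.relation.value.lower()]
        obj = uri(a.object) if isinstance(a.object, str) else _timestamp_literal(a.object)
        g.add((uri(a.subject), predicate, obj))
    g.serialize(destination=str(path), format="turtle")


# ---------------------------------------------------------------------------
# Relation matrix (asserted vs inferred)
# ---------------------------------------------------------------------------


def relation_matrix(
    doc: AnnotatedDocument, inferred: Iterable[TemporalAssertion] = ()
) -> pd.DataFrame:
    """Square event-by-event table of temporal relations.

    Cell (i, j) holds the relation of event i to event j, tagged
    ``(asserted)`` or ``(inferred)``; undecided pairs read ``unknown`` and the
    diagonal is empty.  Asserted relations win over inferred ones for the
    same cell.  Serialize with ``df.to_csv(path, sep="\\t")``.
    """
    ids = [e.id for e in doc.events]
    cells = {(a, b): "unknown" for a in ids for b in ids if a != b}

    def label(a: TemporalAssertion, tag: str) -> str:
        # a relation decided only at a coarse granularity says so
        qualifier = f"@{a.relation_granularity.label}" if a.relation_granularity else ""
        return f"{a.relation.value}{qualifier} ({tag})"

    for a in sorted(inferred, key=lambda x: (x.subject, str(x.object), x.relation.value)):
        if isinstance(a.object, str) and (a.subject, a.object) in cells:
            cells[(a.subject, a.object)] = label(a, "inferred")
    for a in doc.assertions:
        if a.asserted and isinstance(a.object, str) and (a.subject, a.object) in cells:
            cells[(a.subject, a.object)] = label(a, "asserted")
    data = [[cells.get((row, col), "") for col in ids] for row in ids]
    return pd.DataFrame(data, index=ids, columns=ids)
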