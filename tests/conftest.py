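import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")

from clintime.temporal_model import (
    AnnotatedDocument,
    Duration,
    Event,
    EventTimes,
    Granularity,
    Relation,
    TemporalAssertion,
    TimeStamp,
)


@pytest.fixture
def implant_offset_doc():
    """Two events linked by a narrated 60-day delay, no timestamps."""
    return AnnotatedDocument(
        doc_id="implant-offset",
        events=[
            Event("implant", "stent_implantation", "stent implantation"),
            Event("discont", "antiplatelet_stop", "antiplatelet therapy discontinued"),
        ],
        assertions=[
            TemporalAssertion(
                "discont", Relation.AFTER, "implant", offset=Duration(60, Granularity.DAY)
            )
        ],
    )


@pytest.fixture
def therapy_month_doc():
    """Therapy starting May 2006, stopped the day before a July 2006 surgery."""
    return AnnotatedDocument(
        doc_id="therapy-months",
        events=[
            Event("therapy", "antiplatelet_therapy", "antiplatelet therapy"),
            Event("surgery", "unrelated_surgery", "prostate surgery"),
            Event("stop", "antiplatelet_stop", "therapy stopped"),
        ],
        assertions=[
            TemporalAssertion(
                "stop", Relation.BEFORE, "surgery", offset=Duration(1, Granularity.DAY)
            ),
            TemporalAssertion("stop", Relation.FINISHES, "therapy"),
        ],
        event_timestamps={
            "therapy": EventTimes(start=TimeStamp(2006, 5, granularity=Granularity.MONTH)),
            "surgery": EventTimes(start=TimeStamp(2006, 7, granularity=Granularity.MONTH)),
        },
    )


@pytest.fixture
def granular_chain_doc():
    """event1 before event2 at day granularity; event3 is 183 days after event2."""
    return AnnotatedDocument(
        doc_id="granular-chain",
        events=[Event("e1", "other"), Event("e2", "other"), Event("e3", "other")],
        assertions=[
            TemporalAssertion(
                "e1", Relation.BEFORE, "e2", relation_granularity=Granularity.DAY
            ),
            TemporalAssertion(
                "e3", Relation.AFTER, "e2", offset=Duration(183, Granularity.DAY)
            ),
        ],
    )


@pytest.fixture
def equal_pair_doc():
    """Three events: one EQUAL assertion plus two timestamps (matrix fixture)."""
    return AnnotatedDocument(
        doc_id="equal-pair",
        events=[
            Event("E1", "stent_implantation", "stent implanted"),
            Event("E2", "late_stent_thrombosis", "thrombosis identified"),
            Event("E3", "antiplatelet_start", "antiplatelet therapy started"),
        ],
        assertions=[TemporalAssertion("E3", Relation.EQUAL, "E1")],
        event_timestamps={
            "E1": EventTimes(start=TimeStamp(2006, 4, 21)),
            "E2": EventTimes(start=TimeStamp(2006, 10, 21)),
        },
    )
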