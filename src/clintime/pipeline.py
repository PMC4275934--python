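"""End-to-end convenience: build → propagate → infer → sort for one document."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .reasoner import (
    ConstraintGraph,
    DomainAxiomSet,
    ReasonerConfig,
    build_graph,
    infer_relations,
    propagate_timestamps,
)
from .temporal_model import AnnotatedDocument, Granularity, TemporalAssertion
from .timeline import TimelineResult, sort_timeline

__all__ = ["Analysis", "analyze"]


@dataclass
class Analysis:
    """Everything the reasoner derived for one document."""

    graph: ConstraintGraph
    inferred: List[TemporalAssertion]
    timeline: TimelineResult


def analyze(
    doc: AnnotatedDocument,
    axioms: Optional[DomainAxiomSet] = None,
    config: Optional[ReasonerConfig] = None,
    granularity: Optional[Granularity] = None,
) -> Analysis:
    """Run the full reasoning pipeline on one annotated document."""
    graph = build_graph(doc, axioms=axioms, config=config)
    propagate_timestamps(graph)
    inferred = infer_relations(graph)
    timeline = sort_timeline(graph, granularity=granularity)
    return Analysis(graph=graph, inferred=inferred, timeline=timeline)
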