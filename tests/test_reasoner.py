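"""Constraint-graph construction, closure, propagation, and duration chaining."""

import itertools

import networkx as nx
import numpy as np
import pytest

from helpers_oracles import (
    oracle_event_relations,
    random_offset_doc,
    random_relational_doc,
)

from clintime.errors import (
    InconsistencyError,
    InconsistentOffsetsError,
    InsufficientInformationError,
    InsufficientPrecisionError,
    SchemaError,
    TimestampConflictError,
)
from clintime.reasoner import (
    ConstraintGraph,
    DomainAxiomSet,
    EdgeKind,
    ReasonerConfig,
    build_graph,
    check_consistency,
    duration_between,
    event_duration,
    infer_relations,
    propagate_timestamps,
)
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

G = Granularity
S, E = ConstraintGraph.start, ConstraintGraph.end

INSTANT_OTHER = DomainAxiomSet(instantaneous_event_types=frozenset({"other"}))


def doc_of(events, assertions, timestamps=None, durations=None):
    return AnnotatedDocument(
        doc_id="t",
        events=[Event(e, "other") for e in events],
        assertions=assertions,
        event_timestamps=timestamps or {},
        event_durations=durations or {},
    )


class TestBuildGraph:
    def test_offset_assertion_compiles_to_exact_edge(self, implant_offset_doc):
        g = build_graph(implant_offset_doc)
        exact = [e for e in g.edges if e.kind == EdgeKind.EXACT]
        assert len(exact) == 1
        assert exact[0].u == E("implant")
        assert exact[0].v == S("discont")
        assert exact[0].offset == Duration(60, G.DAY)

    def test_equal_assertion_compiles_to_two_equalities(self):
        g = build_graph(doc_of(["a", "b"], [TemporalAssertion("a", Relation.EQUAL, "b")]))
        eq = [e for e in g.edges if e.kind == EdgeKind.EQ]
        assert {(e.u, e.v) for e in eq} == {(S("a"), S("b")), (E("a"), E("b"))}

    def test_death_last_axiom_injects_one_edge_per_other_event(self):
        doc = AnnotatedDocument(
            doc_id="d",
            events=[
                Event("implant", "stent_implantation"),
                Event("lst", "late_stent_thrombosis"),
                Event("death", "death"),
            ],
        )
        g = build_graph(doc, axioms=DomainAxiomSet(death_last=True))
        injected = [e for e in g.edges if e.kind == EdgeKind.LT and e.v == S("death")]
        assert len(injected) == 2

    def test_unknown_event_reference_rejected(self):
        doc = doc_of(["a"], [])
        doc.assertions.append(TemporalAssertion("a", Relation.BEFORE, "ghost"))
        with pytest.raises(SchemaError, match="ghost"):
            build_graph(doc)


class TestInferRelations:
    def test_transitivity(self):
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b"),
                TemporalAssertion("b", Relation.BEFORE, "c"),
            ],
        )
        inferred = infer_relations(build_graph(doc))
        assert ("a", Relation.BEFORE, "c") in {(x.subject, x.relation, x.object) for x in inferred}

    def test_inversion_twin_always_emitted(self):
        doc = doc_of(["a", "b"], [TemporalAssertion("a", Relation.BEFORE, "b")])
        inferred = infer_relations(build_graph(doc))
        assert {(x.subject, x.relation, x.object) for x in inferred} == {
            ("b", Relation.AFTER, "a")
        }

    def test_equality_substitutes_into_order(self):
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b"),
                TemporalAssertion("b", Relation.EQUAL, "c"),
            ],
        )
        decided = {(x.subject, x.relation, x.object) for x in infer_relations(build_graph(doc))}
        assert ("a", Relation.BEFORE, "c") in decided

    def test_timestamp_comparison_at_coarser_granularity(self):
        doc = doc_of(
            ["a", "b"],
            [],
            timestamps={
                "a": EventTimes(start=TimeStamp(2006, 5, 14)),
                "b": EventTimes(start=TimeStamp(2006, 5, granularity=G.MONTH)),
            },
        )
        inferred = infer_relations(build_graph(doc))
        equal = [x for x in inferred if x.relation == Relation.EQUAL]
        assert equal and all(x.relation_granularity == G.MONTH for x in equal)

    def test_strict_cycle_reported_with_cycle(self):
        doc = doc_of(
            ["a", "b"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b"),
                TemporalAssertion("b", Relation.BEFORE, "a"),
            ],
        )
        with pytest.raises(InconsistencyError) as err:
            infer_relations(build_graph(doc))
        assert err.value.cycle

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        doc = random_relational_doc(rng)
        g = build_graph(doc)
        decided = {
            (x.subject, x.object): x.relation.value
            for x in doc.assertions
            if x.relation in (Relation.BEFORE, Relation.AFTER, Relation.EQUAL)
        }
        for x in infer_relations(g):
            decided[(x.subject, x.object)] = x.relation.value
        assert decided == oracle_event_relations(doc)


class TestPropagateTimestamps:
    def test_equality_copies_stamp(self, equal_pair_doc):
        g = propagate_timestamps(build_graph(equal_pair_doc))
        assert g.point_timestamps[S("E3")] == TimeStamp(2006, 4, 21)

    def test_offset_edge_computes_calendar_stamp(self):
        doc = doc_of(
            ["a", "b"],
            [TemporalAssertion("a", Relation.BEFORE, "b", offset=Duration(60, G.DAY))],
            timestamps={"a": EventTimes(end=TimeStamp(2006, 5, 1))},
        )
        g = propagate_timestamps(build_graph(doc))
        assert g.point_timestamps[S("b")] == TimeStamp(2006, 6, 30)

    def test_no_timestamps_is_a_fixpoint(self, implant_offset_doc):
        g = propagate_timestamps(build_graph(implant_offset_doc))
        assert g.point_timestamps == {}

    def test_conflicting_derivations_raise(self):
        doc = doc_of(
            ["a", "b"],
            [TemporalAssertion("a", Relation.EQUAL, "b")],
            timestamps={
                "a": EventTimes(start=TimeStamp(2006, 5, 1)),
                "b": EventTimes(start=TimeStamp(2006, 7, 1)),
            },
        )
        with pytest.raises(TimestampConflictError, match="timestamp conflict"):
            propagate_timestamps(build_graph(doc))

    def test_coarser_derivation_consistent_with_finer_stamp(self):
        # month-level derivation agrees with an existing day-level stamp
        doc = doc_of(
            ["a", "b"],
            [TemporalAssertion("a", Relation.EQUAL, "b")],
            timestamps={
                "a": EventTimes(start=TimeStamp(2006, 5, granularity=G.MONTH)),
                "b": EventTimes(start=TimeStamp(2006, 5, 14)),
            },
        )
        propagate_timestamps(build_graph(doc))  # no conflict


class TestEventDuration:
    def test_annotation_wins(self):
        doc = doc_of(["a"], [], durations={"a": Duration(2, G.MONTH)})
        assert event_duration(build_graph(doc), "a", G.MONTH) == Duration(2, G.MONTH)

    def test_month_truncation_of_day_offset(self, therapy_month_doc):
        g = propagate_timestamps(build_graph(therapy_month_doc))
        assert event_duration(g, "therapy", G.MONTH) == Duration(2, G.MONTH)

    def test_instantaneous_event_has_zero_duration(self):
        doc = doc_of(["a"], [])
        g = build_graph(doc, axioms=INSTANT_OTHER)
        assert event_duration(g, "a", G.DAY) == Duration(0, G.DAY)

    def test_unresolvable_raises_insufficient_information(self):
        with pytest.raises(InsufficientInformationError, match="insufficient information"):
            event_duration(build_graph(doc_of(["a"], [])), "a", G.DAY)

    def test_range_only_evidence_raises_insufficient_precision(self):
        doc = doc_of(
            ["a"], [], durations={"a": Duration(2, G.MONTH, is_range=True, range_high=3)}
        )
        with pytest.raises(InsufficientPrecisionError, match="insufficient precision"):
            event_duration(build_graph(doc), "a", G.MONTH)


class TestDurationBetween:
    def test_direct_offset(self, implant_offset_doc):
        g = build_graph(implant_offset_doc)
        assert duration_between(g, "implant", "discont", G.DAY) == Duration(60, G.DAY)

    def test_granular_relation_contributes_zero(self, granular_chain_doc):
        g = build_graph(granular_chain_doc, axioms=INSTANT_OTHER)
        assert duration_between(g, "e1", "e3", G.DAY) == Duration(183, G.DAY)

    def test_granular_relation_off_leaves_chain_unresolved(self, granular_chain_doc):
        g = build_graph(
            granular_chain_doc,
            axioms=INSTANT_OTHER,
            config=ReasonerConfig(granular_relations=False),
        )
        with pytest.raises(InsufficientInformationError):
            duration_between(g, "e1", "e3", G.DAY)

    def test_self_distance_is_zero(self, implant_offset_doc):
        g = build_graph(implant_offset_doc)
        assert duration_between(g, "implant", "implant", G.DAY) == Duration(0, G.DAY)

    def test_chain_sums_and_matches_simple_path_oracle(self):
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b", offset=Duration(1, G.MONTH)),
                TemporalAssertion("b", Relation.BEFORE, "c", offset=Duration(2, G.MONTH)),
            ],
        )
        g = build_graph(doc, axioms=INSTANT_OTHER)
        assert duration_between(g, "a", "c", G.MONTH) == Duration(3, G.MONTH)
        # independent oracle: event-level simple paths in networkx
        nxg = nx.Graph()
        nxg.add_edge("a", "b", months=1)
        nxg.add_edge("b", "c", months=2)
        sums = {
            sum(nxg[u][v]["months"] for u, v in zip(path, path[1:]))
            for path in nx.all_simple_paths(nxg, "a", "c")
        }
        assert sums == {3}

    def test_symmetric_magnitude(self, implant_offset_doc):
        g = build_graph(implant_offset_doc)
        assert duration_between(g, "discont", "implant", G.DAY) == Duration(60, G.DAY)

    def test_disagreeing_paths_rejected_not_averaged(self):
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b", offset=Duration(10, G.DAY)),
                TemporalAssertion("b", Relation.BEFORE, "c", offset=Duration(10, G.DAY)),
                TemporalAssertion("a", Relation.BEFORE, "c", offset=Duration(30, G.DAY)),
            ],
        )
        g = build_graph(doc, axioms=INSTANT_OTHER)
        with pytest.raises(InconsistentOffsetsError, match="inconsistent offsets"):
            duration_between(g, "a", "c", G.DAY)

    def test_paths_agreeing_at_output_unit_accepted(self):
        # 60 vs 61 days disagree at day scale but agree at month scale
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b", offset=Duration(30, G.DAY)),
                TemporalAssertion("b", Relation.BEFORE, "c", offset=Duration(30, G.DAY)),
                TemporalAssertion("a", Relation.BEFORE, "c", offset=Duration(61, G.DAY)),
            ],
        )
        g = build_graph(doc, axioms=INSTANT_OTHER)
        assert duration_between(g, "a", "c", G.MONTH) == Duration(2, G.MONTH)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_latent_positions_on_random_offset_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        doc, pos = random_offset_doc(rng)
        g = build_graph(doc, axioms=INSTANT_OTHER)
        for a, b in itertools.combinations(sorted(pos), 2):
            assert duration_between(g, a, b, G.DAY).magnitude == abs(pos[a] - pos[b])


class TestCheckConsistency:
    def test_direct_cycle(self):
        doc = doc_of(
            ["a", "b"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b"),
                TemporalAssertion("b", Relation.BEFORE, "a"),
            ],
        )
        report = check_consistency(build_graph(doc))
        assert not report.ok
        assert len(report.cycles) == 1

    def test_cycle_through_equality_chain(self):
        doc = doc_of(
            ["a", "b", "c"],
            [
                TemporalAssertion("a", Relation.BEFORE, "b"),
                TemporalAssertion("b", Relation.EQUAL, "c"),
                TemporalAssertion("c", Relation.BEFORE, "a"),
            ],
        )
        assert not check_consistency(build_graph(doc)).ok

    def test_consistent_fixture_reports_clean(self, therapy_month_doc):
        assert check_consistency(build_graph(therapy_month_doc)).ok

    def test_timestamp_conflicts_reported(self):
        doc = doc_of(
            ["a", "b"],
            [TemporalAssertion("a", Relation.EQUAL, "b")],
            timestamps={
                "a": EventTimes(start=TimeStamp(2006, 5, 1)),
                "b": EventTimes(start=TimeStamp(2007, 5, 1)),
            },
        )
        report = check_consistency(build_graph(doc))
        assert report.timestamp_conflicts


class TestClosureProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_under_added_assertions(self, seed):
        rng = np.random.default_rng(200 + seed)
        doc = random_relational_doc(rng)
        if len(doc.assertions) < 2:
            return
        smaller = AnnotatedDocument(
            doc_id="m", events=doc.events, assertions=doc.assertions[:-1]
        )

        def decided(d):
            core = (Relation.BEFORE, Relation.AFTER, Relation.EQUAL)
            out = {
                (x.subject, x.relation, x.object)
                for x in infer_relations(build_graph(d))
            }
            out |= {
                (x.subject, x.relation, x.object)
                for x in d.assertions
                if x.relation in core
            }
            return out

        assert decided(smaller) <= decided(doc)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_closure(self, seed):
        rng = np.random.default_rng(300 + seed)
        doc = random_relational_doc(rng)
        g = build_graph(doc)
        assert infer_relations(g) == infer_relations(g)
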