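"""Point-based temporal constraint reasoning over annotated documents.

Interval relations are compiled to constraints between event *start* and
*end* points, which turns relation inference into a reachability problem:
an event-level BEFORE is a strict path from one event's end point to the
other's start point, EQUAL is point identity of both endpoints.  Closure is
computed with a Floyd–Warshall pass over a three-valued edge algebra
(unrelated / ≤ / <); the networks here are tiny (two points per event), so
the quadratic matrix is the simplest correct representation.

Timestamps propagate along equality and exact-offset edges to a fixpoint;
stamps are only ever added or refined to a finer granularity, so the
iteration terminates, and two derivations that disagree by more than one
unit at their common granularity (the precision limit of coarse calendar
arithmetic) raise a ``timestamp conflict``.  Durations resolve through a
fixed evidence order —
explicit annotation, then start/end timestamps, then chaining along
exact-offset paths through intermediate events — mirroring how a reader
reconstructs a delay the narrative never states directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import (
    InconsistencyError,
    InconsistentOffsetsError,
    InsufficientInformationError,
    InsufficientPrecisionError,
    SchemaError,
    TimestampConflictError,
)
from .temporal_model import (
    AnnotatedDocument,
    Duration,
    Event,
    Granularity,
    MINUTES_PER_UNIT,
    Relation,
    TemporalAssertion,
    TimeStamp,
    add_duration,
    timestamp_difference,
    truncate,
)

__all__ = [
    "Point",
    "EdgeKind",
    "Edge",
    "DomainAxiomSet",
    "ReasonerConfig",
    "ConstraintGraph",
    "ConsistencyReport",
    "build_graph",
    "propagate_timestamps",
    "infer_relations",
    "event_duration",
    "duration_between",
    "check_consistency",
]

Point = Tuple[str, str]  # (event id or anchor id, "s" | "e")


class EdgeKind(Enum):
    EQ = "eq"          # same instant
    LT = "lt"          # strictly earlier, unknown distance
    LE = "le"          # earlier or simultaneous, unknown distance
    EXACT = "exact"    # exactly `offset` later (strict when offset > 0)
    GRAN = "gran"      # earlier-or-equal; distance 0 at `granularity`


@dataclass(frozen=True)
class Edge:
    u: Point
    v: Point
    kind: EdgeKind
    offset: Optional[Duration] = None
    granularity: Optional[Granularity] = None


@dataclass(frozen=True)
class DomainAxiomSet:
    """Background knowledge injected into the constraint graph.

    ``death_last`` encodes that a patient's death closes the care timeline;
    ``instantaneous_event_types`` collapses start and end points of event
    types that occur at a single point in time (a stent implantation does not
    span months).  Both are off unless requested.
    """

    death_last: bool = False
    instantaneous_event_types: FrozenSet[str] = frozenset()


#: Event types that occur at a single point in time in this domain —
#: everything except the antiplatelet-therapy interval and the open-ended
#: ``other`` category.
POINT_EVENT_TYPES = frozenset(
    {
        "stent_implantation",
        "followup_stent_implantation",
        "antiplatelet_start",
        "antiplatelet_stop",
        "unrelated_surgery",
        "late_stent_thrombosis",
        "myocardial_infarction",
        "er_admission",
        "death",
    }
)


def default_axioms() -> DomainAxiomSet:
    """Axiom set recommended for late-stent-thrombosis narratives."""
    return DomainAxiomSet(death_last=True, instantaneous_event_types=POINT_EVENT_TYPES)


@dataclass(frozen=True)
class ReasonerConfig:
    """Tunable reasoning behaviour.

    ``granular_relations`` enables the same-granularity-unit reading of
    un-offset BEFORE edges carrying a relation granularity ("before, at day
    granularity" = same day), which makes chains like "event2 plus 183 days"
    resolvable from event1.  ``out_unit`` is the default duration reporting
    unit (month, the dominant granularity in adverse-event narratives).
    """

    granular_relations: bool = True
    out_unit: Granularity = Granularity.MONTH
    dialect: str = "us"


class ConstraintGraph:
    """Working state of the reasoner for one document."""

    def __init__(
        self,
        doc: AnnotatedDocument,
        axioms: DomainAxiomSet,
        config: ReasonerConfig,
    ) -> None:
        self.doc = doc
        self.axioms = axioms
        self.config = config
        self.events: Dict[str, Event] = doc.event_index
        self.edges: List[Edge] = []
        self.point_timestamps: Dict[Point, TimeStamp] = {}
        self.event_durations: Dict[str, Duration] = dict(doc.event_durations)
        self._anchor_count = 0
        self._closure: Optional["_Closure"] = None

    # -- point helpers -------------------------------------------------------

    @staticmethod
    def start(eid: str) -> Point:
        return (eid, "s")

    @staticmethod
    def end(eid: str) -> Point:
        return (eid, "e")

    def points(self) -> List[Point]:
        pts: List[Point] = []
        for eid in self.events:
            pts.append(self.start(eid))
            pts.append(self.end(eid))
        for p in self.point_timestamps:
            if p not in pts:
                pts.append(p)
        return pts

    def add_edge(self, edge: Edge) -> None:
        self.edges.append(edge)
        self._closure = None

    def new_anchor(self, ts: TimeStamp) -> Point:
        """Anonymous point carrying a fixed timestamp (object-of-assertion times)."""
        self._anchor_count += 1
        p: Point = (f"@t{self._anchor_count}", "s")
        self.point_timestamps[p] = ts
        return p

    def copy(self) -> "ConstraintGraph":
        g = ConstraintGraph(self.doc, self.axioms, self.config)
        g.edges = list(self.edges)
        g.point_timestamps = dict(self.point_timestamps)
        g.event_durations = dict(self.event_durations)
        g._anchor_count = self._anchor_count
        return g

    def closure(self) -> "_Closure":
        if self._closure is None:
            self._closure = _Closure(self)
        return self._closure


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_graph(
    doc: AnnotatedDocument,
    axioms: Optional[DomainAxiomSet] = None,
    config: Optional[ReasonerConfig] = None,
) -> ConstraintGraph:
    """Compile a validated document into a point constraint graph.

    Relation mapping (a = subject, b = object): BEFORE → end(a) < start(b)
    (exact when an offset is given; distance-0-at-granularity when only a
    relation granularity is given and granular relations are enabled);
    EQUAL → start/end point identity; STARTS/FINISHES → one endpoint
    identity; DURING/CONTAINS → nested endpoint inequalities.  Event duration
    annotations become exact start→end offsets; axioms inject their
    constraints last.
    """
    doc.validate()
    axioms = axioms or DomainAxiomSet()
    config = config or ReasonerConfig()
    g = ConstraintGraph(doc, axioms, config)
    S, E = ConstraintGraph.start, ConstraintGraph.end

    for eid in g.events:
        g.add_edge(Edge(S(eid), E(eid), EdgeKind.LE))

    for eid, times in doc.event_timestamps.items():
        if times.start is not None:
            g.point_timestamps[S(eid)] = times.start
        if times.end is not None:
            g.point_timestamps[E(eid)] = times.end

    for eid, d in doc.event_durations.items():
        if d.is_range:
            if d.magnitude > 0:
                g.add_edge(Edge(S(eid), E(eid), EdgeKind.LT))
        else:
            g.add_edge(Edge(S(eid), E(eid), EdgeKind.EXACT, offset=d))

    for a in doc.assertions:
        _compile_assertion(g, a)

    for eid, ev in g.events.items():
        if ev.event_type in axioms.instantaneous_event_types:
            g.add_edge(Edge(S(eid), E(eid), EdgeKind.EQ))
    if axioms.death_last:
        deaths = [eid for eid, ev in g.events.items() if ev.event_type == "death"]
        for d_id in deaths:
            for eid in g.events:
                if eid != d_id:
                    g.add_edge(Edge(E(eid), S(d_id), EdgeKind.LT))
    return g


def _compile_assertion(g: ConstraintGraph, a: TemporalAssertion) -> None:
    if a.subject not in g.events:
        raise SchemaError(f"assertion references unknown event {a.subject!r}")
    S, E = ConstraintGraph.start, ConstraintGraph.end
    s_s, s_e = S(a.subject), E(a.subject)
    if isinstance(a.object, TimeStamp):
        anchor = g.new_anchor(a.object)
        o_s = o_e = anchor
    else:
        if a.object not in g.events:
            raise SchemaError(f"assertion references unknown event {a.object!r}")
        o_s, o_e = S(a.object), E(a.object)

    def before(earlier_end: Point, later_start: Point) -> None:
        if a.offset is not None:
            g.add_edge(
                Edge(
                    earlier_end,
                    later_start,
                    EdgeKind.EXACT,
                    offset=a.offset,
                    granularity=a.relation_granularity,
                )
            )
        elif a.relation_granularity is not None and g.config.granular_relations:
            g.add_edge(
                Edge(earlier_end, later_start, EdgeKind.GRAN, granularity=a.relation_granularity)
            )
        else:
            g.add_edge(Edge(earlier_end, later_start, EdgeKind.LT))

    rel = a.relation
    if rel == Relation.BEFORE:
        before(s_e, o_s)
    elif rel == Relation.AFTER:
        before(o_e, s_s)
    elif rel == Relation.EQUAL:
        g.add_edge(Edge(s_s, o_s, EdgeKind.EQ))
        g.add_edge(Edge(s_e, o_e, EdgeKind.EQ))
    elif rel == Relation.STARTS:
        g.add_edge(Edge(s_s, o_s, EdgeKind.EQ))
    elif rel == Relation.FINISHES:
        g.add_edge(Edge(s_e, o_e, EdgeKind.EQ))
    elif rel == Relation.DURING:
        g.add_edge(Edge(o_s, s_s, EdgeKind.LE))
        g.add_edge(Edge(s_e, o_e, EdgeKind.LE))
    elif rel == Relation.CONTAINS:
        g.add_edge(Edge(s_s, o_s, EdgeKind.LE))
        g.add_edge(Edge(o_e, s_e, EdgeKind.LE))
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unhandled relation {rel}")


# ---------------------------------------------------------------------------
# Closure over the three-valued point algebra
# ---------------------------------------------------------------------------

_NONE, _LE, _LT = 0, 1, 2


class _Closure:
    """Transitive closure of point order, with equality classes collapsed.

    Includes order edges derived from point timestamps: stamps strictly
    ordered at the coarser of their two granularities imply strict point
    order (every instant of May precedes every instant of July).
    """

    def __init__(self, g: ConstraintGraph) -> None:
        self.graph = g
        points = g.points()
        parent = {p: p for p in points}

        def find(p: Point) -> Point:
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        def union(a: Point, b: Point) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for e in g.edges:
            if e.kind == EdgeKind.EQ or (e.kind == EdgeKind.EXACT and e.offset.magnitude == 0):
                union(e.u, e.v)
        self._find = find
        reps = sorted({find(p) for p in points})
        index = {r: i for i, r in enumerate(reps)}
        self.reps = reps
        self._index = index
        m = len(reps)
        rel = [[_NONE] * m for _ in range(m)]
        for i in range(m):
            rel[i][i] = _LE

        def put(u: Point, v: Point, value: int) -> None:
            i, j = index[find(u)], index[find(v)]
            rel[i][j] = max(rel[i][j], value)

        self._base_edges: List[Tuple[int, int, int]] = []
        for e in g.edges:
            if e.kind == EdgeKind.LT:
                put(e.u, e.v, _LT)
            elif e.kind in (EdgeKind.LE, EdgeKind.GRAN):
                put(e.u, e.v, _LE)
            elif e.kind == EdgeKind.EXACT and e.offset.magnitude > 0:
                put(e.u, e.v, _LT)
        # order implied by timestamps (same-class pairs carry no order)
        stamped = list(g.point_timestamps.items())
        for (p, tp), (q, tq) in itertools.combinations(stamped, 2):
            if find(p) == find(q):
                continue
            gc = Granularity(max(tp.granularity, tq.granularity))
            a, b = truncate(tp, gc), truncate(tq, gc)
            if a.to_datetime() < b.to_datetime():
                put(p, q, _LT)
            elif b.to_datetime() < a.to_datetime():
                put(q, p, _LT)
        for k in range(m):
            rk = rel[k]
            for i in range(m):
                rik = rel[i][k]
                if rik:
                    ri = rel[i]
                    for j in range(m):
                        if rk[j]:
                            via = _LT if (rik == _LT or rk[j] == _LT) else _LE
                            if via > ri[j]:
                                ri[j] = via
        self._rel = rel
        self.strict_cycle: Optional[List[Point]] = None
        for i in range(m):
            if rel[i][i] == _LT:
                self.strict_cycle = self._find_cycle(reps[i])
                break

    def _find_cycle(self, rep: Point) -> List[Point]:
        """One shortest cycle through ``rep`` over the base (non-derived) edges."""
        g = self.graph
        adjacency: Dict[Point, List[Point]] = {}
        for e in g.edges:
            if e.kind == EdgeKind.EQ or (e.kind == EdgeKind.EXACT and e.offset.magnitude == 0):
                adjacency.setdefault(self._find(e.u), []).append(self._find(e.v))
                adjacency.setdefault(self._find(e.v), []).append(self._find(e.u))
            else:
                adjacency.setdefault(self._find(e.u), []).append(self._find(e.v))
        # BFS back to rep
        frontier = [(rep, [rep])]
        seen = {rep}
        while frontier:
            nxt = []
            for node, path in frontier:
                for succ in adjacency.get(node, []):
                    if succ == rep:
                        return path + [rep]
                    if succ not in seen:
                        seen.add(succ)
                        nxt.append((succ, path + [succ]))
            frontier = nxt
        return [rep, rep]

    # -- queries -------------------------------------------------------------

    def same(self, p: Point, q: Point) -> bool:
        # explicit equality, or ≤ in both directions (antisymmetry)
        if self._find(p) == self._find(q):
            return True
        return self._value(p, q) == _LE and self._value(q, p) == _LE

    def _value(self, p: Point, q: Point) -> int:
        i = self._index.get(self._find(p))
        j = self._index.get(self._find(q))
        if i is None or j is None:
            return _NONE
        return self._rel[i][j]

    def strict(self, p: Point, q: Point) -> bool:
        return self._value(p, q) == _LT

    def le(self, p: Point, q: Point) -> bool:
        return self._value(p, q) >= _LE


def _require_consistent(g: ConstraintGraph) -> _Closure:
    cl = g.closure()
    if cl.strict_cycle is not None:
        cycle = " -> ".join(f"{eid}.{role}" for eid, role in cl.strict_cycle)
        raise InconsistencyError(f"strict temporal cycle: {cycle}", cycle=cl.strict_cycle)
    return cl


# ---------------------------------------------------------------------------
# Timestamp propagation
# ---------------------------------------------------------------------------


def propagate_timestamps(g: ConstraintGraph) -> ConstraintGraph:
    """Fixpoint timestamp computation along equality and exact-offset edges.

    Equality copies stamps, exact offsets apply calendar arithmetic in either
    direction, and (when granular relations are enabled) a distance-0-at-g
    edge copies the stamp truncated to g.  Stamps are only ever added or
    refined to a finer granularity, so the iteration terminates.  Arithmetic
    performed at a coarse granularity is accurate to one unit of that
    granularity (unit conversion rounds), so two derivations are in conflict
    — :class:`TimestampConflictError` — only when they disagree by more than
    one unit at their common granularity; within that slack the finer (or
    first-derived) stamp is kept.
    """
    stamps = g.point_timestamps

    def assign(p: Point, ts: TimeStamp) -> bool:
        current = stamps.get(p)
        if current is None:
            stamps[p] = ts
            g._closure = None
            return True
        gc = Granularity(max(current.granularity, ts.granularity))
        if timestamp_difference(current, ts, gc).magnitude > 1:
            raise TimestampConflictError(
                f"timestamp conflict at {p[0]}.{p[1]}: "
                f"{current.isoformat()} vs {ts.isoformat()}"
            )
        if ts.granularity < current.granularity:
            stamps[p] = ts
            g._closure = None
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in g.edges:
            if e.kind == EdgeKind.EQ or (e.kind == EdgeKind.EXACT and e.offset.magnitude == 0):
                if e.u in stamps:
                    changed |= assign(e.v, stamps[e.u])
                if e.v in stamps:
                    changed |= assign(e.u, stamps[e.v])
            elif e.kind == EdgeKind.EXACT:
                if e.u in stamps:
                    changed |= assign(e.v, add_duration(stamps[e.u], e.offset, +1))
                if e.v in stamps:
                    changed |= assign(e.u, add_duration(stamps[e.v], e.offset, -1))
            elif e.kind == EdgeKind.GRAN and g.config.granular_relations:
                gr = e.granularity
                if e.u in stamps:
                    ts = stamps[e.u]
                    changed |= assign(e.v, truncate(ts, Granularity(max(gr, ts.granularity))))
                if e.v in stamps:
                    ts = stamps[e.v]
                    changed |= assign(e.u, truncate(ts, Granularity(max(gr, ts.granularity))))
    return g


# ---------------------------------------------------------------------------
# Relation inference
# ---------------------------------------------------------------------------


def infer_relations(g: ConstraintGraph) -> List[TemporalAssertion]:
    """Event-level relations decidable from the closed point network.

    Covers transitivity of order and equality, substitution of equality into
    order, inversion (every BEFORE has its AFTER twin), and relation
    derivation from timestamps: start stamps compared at the coarser of the
    two granularities yield BEFORE/AFTER when strictly ordered and EQUAL
    tagged with that granularity when they coincide at it.  Raises
    :class:`InconsistencyError` (with a minimal cycle) on strict cycles.
    """
    cl = _require_consistent(g)
    S, E = ConstraintGraph.start, ConstraintGraph.end
    stamps = g.point_timestamps
    asserted = {
        (a.subject, a.relation, a.object)
        for a in g.doc.assertions
        if a.asserted and isinstance(a.object, str)
    }
    out: List[TemporalAssertion] = []
    ids = list(g.events)
    for a, b in itertools.permutations(ids, 2):
        rel: Optional[Relation] = None
        rel_g: Optional[Granularity] = None
        if cl.strict(E(a), S(b)):
            rel = Relation.BEFORE
        elif cl.strict(E(b), S(a)):
            rel = Relation.AFTER
        elif cl.same(S(a), S(b)) and cl.same(E(a), E(b)):
            rel = Relation.EQUAL
        else:
            ta, tb = stamps.get(S(a)), stamps.get(S(b))
            if ta is not None and tb is not None:
                gc = Granularity(max(ta.granularity, tb.granularity))
                da, db = truncate(ta, gc).to_datetime(), truncate(tb, gc).to_datetime()
                if da < db:
                    rel = Relation.BEFORE
                elif db < da:
                    rel = Relation.AFTER
                else:
                    rel, rel_g = Relation.EQUAL, gc
        if rel is not None and (a, rel, b) not in asserted:
            out.append(
                TemporalAssertion(
                    subject=a,
                    relation=rel,
                    object=b,
                    relation_granularity=rel_g,
                    asserted=False,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Durations
# ---------------------------------------------------------------------------


def _exact_adjacency(g: ConstraintGraph) -> Dict[Point, List[Tuple[Point, int]]]:
    """Signed-minute adjacency over edges with exactly known distances."""
    adj: Dict[Point, List[Tuple[Point, int]]] = {}

    def link(u: Point, v: Point, minutes: int) -> None:
        adj.setdefault(u, []).append((v, minutes))
        adj.setdefault(v, []).append((u, -minutes))

    for e in g.edges:
        if e.kind == EdgeKind.EQ:
            link(e.u, e.v, 0)
        elif e.kind == EdgeKind.EXACT:
            link(e.u, e.v, e.offset.in_minutes())
        elif e.kind == EdgeKind.GRAN and g.config.granular_relations:
            link(e.u, e.v, 0)
    return adj


def _path_sums(
    g: ConstraintGraph,
    sources: Sequence[Point],
    targets: Set[Point],
    out_unit: Granularity,
) -> Set[int]:
    """Magnitudes (in ``out_unit``) of all simple exact paths source→target."""
    adj = _exact_adjacency(g)
    depth_cap = max(2 * len(g.events) + 2, 4)
    den = MINUTES_PER_UNIT[out_unit]
    sums: Set[int] = set()

    def dfs(node: Point, total: int, visited: Set[Point]) -> None:
        if node in targets:
            sums.add((2 * abs(total) + den) // (2 * den))
            return
        if len(visited) > depth_cap:
            return
        for succ, minutes in adj.get(node, []):
            if succ not in visited:
                visited.add(succ)
                dfs(succ, total + minutes, visited)
                visited.discard(succ)

    for src in sources:
        if src in targets:
            continue
        dfs(src, 0, {src})
    return sums


def event_duration(
    g: ConstraintGraph, eid: str, out_unit: Optional[Granularity] = None
) -> Duration:
    """Duration of one event, in ``out_unit``.

    Evidence order: (1) explicit duration annotation; (2) start and end
    timestamps, differenced at the coarser granularity; (3) chaining along
    exact-offset paths from the event's start point to its end point through
    related events.  Range-only evidence raises ``insufficient precision``;
    no evidence raises ``insufficient information``.
    """
    if eid not in g.events:
        raise SchemaError(f"unknown event {eid!r}")
    out_unit = out_unit or g.config.out_unit
    from .temporal_model import convert_duration

    annotated = g.event_durations.get(eid)
    range_only = annotated is not None and annotated.is_range
    if annotated is not None and not annotated.is_range:
        return convert_duration(annotated, out_unit)

    S, E = ConstraintGraph.start(eid), ConstraintGraph.end(eid)
    ts_s, ts_e = g.point_timestamps.get(S), g.point_timestamps.get(E)
    if ts_s is not None and ts_e is not None:
        return convert_duration(timestamp_difference(ts_s, ts_e), out_unit)

    sums = _path_sums(g, [S], {E}, out_unit)
    if len(sums) == 1:
        return Duration(sums.pop(), out_unit)
    if len(sums) > 1:
        raise InconsistentOffsetsError(
            f"inconsistent offsets for duration of {eid!r}: {sorted(sums)} {out_unit.label}s"
        )
    if range_only:
        raise InsufficientPrecisionError(
            f"insufficient precision: only a range duration is annotated for {eid!r}"
        )
    raise InsufficientInformationError(f"insufficient information for duration of {eid!r}")


def duration_between(
    g: ConstraintGraph, a: str, b: str, out_unit: Optional[Granularity] = None
) -> Duration:
    """Temporal distance between two events, in ``out_unit``.

    Evidence order: (1) both events timestamped → calendar difference of
    their start stamps at the coarser granularity; (2) sums over all simple
    exact-offset paths, from a direct edge up to chains through intermediate
    events — the paths must agree at ``out_unit``, disagreement is an error,
    never an average.
    """
    for eid in (a, b):
        if eid not in g.events:
            raise SchemaError(f"unknown event {eid!r}")
    out_unit = out_unit or g.config.out_unit
    from .temporal_model import convert_duration

    if a == b:
        return Duration(0, out_unit)

    S, E = ConstraintGraph.start, ConstraintGraph.end
    ts_a, ts_b = g.point_timestamps.get(S(a)), g.point_timestamps.get(S(b))
    if ts_a is not None and ts_b is not None:
        return convert_duration(timestamp_difference(ts_a, ts_b), out_unit)

    # a direct exact edge is the length-1 special case of the path search,
    # which also exposes longer paths that disagree with it
    a_points = {S(a), E(a)}
    b_points = {S(b), E(b)}
    sums = _path_sums(g, sorted(a_points), b_points, out_unit)
    if len(sums) == 1:
        return Duration(sums.pop(), out_unit)
    if len(sums) > 1:
        raise InconsistentOffsetsError(
            f"inconsistent offsets between {a!r} and {b!r}: {sorted(sums)} {out_unit.label}s"
        )
    ranged = any(
        g.event_durations.get(eid) is not None and g.event_durations[eid].is_range
        for eid in (a, b)
    )
    if ranged:
        raise InsufficientPrecisionError(
            f"insufficient precision: range-valued evidence between {a!r} and {b!r}"
        )
    raise InsufficientInformationError(f"insufficient information between {a!r} and {b!r}")


# ---------------------------------------------------------------------------
# Consistency reporting
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    """Strict cycles and timestamp conflicts found in a graph."""

    cycles: List[List[Point]] = field(default_factory=list)
    timestamp_conflicts: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.cycles and not self.timestamp_conflicts

    def __bool__(self) -> bool:  # truthy ⟺ consistent
        return self.ok


def check_consistency(g: ConstraintGraph) -> ConsistencyReport:
    """Non-raising consistency audit: cycles and timestamp conflicts."""
    report = ConsistencyReport()
    cl = g.closure()
    if cl.strict_cycle is not None:
        report.cycles.append(cl.strict_cycle)
    try:
        propagate_timestamps(g.copy())
    except TimestampConflictError as exc:
        report.timestamp_conflicts.append(str(exc))
    return report
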