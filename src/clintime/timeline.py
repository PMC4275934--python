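"""Sort events of a closed constraint graph into ordered timeline buckets.

A bucket collects events that begin together at the working granularity —
the annotation semantics ("occurred or began at the same time") cannot
distinguish occurrence from beginning, so ordering is by start points;
point-like events reduce to full interval equality.  Buckets are ordered by
strict start-point order and by timestamp comparison at the working
granularity.  A narrative whose events cannot be totally ordered yields a
partial-order result listing the incomparable pairs rather than a forced
guess.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .errors import InconsistencyError
from .reasoner import ConstraintGraph, _require_consistent
from .temporal_model import Granularity, TimeStamp, truncate

__all__ = ["TimelineBucket", "TimelineResult", "sort_timeline", "timeline_to_json"]


@dataclass(frozen=True)
class TimelineBucket:
    """Events simultaneous at the working granularity, with an ordinal position."""

    index: int
    events: Tuple[str, ...]
    anchor: Optional[TimeStamp] = None


@dataclass
class TimelineResult:
    """Ordered buckets; ``total`` is False when some pairs are incomparable."""

    buckets: List[TimelineBucket]
    total: bool
    incomparable_pairs: List[Tuple[str, str]] = field(default_factory=list)
    granularity: Optional[Granularity] = None

    def bucket_of(self, eid: str) -> Optional[int]:
        for b in self.buckets:
            if eid in b.events:
                return b.index
        return None


def _effective_stamp(
    g: ConstraintGraph, eid: str, working: Optional[Granularity]
) -> Optional[TimeStamp]:
    ts = g.point_timestamps.get(ConstraintGraph.start(eid))
    if ts is None:
        return None
    if working is not None and working > ts.granularity:
        return truncate(ts, working)
    return ts


def sort_timeline(
    g: ConstraintGraph, granularity: Optional[Granularity] = None
) -> TimelineResult:
    """Merge events into simultaneity classes and order the classes.

    ``granularity`` defaults to the coarsest granularity present among the
    document's timestamps (comparisons are only meaningful at the resolution
    every stamp can reach).  Deterministic: ties are broken by smallest event
    id, and incomparable pairs are reported sorted.
    """
    cl = _require_consistent(g)
    ids = sorted(g.events)
    if granularity is None and g.point_timestamps:
        granularity = Granularity(max(ts.granularity for ts in g.point_timestamps.values()))

    stamps = {eid: _effective_stamp(g, eid, granularity) for eid in ids}

    parent = {eid: eid for eid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    def stamp_cmp(sa: TimeStamp, sb: TimeStamp) -> int:
        # mixed granularities compare at the coarser of the two
        gc = Granularity(max(sa.granularity, sb.granularity))
        da, db = truncate(sa, gc).to_datetime(), truncate(sb, gc).to_datetime()
        return -1 if da < db else (1 if db < da else 0)

    S = ConstraintGraph.start
    for a, b in itertools.combinations(ids, 2):
        if cl.same(S(a), S(b)):
            union(a, b)
        elif stamps[a] is not None and stamps[b] is not None:
            if stamp_cmp(stamps[a], stamps[b]) == 0:
                union(a, b)

    groups: Dict[str, List[str]] = {}
    for eid in ids:
        groups.setdefault(find(eid), []).append(eid)

    def group_before(ga: str, gb: str) -> bool:
        for a in groups[ga]:
            for b in groups[gb]:
                if cl.strict(S(a), S(b)):
                    return True
                sa, sb = stamps[a], stamps[b]
                if sa is not None and sb is not None and stamp_cmp(sa, sb) < 0:
                    return True
        return False

    dag = nx.DiGraph()
    dag.add_nodes_from(groups)
    for ga, gb in itertools.permutations(groups, 2):
        if group_before(ga, gb):
            dag.add_edge(ga, gb)
    if not nx.is_directed_acyclic_graph(dag):
        raise InconsistencyError(
            "event order conflicts with simultaneity at the working granularity"
        )

    order = list(nx.lexicographical_topological_sort(dag))
    reach = {n: nx.descendants(dag, n) for n in dag.nodes}
    incomparable: List[Tuple[str, str]] = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        if gb not in reach[ga] and ga not in reach[gb]:
            for a in groups[ga]:
                for b in groups[gb]:
                    incomparable.append(tuple(sorted((a, b))))
    incomparable.sort()

    buckets = []
    for i, rep in enumerate(order):
        members = tuple(sorted(groups[rep]))
        anchors = [stamps[eid] for eid in members if stamps[eid] is not None]
        anchor = min(anchors, key=lambda t: t.to_datetime()) if anchors else None
        buckets.append(TimelineBucket(index=i, events=members, anchor=anchor))
    return TimelineResult(
        buckets=buckets,
        total=not incomparable,
        incomparable_pairs=incomparable,
        granularity=granularity,
    )


def timeline_to_json(result: TimelineResult) -> List[dict]:
    """JSON-ready bucket list: ``[{index, event_ids, anchor}, ...]``."""
    return [
        {
            "index": b.index,
            "event_ids": list(b.events),
            "anchor": b.anchor.isoformat() if b.anchor else None,
        }
        for b in result.buckets
    ]
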