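"""Independent brute-force oracles and random-document generators.

The oracles restate the interval→endpoint semantics directly as boolean
reachability matrices iterated to a fixpoint, sharing no code with the
package's closure engine.
"""

import itertools

import numpy as np

from clintime.temporal_model import (
    AnnotatedDocument,
    Duration,
    Event,
    Granularity,
    Relation,
    TemporalAssertion,
)


def oracle_event_relations(doc):
    """All BEFORE/AFTER/EQUAL pairs decidable by endpoint reachability.

    Returns a dict mapping ordered (a, b) id pairs to a relation name.
    """
    ids = [e.id for e in doc.events]
    pts = [(i, r) for i in ids for r in ("s", "e")]
    idx = {p: k for k, p in enumerate(pts)}
    m = len(pts)
    le = np.zeros((m, m), dtype=bool)  # includes strict
    lt = np.zeros((m, m), dtype=bool)
    np.fill_diagonal(le, True)

    def add_le(u, v):
        le[idx[u], idx[v]] = True

    def add_lt(u, v):
        lt[idx[u], idx[v]] = True
        le[idx[u], idx[v]] = True

    def add_eq(u, v):
        add_le(u, v)
        add_le(v, u)

    for i in ids:
        add_le((i, "s"), (i, "e"))
    for a in doc.assertions:
        s, o = a.subject, a.object
        if a.relation == Relation.BEFORE:
            add_lt((s, "e"), (o, "s"))
        elif a.relation == Relation.AFTER:
            add_lt((o, "e"), (s, "s"))
        elif a.relation == Relation.EQUAL:
            add_eq((s, "s"), (o, "s"))
            add_eq((s, "e"), (o, "e"))
        elif a.relation == Relation.STARTS:
            add_eq((s, "s"), (o, "s"))
        elif a.relation == Relation.FINISHES:
            add_eq((s, "e"), (o, "e"))
        elif a.relation == Relation.DURING:
            add_le((o, "s"), (s, "s"))
            add_le((s, "e"), (o, "e"))
        elif a.relation == Relation.CONTAINS:
            add_le((s, "s"), (o, "s"))
            add_le((o, "e"), (s, "e"))

    changed = True
    while changed:
        new_le = le | (le @ le)
        new_lt = lt | (lt @ le) | (le @ lt)
        changed = not (np.array_equal(new_le, le) and np.array_equal(new_lt, lt))
        le, lt = new_le, new_lt

    def eq(u, v):
        return le[idx[u], idx[v]] and le[idx[v], idx[u]]

    decided = {}
    for a, b in itertools.permutations(ids, 2):
        if lt[idx[(a, "e")], idx[(b, "s")]]:
            decided[(a, b)] = "BEFORE"
        elif lt[idx[(b, "e")], idx[(a, "s")]]:
            decided[(a, b)] = "AFTER"
        elif eq((a, "s"), (b, "s")) and eq((a, "e"), (b, "e")):
            decided[(a, b)] = "EQUAL"
    return decided


def random_relational_doc(rng, max_events=8):
    """Consistent-by-construction document sampled from latent intervals."""
    n = int(rng.integers(3, max_events + 1))
    ids = [f"ev{i}" for i in range(n)]
    starts = rng.integers(0, 10, n)
    ends = starts + rng.integers(0, 5, n)
    candidates = []
    for a, b in itertools.permutations(range(n), 2):
        if ends[a] < starts[b]:
            candidates.append((ids[a], Relation.BEFORE, ids[b]))
        if starts[a] == starts[b]:
            candidates.append((ids[a], Relation.STARTS, ids[b]))
        if ends[a] == ends[b]:
            candidates.append((ids[a], Relation.FINISHES, ids[b]))
        if starts[a] == starts[b] and ends[a] == ends[b] and a < b:
            candidates.append((ids[a], Relation.EQUAL, ids[b]))
        if starts[a] <= starts[b] and ends[b] <= ends[a]:
            candidates.append((ids[b], Relation.DURING, ids[a]))
    k = min(len(candidates), int(rng.integers(n, 2 * n + 1)))
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
    return AnnotatedDocument(
        doc_id="random-relational",
        events=[Event(i, "other") for i in ids],
        assertions=[TemporalAssertion(s, rel, o) for s, rel, o in chosen],
    )


def random_offset_doc(rng, max_events=6):
    """Connected offset graph from latent day positions; returns (doc, positions)."""
    n = int(rng.integers(3, max_events + 1))
    ids = [f"ev{i}" for i in range(n)]
    pos = {ids[i]: int(p) for i, p in enumerate(rng.choice(500, size=n, replace=False))}

    def link(a, b):
        if pos[a] == pos[b]:
            return TemporalAssertion(a, Relation.EQUAL, b)
        early, late = (a, b) if pos[a] < pos[b] else (b, a)
        return TemporalAssertion(
            early,
            Relation.BEFORE,
            late,
            offset=Duration(abs(pos[a] - pos[b]), Granularity.DAY),
        )

    assertions = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        assertions.append(link(ids[i], ids[j]))
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.choice(n, size=2, replace=False)
        assertions.append(link(ids[int(a)], ids[int(b)]))

    doc = AnnotatedDocument(
        doc_id="random-offsets",
        events=[Event(i, "other") for i in ids],
        assertions=assertions,
    )
    return doc, pos
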