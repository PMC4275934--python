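"""Score inferred timelines and durations against gold standards.

Two ordering metrics are reported: *strict* (the bucket sequence matches the
gold timeline exactly — the document-level "correctly ordered every event"
reading) and *pairwise* (fraction of event pairs whose relative order
matches), a finer diagnostic.  Duration scoring is exact-match at a working
unit (month by default, the dominant narrative granularity); predictions the
reasoner declines to make count as incorrect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .annotation_io import GoldStandard
from .errors import ClintimeError, SchemaError
from .pipeline import analyze
from .reasoner import DomainAxiomSet, ReasonerConfig, duration_between, event_duration
from .temporal_model import AnnotatedDocument, Duration, Granularity, convert_duration
from .timeline import TimelineResult

__all__ = [
    "EvaluationReport",
    "score_ordering",
    "score_durations",
    "evaluate_corpus",
]


@dataclass
class PerDocResult:
    doc_id: str
    ordered_ok: bool
    pairwise_ordering: float
    duration_errors: List[str] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Corpus-level accuracies with their denominators."""

    n_docs: int
    ordering_accuracy: float
    n_event_duration_docs: int
    event_duration_accuracy: float
    n_pair_duration_docs: int
    pair_duration_accuracy: float
    per_doc: List[PerDocResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_docs": self.n_docs,
            "ordering_accuracy": self.ordering_accuracy,
            "n_event_duration_docs": self.n_event_duration_docs,
            "event_duration_accuracy": self.event_duration_accuracy,
            "n_pair_duration_docs": self.n_pair_duration_docs,
            "pair_duration_accuracy": self.pair_duration_accuracy,
            "per_doc": [
                {
                    "doc_id": r.doc_id,
                    "ordered_ok": r.ordered_ok,
                    "pairwise_ordering": r.pairwise_ordering,
                    "duration_errors": r.duration_errors,
                }
                for r in self.per_doc
            ],
        }


def _bucket_indices(buckets: List[List[str]]) -> Dict[str, int]:
    return {eid: i for i, bucket in enumerate(buckets) for eid in bucket}


def score_ordering(
    predicted: Union[TimelineResult, List[List[str]]], gold: GoldStandard
) -> Dict[str, float]:
    """Compare a predicted timeline with the gold bucket sequence.

    Returns ``{"strict": bool, "pairwise": fraction}``.  Strict requires the
    bucket sequences to be identical (a partial-order prediction is strict-
    incorrect unless gold shows the same grouping and order); pairwise is the
    fraction of event pairs whose relative position (before/equal/after)
    matches gold, with incomparable predicted pairs counting as mismatches.
    """
    if isinstance(predicted, TimelineResult):
        pred_buckets = [sorted(b.events) for b in predicted.buckets]
        incomparable = set(predicted.incomparable_pairs)
    else:
        pred_buckets = [sorted(b) for b in predicted]
        incomparable = set()
    gold_buckets = [sorted(b) for b in gold.ordered_events]
    pred_ids = {eid for b in pred_buckets for eid in b}
    gold_ids = {eid for b in gold_buckets for eid in b}
    if pred_ids != gold_ids:
        raise SchemaError(
            f"event id universes differ: only-predicted={sorted(pred_ids - gold_ids)}, "
            f"only-gold={sorted(gold_ids - pred_ids)}"
        )

    strict = pred_buckets == gold_buckets and not incomparable

    pred_idx = _bucket_indices(pred_buckets)
    gold_idx = _bucket_indices(gold_buckets)
    ids = sorted(gold_ids)
    n_pairs = 0
    n_match = 0
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            n_pairs += 1
            if tuple(sorted((a, b))) in incomparable:
                continue
            sign_pred = (pred_idx[a] > pred_idx[b]) - (pred_idx[a] < pred_idx[b])
            sign_gold = (gold_idx[a] > gold_idx[b]) - (gold_idx[a] < gold_idx[b])
            if sign_pred == sign_gold:
                n_match += 1
    pairwise = n_match / n_pairs if n_pairs else 1.0
    return {"strict": strict, "pairwise": pairwise}


def score_durations(
    predicted: Dict, gold: Dict, unit: Granularity = Granularity.MONTH
) -> float:
    """Exact-match fraction of durations at the working unit.

    ``predicted`` maps the same keys as ``gold`` to :class:`Duration` values
    or to ``None`` / error strings for unresolvable cases, which count as
    incorrect.  Both sides are converted to ``unit`` before comparison.
    """
    if not gold:
        return 1.0
    n_match = 0
    for key, gold_d in gold.items():
        pred = predicted.get(key)
        if isinstance(pred, Duration) and not pred.is_range:
            if convert_duration(pred, unit).magnitude == convert_duration(gold_d, unit).magnitude:
                n_match += 1
    return n_match / len(gold)


def evaluate_corpus(
    pairs: Iterable[Tuple[AnnotatedDocument, Optional[GoldStandard]]],
    axioms: Optional[DomainAxiomSet] = None,
    config: Optional[ReasonerConfig] = None,
    granularity: Optional[Granularity] = None,
    unit: Granularity = Granularity.MONTH,
) -> EvaluationReport:
    """Run the pipeline over (document, gold) pairs and aggregate accuracies.

    Ordering accuracy is the fraction of documents whose bucket sequence is
    strictly correct.  Duration accuracies are per document: a document
    counts as correct when every gold duration it carries is matched exactly
    at ``unit``; denominators count only documents whose gold lists the
    respective kind of duration.  Documents without gold are skipped with a
    warning.
    """
    n_docs = 0
    n_ordered = 0
    n_ed_docs = 0
    n_ed_ok = 0
    n_pd_docs = 0
    n_pd_ok = 0
    per_doc: List[PerDocResult] = []

    for doc, gold in pairs:
        if gold is None:
            warnings.warn(f"no gold standard for document {doc.doc_id!r}; skipped")
            continue
        n_docs += 1
        result = analyze(doc, axioms=axioms, config=config, granularity=granularity)
        ordering = score_ordering(result.timeline, gold)
        errors: List[str] = []

        if gold.event_durations:
            n_ed_docs += 1
            predicted: Dict[str, Optional[Duration]] = {}
            for eid in gold.event_durations:
                try:
                    predicted[eid] = event_duration(result.graph, eid, unit)
                except ClintimeError as exc:
                    predicted[eid] = None
                    errors.append(f"event {eid}: {exc}")
            frac = score_durations(predicted, gold.event_durations, unit)
            if frac == 1.0:
                n_ed_ok += 1
            elif not errors:
                errors.append(f"event durations matched {frac:.2f}")

        if gold.pair_durations:
            n_pd_docs += 1
            predicted_pairs: Dict[Tuple[str, str], Optional[Duration]] = {}
            for (a, b) in gold.pair_durations:
                try:
                    predicted_pairs[(a, b)] = duration_between(result.graph, a, b, unit)
                except ClintimeError as exc:
                    predicted_pairs[(a, b)] = None
                    errors.append(f"pair {a}->{b}: {exc}")
            frac = score_durations(predicted_pairs, gold.pair_durations, unit)
            if frac == 1.0:
                n_pd_ok += 1
            elif not errors:
                errors.append(f"pair durations matched {frac:.2f}")

        if ordering["strict"]:
            n_ordered += 1
        per_doc.append(
            PerDocResult(
                doc_id=doc.doc_id,
                ordered_ok=bool(ordering["strict"]),
                pairwise_ordering=ordering["pairwise"],
                duration_errors=errors,
            )
        )

    if n_docs == 0:
        raise ClintimeError("no documents to evaluate")
    return EvaluationReport(
        n_docs=n_docs,
        ordering_accuracy=n_ordered / n_docs,
        n_event_duration_docs=n_ed_docs,
        event_duration_accuracy=(n_ed_ok / n_ed_docs) if n_ed_docs else 0.0,
        n_pair_duration_docs=n_pd_docs,
        pair_duration_accuracy=(n_pd_ok / n_pd_docs) if n_pd_docs else 0.0,
        per_doc=per_doc,
    )
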