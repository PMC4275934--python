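# Methods

This note documents the temporal model implemented by `clintime`, the
choices made where the design was genuinely open, what the synthetic corpus
does and does not emulate, and the known limitations.

## Granularity and calendar arithmetic

Narrative time is stated at mixed resolutions, so every `TimeStamp` and
`Duration` carries a granularity from the totally ordered set
minute < hour < day < month < year (coarser = greater). Operations follow
three rules:

1. **Comparisons happen at the coarser granularity of the operands.** Two
   stamps are compared after truncating both to the coarser of their
   granularities; "May 2006" and "2006-07-14" are ordered at month level.
2. **Arithmetic never manufactures precision.** Adding a duration to a
   stamp yields a result at the *coarser* of the two granularities: a
   60-day offset applied to a month stamp moves it two months; a 2-month
   offset applied to a day stamp yields a month-granularity result.
3. **Fixed unit conversions.** 1 year = 12 months, 1 month = 30 days,
   1 day = 24 hours, 1 hour = 60 minutes; conversion to a coarser unit
   rounds to the nearest integer with ties up. The 30-day month is a
   convention, not an empirical value: it makes day↔month conversion
   deterministic and keeps a "60 days" narrative equal to "2 months" at the
   month scale, which is the scale this domain reports at.

The calendar is proleptic Gregorian; month and year steps clamp the day of
month (Jan 31 + 1 month = Feb 28/29). Durations may be ranges
("2-3 months"); ranges are preserved, exported, and reported, but excluded
from arithmetic — a query whose only evidence is a range fails with
*insufficient precision* rather than guessing an endpoint.

### Precision of coarse arithmetic

A derivation chain that passes through a coarse granularity is accurate to
**one unit of that granularity**: converting 78 days to months rounds to 3,
so a month stamp plus 78 days can land one month away from the exact
day-level result. Timestamp propagation therefore treats two derivations of
the same point as conflicting only when they disagree by *more than* one
unit at their common granularity; within that slack the finer-granularity
stamp is kept (stamps are only ever added or refined finer, which
guarantees termination). The corollary is that a genuine one-unit
annotation contradiction (two sources placing an event in adjacent months)
is absorbed rather than flagged — the cost of doing arithmetic at the
granularity the narrative provides.

## Expression normalization

The normalizer is rule-based and total: it recognizes ISO forms at every
granularity, English month-name + year, US (or, per config, international)
slash dates, digit and number-word magnitudes (zero–twelve) with the five
units, and "N-M unit" ranges. Everything else returns an `unsupported`
result with a note instead of raising. Mixed-granularity compounds
("two month and ten days") are deliberately surfaced as unsupported — they
are a documented failure mode of this annotation style — unless
`resolve_mixed` is set, which converts to the finer unit under the 30-day
convention (70 days). Canonical re-serialization round-trips exactly, which
is what makes document writes byte-stable.

## The point constraint graph

Interval relations compile to constraints over two points per event. This
reformulation was chosen over composing interval relations directly because
it turns closure into plain reachability, which has a brute-force oracle
(boolean matrices iterated to fixpoint) that the test suite runs against
1,000 random documents. The closure algebra is three-valued — unrelated,
≤, < — closed with a Floyd–Warshall pass over equality-collapsed classes;
equality is explicit identity *or* ≤-antisymmetry (mutual DURING implies
EQUAL). A strict self-reachable class is an inconsistency and is reported
with a minimal cycle.

Two kinds of evidence extend the pure relation network:

- **Timestamps** add strict order edges between stamped points that are
  strictly ordered at their pairwise-coarser granularity (every instant of
  May precedes every instant of July). Stamp pairs inside one equality
  class are skipped: they may legitimately differ by the one-unit slack
  described above, and deriving order from them would fabricate a cycle.
- **Granular relations** ("event1 before event2, at day granularity") are,
  when enabled (default), read as *same day, in order*: a ≤ edge that
  contributes distance 0 at day granularity to duration chains and copies
  stamps truncated to that granularity. This turns the classic failure case
  — event3 narrated 183 days after event2, event1 same-day-before event2 —
  into a supported 183-day inference. The same-unit assumption is exactly
  that, an assumption; it can be switched off (`granular_relations=off`).

Event-level relations are read off the closed network: BEFORE is a strict
path end(*a*) → start(*b*), EQUAL is identity of both endpoint pairs, and
every derived BEFORE emits its AFTER twin. When the point network is
silent, events whose *start* (occurrence) stamps coincide at the coarser
granularity are reported EQUAL *tagged with that granularity*, and strictly
ordered start stamps yield BEFORE. This occurrence-time reading is the
right one for the narration style ("events occurred or began at the same
time") but it does mean a BEFORE derived purely from stamps orders
beginnings, not interval ends — for the one interval event in this domain
(antiplatelet therapy) such a relation should be read as "began before".
Undecidable pairs stay `unknown`; nothing is guessed.

## Durations

`event_duration` resolves in a fixed order: (1) an explicit non-range
duration annotation; (2) start and end stamps, differenced at their coarser
granularity; (3) the sum over simple exact-offset paths from the event's
start point to its end point. `duration_between` uses the events' start
stamps when both exist, otherwise all simple exact-offset paths between the
two events' points (a direct edge is the length-1 path). All paths must
agree *after conversion to the output unit* — 60 and 61 days agree at month
scale — and disagreement is an error (`inconsistent offsets`), never an
average: conflicting narrated distances are an annotation problem the user
must see. Path search is depth-capped at twice the event count; graphs here
have a handful of events, so exhaustive simple-path enumeration is
appropriate.

## Domain axioms

Two pieces of background knowledge are representable and off by default:
`death_last` (a strict edge from every other event's end into the death
event's start) and `instantaneous_event_types` (start = end). For
late-stent-thrombosis narratives the recommended set
(`default_axioms()`) marks every domain event type instantaneous except the
antiplatelet-therapy interval, and enables `death_last`. The instantaneous
axiom is what lets offset chains pass *through* a point event (its start
and end collapse), and the corpus evaluation pipeline uses it throughout.

## Timeline buckets

A bucket collects events that **begin together** at the working
granularity: point identity of starts, or coincident start stamps after
truncation. Bucketing by starts (rather than full interval equality) is
deliberate — the annotation semantics cannot distinguish "occurred" from
"began", and it gives interval events a well-defined place (therapy sits in
the bucket where it started). Buckets are ordered by strict start-point
order and stamp comparison; the result is a total order when every class
pair is comparable, otherwise a partial-order result listing the
incomparable pairs — a forced guess would silently corrupt downstream
scoring. Output is deterministic: ready classes are emitted smallest event
id first. The working granularity defaults to the coarsest granularity
present among the document's stamps, the finest level at which every stamp
can participate.

## Evaluation

Ordering is scored two ways: **strict** (the predicted bucket sequence
equals the gold sequence — the document-level "every event correctly
ordered" reading) and **pairwise** (fraction of event pairs whose relative
position matches; incomparable predicted pairs count as wrong). Duration
scoring is exact match at a working unit, month by default, with both sides
converted under the same 30-day convention; a prediction the reasoner
declines to make counts as incorrect. Corpus accuracies are per document: a
document is duration-correct only if every gold duration it carries
matches, and denominators count only documents whose gold lists that kind
of duration.

## Synthetic corpus

The generator stands in for the non-deposited narratives. Its latent
timeline is sampled at day granularity: implantation (day 0, therapy starts
the same day), therapy stop after a lognormal number of months, late stent
thrombosis at least 6 months post implant (the case definition), optional
same-day myocardial infarction and ER admission, optional strictly-last
death, optional unrelated surgery strictly between implant and thrombosis.

Defaults are anchored to the published marginals of the use case where any
exist, and are otherwise documented choices:

| parameter | default | basis |
| --- | --- | --- |
| therapy duration | lognormal, median 6.8 mo, σ=0.45 | puts ≈61% of cases at ≥6 months, the reported longer-group share (22/36) |
| implant→thrombosis | lognormal, median 14.6 mo, σ=0.55 | reported shorter-group median |
| `lst_group_effect` | 1.87 | ratio of reported group medians (27.3/14.6); the mechanism behind the survival demo's pattern |
| `p_surgery`, `p_mi`, `p_er`, `p_death` | 0.25 / 0.5 / 0.6 / 0.1 | not published; plausible for thrombosis presentations (MI and ER common at the event, death a minority) |
| style mix | month-heavy (0.35 absolute-month) | month was the dominant narrative granularity |
| `p_missing_duration`, `p_range_duration` | 0.15 / 0.05 | the documented exclusion and failure modes |

The latent truth is then *rendered* per an expression-style mix — absolute
day/month stamps, day- or month-valued offsets from the implantation
anchor, explicit duration annotations — so granularity truncation, rounded
offsets, missing and range durations arise exactly as annotation artifacts,
not as label noise. The gold standard always records the latent day-level
truth. A document is flagged `ambiguous` whenever any rendering choice may
under-determine order or a duration; the flag is conservative
(month-granularity styles always set it, even when no two events actually
collide).

Two properties define the generator's contract, both asserted by the test
suite: under `unambiguous_spec` (day-exact styles, no missing or range
durations) the reasoner recovers the gold ordering and every duration
exactly on all 238 documents; and document generation is counter-seeded
(substream per document index), so corpora are bit-reproducible regardless
of generation order.

What the generator does **not** emulate: narrative text itself (documents
are born annotated — annotation errors, NER misses and inter-annotator
disagreement are out of scope), reporting biases of a spontaneous-report
database, long chains of unannotated intermediate events, and censoring
(every synthetic case ends in thrombosis, as in the source data). Passing
tests therefore demonstrate the *reasoning* layer's correctness given
faithful annotations, not robustness to annotation noise.

## Survival demonstration

Documents whose reasoned output yields both a therapy duration and an
implant-to-thrombosis time at month granularity are split at 6 months of
therapy (exactly 6 months goes to the *longer* group, per the "6 or more
months" definition); the rest are excluded. The Kaplan–Meier estimator and
the log-rank test are implemented from their standard formulas
(product-limit; (ΣO−ΣE)²/ΣV against χ²₁) so the demo is dependency-light
and bit-reproducible, and both are cross-checked against `lifelines` to
1e-9 in the tests. The reported median is the smallest observed time with
S(t) ≤ 0.5 (with no censoring and even n this picks the upper middle order
statistic); a curve that never reaches 0.5 has median ∞.

## Numerical and degenerate-input choices

- Rounding: half-up on non-negative magnitudes everywhere
  (`floor(x + 0.5)`), implemented in integer arithmetic.
- Path sums are accumulated in exact integer minutes and converted to the
  output unit once, at the end.
- `duration_between(e, e)` is 0 in any unit; an empty corpus, an empty
  survival group, and an empty KM input are errors, not silent zeros.
- Zero-variance log-rank comparisons (identical groups) return statistic 0,
  p = 1.
- Tie-breaking is by event id everywhere an order is otherwise
  unconstrained, making every output deterministic for a given input.

## Known limitations

- The one-unit conflict slack (above) can absorb a genuine adjacent-unit
  annotation contradiction.
- Stamp-derived BEFORE orders occurrence times; it is not evidence that one
  interval *ended* before another began.
- The relation vocabulary omits OVERLAPS/MEETS; the annotation style this
  package targets never produces them, and CONTAINS/DURING are accepted
  mainly for completeness.
- Range durations are inert in arithmetic; a future interval-arithmetic
  extension could propagate them as bounds instead.
- No uncertainty or probabilistic reasoning: every assertion is treated as
  certain, and conflicts are errors rather than evidence to be weighed.
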