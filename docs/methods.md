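# Methods

## The annotation model

A corpus is a list of documents; a document carries raw text, ordered
non-overlapping sentence spans, typed entity spans, and events.  An
event is a trigger span (optional — triggerless events exist, e.g. an
implicit correlation linking two triggered events), an event-type label,
role-labelled participants referencing entities or other events, and a
`MetaKnowledge` record: one value for each of the five dimensions plus
per-dimension clue spans.  All offsets are 0-based, half-open, character
offsets into the document text.

The scheme's constraints are enforced by validation rather than by
construction, so files produced elsewhere can be checked:

* every dimension holds exactly one value from its enumeration;
* KT ∈ {Analysis, Investigation}, CL ≠ L3, Polarity = Negative and
  Manner ∈ {High, Low} each require at least one recorded clue span
  (errors).  Clues are optional for Fact and Observation, which are
  frequently expressed with no overt marker, and for Method, which is
  signalled by the trigger word itself;
* a clue span outside the trigger's sentence is a **warning**, not an
  error: clues can legitimately act at a distance, across long
  coordinations or from a neighbouring sentence;
* CL ≠ L3 on a non-Analysis event is likewise a warning.  Certainty
  grading is essentially a property of analytical claims, but a hard
  error would make rare legitimate annotations unrepresentable;
* unresolved participant references and reference cycles are reported as
  violations, never raised as exceptions mid-validation.

Hyper-dimension values (New Knowledge, Hypothesis) are never stored on
events or serialized; they are recomputed on demand from (Source, KT,
CL).  Storing them would allow the stored value and the inference rules
to drift apart.  The rules exist twice — as ordered wildcard tables
(authoritative) and as closed-form predicates — and the test suite
asserts their equivalence on all 2 × 6 × 3 = 36 input combinations,
along with the structural fact that New Knowledge and Hypothesis are
mutually exclusive (the former requires L3 Observation/Analysis, the
latter Investigation or non-L3 Analysis).

## File formats

The XML dialect is defined by this package (the original annotation
tooling's DTD is not public): `corpus → document → text / sentence /
term / event`, with the five dimension values as optional event
attributes (absent = default) and clue spans as `<clue dim from to>`
children.  The writer emits elements and attributes in a fixed order so
that equal corpora serialize to identical bytes; readers ignore unknown
elements and attributes with a logged warning but treat unknown category
labels and out-of-range spans as hard parse errors naming the document
and element.  The JSONL dialect stores one document per line with keys
mirroring the model.  Round-trip identity (`read(write(C)) == C`) is
fuzz-tested over generator-produced corpora in both dialects.

## The clue lexicon and baseline tagger

The packaged lexicon compiles the most frequently annotated clue
expressions per dimension, the event-type-conditioned negation clues
(*independent*/*independently* for Correlation/Regulation events,
*normal* contrasting a Negative_Regulation, *silent* contrasting a
Positive_Regulation), the Gene_Expression-specific High-manner clue
*overexpression*, and the productive numeric manner patterns
`{NUM}-fold` (High) and `{NUM}-fold less/lower` (Low).  Dual-role clues
are deliberate duplicates across dimensions: *suggest* and *indicate*
(and their inflections) express an analytical knowledge type and slight
speculation simultaneously, so one surface hit sets both KT = Analysis
and CL = L2.  The file is a documented five-column TSV so users can
extend it; entries carry a priority that is 0 almost everywhere
(explicit-Neutral manner markers carry −1 so an explicit High/Low
indication outbids them).

Matching tokenizes on words and numerals (hyphens split, so *3-fold*
is two tokens), is case-insensitive, and keeps only matches not
overlapped by a strictly longer match.  The longest-match rule is what
resolves the negation/manner interaction: in *"had no significant
influence"* the two-token Low-manner clue *no significant* suppresses
both the negation reading of *no* and the High reading of
*significant*, so the event stays Positive with Manner = Low.

The tagger is a deliberate lexical baseline.  Its scope is the trigger's
sentence; per dimension it takes the highest-priority eligible match,
breaking ties by distance to the trigger and then by position.  Because
priorities are flat, proximity is the effective arbiter when clues with
different values co-occur (*"suggested a less important role in the
rapid production"* → Low beats High at the *role* trigger).  An optional
tense heuristic (off by default, since tense is a tendency rather than a
definition) backs off clue-free KT to Observation for past-tense
triggers or Fact for present-tense ones.  Known limits, by design: no
syntactic analysis, so clue scope across coordinated triggers is not
resolved; no cross-sentence clue linking; no word-sense discrimination
(*addition* marks Method even in the connective *in addition*).

## Statistics

All percentage tables share one rounding function: round half up to one
decimal.  A handful of published reference cells are instead consistent
with truncation (e.g. 12821/36858 = 34.78% printed as 34.7%); the
implementation does not special-case them, and tests assert only cells
consistent with the documented rule.  Zero-count categories are always
listed — an empty category is a finding, not noise.  Cross-tabulations
report both the share of all events and the share within each KT
category, flagging empty denominators instead of dividing by zero.

## Agreement

Unweighted Cohen's κ = (p_o − p_e)/(1 − p_e) per dimension, with p_e
from the product of the two annotators' marginals.  CL's ordinal
structure is ignored (one unweighted number per dimension).  Events are
paired by id, falling back to (trigger span, event type); unpaired
events are excluded from κ and listed, since both annotations are meant
to cover the same fixed event set.  Degenerate case: p_e = 1 with
perfect agreement yields κ = 1; with imperfect agreement κ is undefined
and flagged (NaN) rather than forced to a number.  The implementation is
written directly from the formula because it must expose p_o and p_e;
`sklearn.metrics.cohen_kappa_score` serves as an independent
cross-check in the tests.

## Synthetic corpora

The generator emulates the *statistics* of an annotated abstract
collection, not its language.  Defaults encode the reference corpus
conditions: 1000 documents averaging ≈36.9 events each; KT marginal
(Observation .348, Other .313, Analysis .178, Fact .081, Investigation
.053, Method .026); CL conditional on KT with all non-L3 mass on
Analysis (L2 = 2216/6578, L1 = 766/6578); per-KT negation rates from
1.0% (Investigation, Method) to 10.6% (Observation); per-KT
explicit-manner rates of 0.2–8.9% split High:Low by the corpus-wide
1392:323 ratio (no per-KT split is published); Source = Other at 1.5%.
Each event occupies one template sentence with two protein-like
entities; spans are textually real even though the sentences are not
biologically meaningful prose.

Clue insertion is engineered for exact label recovery: per
(dimension, value) pools contain only lexicon patterns that are
unconditioned, fully literal, unique to that dimension and value, and
not a contiguous sub-sequence of a longer pattern, and consecutive
inserted clues are separated by a neutral filler token.  At the default
`clue_insertion_prob` of 1.0 the tagger therefore recovers every
generated label, which turns tagger tests into exact checks; distractor
sentences (event-free, containing clue words) verify the tagger's
sentence scope.  When the insertion probability is lowered, a
non-default value whose clue was withheld reverts to the dimension
default — keeping every generated corpus valid by construction — except
for the clue-optional Fact/Observation KT values, which are kept
clue-free; if an Analysis KT reverts, its non-L3 certainty reverts with
it.  This means marginals are exact at probability 1 and shift toward
the defaults below it, which the generator's documentation treats as
part of the condition being simulated, not as noise.

`perturb_annotations` drives the agreement tests: it relabels events
through per-dimension confusion matrices (rows must sum to 1), dropping
clue spans when a value becomes default and splicing an unambiguous
lexicon clue into the trigger's sentence (shifting all downstream spans)
when it becomes non-default, so perturbed corpora remain valid.

What passing synthetic tests does *not* show: performance on real prose.
Real sentences contain multiple events, long-distance and cross-sentence
clue–trigger links, sense-ambiguous cues, and clue scope governed by
syntax — exactly the phenomena the baseline tagger does not model.  The
synthetic results bound what a lexical baseline can do when the lexical
signal is clean, not what it does on MEDLINE abstracts.

## Problem sizes and numerical choices

Statistical tests run at sizes where their tolerances are meaningful
and the suite stays fast: marginal fidelity uses ≥50,000 events with a
1-percentage-point absolute band; agreement recovery uses ≥20,000
event pairs against the closed-form κ implied by the flip rate, with a
3σ binomial tolerance on p_o propagated through the κ formula;
round-trip fuzzing uses 200 small random corpora across both dialects.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no time-based entropy, and
identical (spec, seed) pairs produce byte-identical serialized corpora.
Probability vectors must sum to 1 within 1e−9.  Sort orders are total
and documented (violations by document then event id; distribution rows
by count then category name; clue frequencies by count then surface
form), so every report is deterministic.
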