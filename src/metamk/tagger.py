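"""Rule-based baseline tagger.

Assigns the five meta-knowledge dimensions to events from lexicon hits in
the trigger's sentence.  This is deliberately a lexical baseline: it does
not parse, and it links clues to events purely by sentence scope and
proximity, so semantic subtleties (long-distance clue-trigger links,
clue scope across coordinated triggers) are out of reach by design.

Precedence, per dimension: highest lexicon priority wins, then the match
nearest the trigger, then the leftmost.  Longer patterns beat shorter
ones already at match time, which resolves the negation/manner
interaction: *no significant* yields Manner=Low and never
Polarity=Negative.  An optional tense heuristic can back off KT to
Observation (past-tense trigger) or Fact (present-tense trigger) when no
KT clue fired; it is off by default since tense is a tendency, not a
definition.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .lexicon import ClueLexicon, ClueMatch, match_clues, tokenize
from .model import (
    AnnotatedEvent,
    Corpus,
    Dimension,
    Document,
    KTValue,
    MetaKnowledge,
    Span,
    default_metaknowledge,
)


@dataclass(frozen=True)
class TaggerOptions:
    tense_heuristic: bool = False


def _distance(a: Span, b: Span) -> int:
    if a.overlaps(b):
        return 0
    return a.start - b.end if a.start > b.end else b.start - a.end


def tag_event(
    event: AnnotatedEvent,
    doc: Document,
    lexicon: ClueLexicon,
    options: TaggerOptions = TaggerOptions(),
) -> MetaKnowledge:
    """Meta-knowledge for one event, from clues in the trigger's sentence.

    Triggerless events get the defaults: without a trigger there is no
    sentence scope to search and no anchor for proximity.
    """
    mk = default_metaknowledge()
    if event.trigger is None:
        return mk
    sentence = doc.sentence_containing(event.trigger)
    if sentence is None:
        return mk
    sentence_text = doc.text[sentence.start : sentence.end]
    matches = match_clues(sentence_text, sentence, lexicon)
    eligible = [m for m in matches if m.entry.applies_to(event.event_type)]

    for dim in Dimension:
        candidates = [m for m in eligible if m.entry.dimension is dim]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda m: (
                -m.entry.priority,
                _distance(m.span, event.trigger),
                m.span.start,
            ),
        )
        mk = mk.with_value(dim, best.entry.value)
        mk.clues[dim] = [best.span]

    if options.tense_heuristic and mk.kt is KTValue.OTHER and not mk.clues[Dimension.KT]:
        trigger_tokens = tokenize(doc.text[event.trigger.start : event.trigger.end])
        if trigger_tokens:
            word = trigger_tokens[0][0]
            if word.endswith("ed"):
                mk = mk.with_value(Dimension.KT, KTValue.OBSERVATION)
            elif word.endswith("s") and not word.endswith("ss"):
                mk = mk.with_value(Dimension.KT, KTValue.FACT)
    return mk


def tag_corpus(
    corpus: Corpus,
    lexicon: ClueLexicon,
    options: TaggerOptions = TaggerOptions(),
) -> Corpus:
    """A new corpus with every event's meta-knowledge re-assigned.

    The input corpus is left untouched; the tagger reads document text
    only, so the operation is idempotent.
    """
    tagged = copy.deepcopy(corpus)
    for doc in tagged.documents:
        for event in doc.events:
            event.mk = tag_event(event, doc, lexicon, options)
    return tagged
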