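"""Shared fixtures: lexicons, single-sentence documents, fixture corpora."""

from __future__ import annotations

import pytest

from metamk.lexicon import load_default_lexicon
from metamk.model import (
    AnnotatedEvent,
    CLValue,
    Corpus,
    Dimension,
    Document,
    KTValue,
    MetaKnowledge,
    Span,
)
from metamk.synthetic import default_paper_spec, generate


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def make_sentence_event():
    """Factory: a one-sentence document holding one triggered event."""

    def build(text: str, trigger_word: str, event_type: str = "Positive_Regulation"):
        offset = text.index(trigger_word)
        doc = Document(id="d1", text=text, sentences=[Span(0, len(text))])
        event = AnnotatedEvent(
            id="e1",
            event_type=event_type,
            trigger=Span(offset, offset + len(trigger_word)),
        )
        doc.events.append(event)
        return doc, event

    return build


@pytest.fixture(scope="session")
def paper_corpus():
    """~5,500 events drawn from the reference category distributions."""
    return generate(default_paper_spec(n_documents=150, seed=123))


def corpus_from_mk(records) -> Corpus:
    """One-document corpus whose events carry the given MetaKnowledge.

    The document text provides clue anchors so that clue-requiring values
    can be made valid: Analysis/Investigation KT, non-L3 CL, Negative
    polarity and non-Neutral manner point at the appropriate word below.
    """
    text = "suggest may not partially examined strongly previously ."
    anchors = {
        "suggest": Span(0, 7),
        "may": Span(8, 11),
        "not": Span(12, 15),
        "partially": Span(16, 25),
        "examined": Span(26, 34),
        "strongly": Span(35, 43),
        "previously": Span(44, 54),
    }
    doc = Document(id="d1", text=text, sentences=[Span(0, len(text))])
    for i, mk in enumerate(records):
        mk = mk.copy()
        if mk.kt is KTValue.ANALYSIS:
            mk.clues[Dimension.KT] = [anchors["suggest"]]
        elif mk.kt is KTValue.INVESTIGATION:
            mk.clues[Dimension.KT] = [anchors["examined"]]
        if mk.cl is CLValue.L2:
            mk.clues[Dimension.CL] = [anchors["suggest"]]
        elif mk.cl is CLValue.L1:
            mk.clues[Dimension.CL] = [anchors["may"]]
        if mk.polarity.value == "Negative":
            mk.clues[Dimension.POLARITY] = [anchors["not"]]
        if mk.manner.value == "High":
            mk.clues[Dimension.MANNER] = [anchors["strongly"]]
        elif mk.manner.value == "Low":
            mk.clues[Dimension.MANNER] = [anchors["partially"]]
        if mk.source.value == "Other":
            mk.clues[Dimension.SOURCE] = [anchors["previously"]]
        doc.events.append(AnnotatedEvent(id=f"e{i + 1}", mk=mk))
    return Corpus(documents=[doc])


def counts_corpus(dimension_counts) -> Corpus:
    """Corpus realizing exact per-(KT, CL, ...) MetaKnowledge counts.

    ``dimension_counts`` is an iterable of (MetaKnowledge prototype, count).
    """
    records = []
    for mk, n in dimension_counts:
        records.extend(mk.copy() for _ in range(n))
    return corpus_from_mk(records)


@pytest.fixture(scope="session")
def reconstruction_corpus():
    """36,858 events: KT counts per the reference KT table, with the
    L2/L1 certainty counts assigned to Analysis events and everything
    else at L3."""
    from metamk.synthetic import CL_COUNTS, KT_COUNTS

    counts = []
    for kt, n in KT_COUNTS.items():
        if kt is KTValue.ANALYSIS:
            l2, l1 = CL_COUNTS[CLValue.L2], CL_COUNTS[CLValue.L1]
            counts.append((MetaKnowledge(kt=kt, cl=CLValue.L2), l2))
            counts.append((MetaKnowledge(kt=kt, cl=CLValue.L1), l1))
            counts.append((MetaKnowledge(kt=kt, cl=CLValue.L3), n - l2 - l1))
        else:
            counts.append((MetaKnowledge(kt=kt), n))
    return counts_corpus(counts)
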