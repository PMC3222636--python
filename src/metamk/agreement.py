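"""Inter-annotator agreement: per-dimension Cohen's kappa and discrepancies.

Two independent annotations of the same fixed event set are compared
per dimension with unweighted Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where ``p_o`` is the observed proportion of agreeing event pairs and
``p_e`` the agreement expected by chance from the two annotators'
marginal category distributions.  CL's ordinal structure is deliberately
ignored (one unweighted number per dimension).  Events present in only
one annotation are excluded from kappa but reported as unmatched, since
both annotators are supposed to have labelled the same events.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .model import DIMENSION_VALUES, AnnotatedEvent, Corpus, Dimension


@dataclass(frozen=True)
class Discrepancy:
    document_id: str
    event_id: str
    dimension: Dimension
    value_a: str
    value_b: str
    clue_a: str | None
    clue_b: str | None


@dataclass(frozen=True)
class DimensionAgreement:
    kappa: float  # NaN when undefined (p_e = 1 with p_o < 1)
    p_o: float
    p_e: float
    n: int
    undefined: bool = False


@dataclass
class AgreementReport:
    dimensions: dict[Dimension, DimensionAgreement]
    discrepancies: list[Discrepancy]
    unmatched_a: list[tuple[str, str]] = field(default_factory=list)
    unmatched_b: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Alignment:
    pairs: list[tuple[str, AnnotatedEvent, AnnotatedEvent]]  # (doc_id, a, b)
    unmatched_a: list[tuple[str, str]]
    unmatched_b: list[tuple[str, str]]


def align_events(corpus_a: Corpus, corpus_b: Corpus) -> Alignment:
    """Pair events of two annotations of the same documents.

    Pairing is by event id first; events whose ids differ are then paired
    by (trigger span, event type).  The document sets must coincide.
    """
    docs_a = {d.id: d for d in corpus_a.documents}
    docs_b = {d.id: d for d in corpus_b.documents}
    if set(docs_a) != set(docs_b):
        diff = sorted(set(docs_a) ^ set(docs_b))
        raise ValueError(f"document sets differ: {diff}")
    pairs: list[tuple[str, AnnotatedEvent, AnnotatedEvent]] = []
    unmatched_a: list[tuple[str, str]] = []
    unmatched_b: list[tuple[str, str]] = []
    for doc_id in sorted(docs_a):
        events_a = docs_a[doc_id].events
        events_b = {ev.id: ev for ev in docs_b[doc_id].events}
        leftover_a: list[AnnotatedEvent] = []
        for ev in events_a:
            match = events_b.pop(ev.id, None)
            if match is not None:
                pairs.append((doc_id, ev, match))
            else:
                leftover_a.append(ev)
        by_signature = {
            (ev.trigger, ev.event_type): ev_id
            for ev_id, ev in events_b.items()
            if ev.trigger is not None
        }
        for ev in leftover_a:
            key = (ev.trigger, ev.event_type)
            if ev.trigger is not None and key in by_signature:
                pairs.append((doc_id, ev, events_b.pop(by_signature.pop(key))))
            else:
                unmatched_a.append((doc_id, ev.id))
        unmatched_b.extend((doc_id, ev_id) for ev_id in sorted(events_b))
    return Alignment(pairs, unmatched_a, unmatched_b)


def cohens_kappa(labels_a, labels_b, categories) -> tuple[float, float, float]:
    """Unweighted Cohen's kappa over two equal-length label sequences.

    Returns ``(kappa, p_o, p_e)``.  When both annotators use a single
    category throughout (p_e = 1): kappa is 1 if they agree perfectly,
    otherwise NaN (chance correction is undefined).
    """
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    if not labels_a:
        raise ValueError("need at least one label pair")
    categories = set(categories)
    for label in labels_a + labels_b:
        if label not in categories:
            raise ValueError(f"label {label!r} not in category set")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    marg_a = Counter(labels_a)
    marg_b = Counter(labels_b)
    p_e = sum((marg_a[c] / n) * (marg_b[c] / n) for c in categories)
    if p_e >= 1.0 - 1e-15:
        return (1.0, p_o, 1.0) if p_o >= 1.0 else (math.nan, p_o, 1.0)
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def _clue_surface(doc_text: str, event: AnnotatedEvent, dim: Dimension) -> str | None:
    spans = event.mk.clues.get(dim, [])
    if not spans:
        return None
    span = spans[0]
    if span.end <= len(doc_text):
        return doc_text[span.start : span.end]
    return None


def per_dimension_agreement(corpus_a: Corpus, corpus_b: Corpus) -> AgreementReport:
    """Agreement report over the aligned events of two annotations."""
    alignment = align_events(corpus_a, corpus_b)
    if not alignment.pairs:
        raise ValueError("no events could be aligned between the two corpora")
    texts_a = {d.id: d.text for d in corpus_a.documents}
    texts_b = {d.id: d.text for d in corpus_b.documents}
    dimensions: dict[Dimension, DimensionAgreement] = {}
    discrepancies: list[Discrepancy] = []
    for dim in Dimension:
        labels_a = [a.mk.value(dim).value for _, a, _ in alignment.pairs]
        labels_b = [b.mk.value(dim).value for _, _, b in alignment.pairs]
        categories = [v.value for v in DIMENSION_VALUES[dim]]
        kappa, p_o, p_e = cohens_kappa(labels_a, labels_b, categories)
        dimensions[dim] = DimensionAgreement(
            kappa=kappa, p_o=p_o, p_e=p_e, n=len(alignment.pairs),
            undefined=math.isnan(kappa),
        )
        for doc_id, ev_a, ev_b in alignment.pairs:
            if ev_a.mk.value(dim) is not ev_b.mk.value(dim):
                discrepancies.append(
                    Discrepancy(
                        document_id=doc_id,
                        event_id=ev_a.id,
                        dimension=dim,
                        value_a=ev_a.mk.value(dim).value,
                        value_b=ev_b.mk.value(dim).value,
                        clue_a=_clue_surface(texts_a[doc_id], ev_a, dim),
                        clue_b=_clue_surface(texts_b[doc_id], ev_b, dim),
                    )
                )
    discrepancies.sort(
        key=lambda d: (d.document_id, d.event_id, d.dimension.value)
    )
    return AgreementReport(
        dimensions=dimensions,
        discrepancies=discrepancies,
        unmatched_a=alignment.unmatched_a,
        unmatched_b=alignment.unmatched_b,
    )
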