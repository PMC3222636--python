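"""Data model for event-level meta-knowledge annotation.

A bio-event (trigger span, ontological type, role-labelled participants) is
enriched with a five-dimension meta-knowledge record:

* **Knowledge Type (KT)** — general information content: Investigation,
  Observation, Analysis, Method, Fact, or Other (default).
* **Certainty Level (CL)** — L3 (no expressed uncertainty, default), L2
  (slight hedging / frequent-but-not-always), L1 (considerable speculation /
  rare occurrence).
* **Polarity** — Positive (default) or Negative (the event is negated).
* **Manner** — expressed rate/strength/intensity: High, Low, or Neutral
  (default).
* **Source** — attribution to the Current study (default) or to Other
  (previous) work.

Non-default values on most dimensions are licensed by a *clue expression*
in the event's textual context; the model stores those clue spans per
dimension and :func:`validate_event` enforces the scheme's clue
requirements.  Analysis and Investigation events must carry a KT clue;
Fact and Observation events may be clue-free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class Dimension(enum.Enum):
    """The five annotated meta-knowledge dimensions."""

    KT = "KT"
    CL = "CL"
    POLARITY = "Polarity"
    MANNER = "Manner"
    SOURCE = "Source"


class KTValue(enum.Enum):
    INVESTIGATION = "Investigation"
    OBSERVATION = "Observation"
    ANALYSIS = "Analysis"
    METHOD = "Method"
    FACT = "Fact"
    OTHER = "Other"


class CLValue(enum.Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"


class PolarityValue(enum.Enum):
    POSITIVE = "Positive"
    NEGATIVE = "Negative"


class MannerValue(enum.Enum):
    HIGH = "High"
    LOW = "Low"
    NEUTRAL = "Neutral"


class SourceValue(enum.Enum):
    CURRENT = "Current"
    OTHER = "Other"


#: Value enumeration for each dimension.
DIMENSION_VALUES = {
    Dimension.KT: KTValue,
    Dimension.CL: CLValue,
    Dimension.POLARITY: PolarityValue,
    Dimension.MANNER: MannerValue,
    Dimension.SOURCE: SourceValue,
}

#: Scheme default per dimension.
DIMENSION_DEFAULTS = {
    Dimension.KT: KTValue.OTHER,
    Dimension.CL: CLValue.L3,
    Dimension.POLARITY: PolarityValue.POSITIVE,
    Dimension.MANNER: MannerValue.NEUTRAL,
    Dimension.SOURCE: SourceValue.CURRENT,
}

#: KT values whose assignment requires an annotated clue expression.
KT_CLUE_REQUIRED_VALUES = frozenset({KTValue.ANALYSIS, KTValue.INVESTIGATION})


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)`` over document text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MetaKnowledge:
    """One value per dimension plus the clue spans licensing each value."""

    kt: KTValue = KTValue.OTHER
    cl: CLValue = CLValue.L3
    polarity: PolarityValue = PolarityValue.POSITIVE
    manner: MannerValue = MannerValue.NEUTRAL
    source: SourceValue = SourceValue.CURRENT
    clues: dict[Dimension, list[Span]] = field(
        default_factory=lambda: {d: [] for d in Dimension}
    )

    def value(self, dimension: Dimension):
        return {
            Dimension.KT: self.kt,
            Dimension.CL: self.cl,
            Dimension.POLARITY: self.polarity,
            Dimension.MANNER: self.manner,
            Dimension.SOURCE: self.source,
        }[dimension]

    def with_value(self, dimension: Dimension, value) -> "MetaKnowledge":
        attr = {
            Dimension.KT: "kt",
            Dimension.CL: "cl",
            Dimension.POLARITY: "polarity",
            Dimension.MANNER: "manner",
            Dimension.SOURCE: "source",
        }[dimension]
        return replace(self, **{attr: value})

    def copy(self) -> "MetaKnowledge":
        return MetaKnowledge(
            kt=self.kt,
            cl=self.cl,
            polarity=self.polarity,
            manner=self.manner,
            source=self.source,
            clues={d: list(spans) for d, spans in self.clues.items()},
        )


def default_metaknowledge() -> MetaKnowledge:
    """Return the scheme defaults: (Other, L3, Positive, Neutral, Current).

    Each dimension's default is the value assigned in the absence of any
    explicit textual indication, so the returned record carries no clue
    spans and validates cleanly on a clue-free event.
    """
    return MetaKnowledge()


@dataclass
class Participant:
    """A role-labelled event participant (entity or nested event)."""

    role: str
    ref: str  # id of an Entity or of another AnnotatedEvent in the document


@dataclass
class Entity:
    id: str
    span: Span
    semantic_type: str = ""


@dataclass
class AnnotatedEvent:
    """A bio-event plus its meta-knowledge record.

    ``trigger`` may be ``None``: triggerless events occur, e.g. implicit
    correlation events linking two triggered events.
    """

    id: str
    event_type: str = ""
    trigger: Span | None = None
    participants: list[Participant] = field(default_factory=list)
    mk: MetaKnowledge = field(default_factory=default_metaknowledge)


@dataclass
class Document:
    id: str
    text: str = ""
    sentences: list[Span] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    events: list[AnnotatedEvent] = field(default_factory=list)

    def sentence_containing(self, span: Span) -> Span | None:
        """The sentence span containing ``span``, or None."""
        for sent in self.sentences:
            if sent.contains(span):
                return sent
        return None

    def event_by_id(self, event_id: str) -> AnnotatedEvent | None:
        for ev in self.events:
            if ev.id == event_id:
                return ev
        return None


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    @property
    def events(self):
        for doc in self.documents:
            yield from doc.events

    def n_events(self) -> int:
        return sum(len(doc.events) for doc in self.documents)


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    dimension: Dimension | None = None
    severity: Severity = Severity.ERROR
    document_id: str | None = None
    event_id: str | None = None


def _span_in_text(span: Span, text: str) -> bool:
    return 0 <= span.start < span.end <= len(text)


def validate_event(
    event: AnnotatedEvent,
    doc: Document,
    _context: tuple[set[str], dict[str, AnnotatedEvent]] | None = None,
) -> list[Violation]:
    """Check one event against the scheme invariants.

    Returns an empty list iff every invariant holds.  Clue requirements:
    KT in {Analysis, Investigation}, CL != L3, Polarity = Negative and
    Manner in {High, Low} each demand a recorded clue span.  A clue span
    outside the trigger's sentence is a warning only, since a clue in the
    extended context (possibly another sentence) can legitimately license
    a value.  Non-L3 certainty outside Analysis events is likewise a
    warning: certainty grading is essentially an Analysis phenomenon but
    the scheme tolerates rare exceptions.
    """
    out: list[Violation] = []
    mk = event.mk

    def add(code, message, dimension=None, severity=Severity.ERROR):
        out.append(
            Violation(code, message, dimension, severity, doc.id, event.id)
        )

    for dim, enum_cls in DIMENSION_VALUES.items():
        if not isinstance(mk.value(dim), enum_cls):
            add(
                "BAD_CATEGORY",
                f"{dim.value} value {mk.value(dim)!r} is not a {enum_cls.__name__}",
                dim,
            )

    trigger_sentence = None
    if event.trigger is not None:
        if not _span_in_text(event.trigger, doc.text):
            add("SPAN_OUT_OF_RANGE", f"trigger {event.trigger} outside document text")
        else:
            trigger_sentence = doc.sentence_containing(event.trigger)
            if doc.sentences and trigger_sentence is None:
                add("TRIGGER_CROSSES_SENTENCE", "trigger not within a single sentence")

    # clue requirements for non-default values
    if mk.kt in KT_CLUE_REQUIRED_VALUES and not mk.clues.get(Dimension.KT):
        add(
            "KT_CLUE_REQUIRED",
            f"KT={mk.kt.value} requires a clue expression",
            Dimension.KT,
        )
    if mk.cl is not CLValue.L3 and not mk.clues.get(Dimension.CL):
        add(
            "CL_CLUE_REQUIRED",
            f"CL={mk.cl.value} requires a clue expression",
            Dimension.CL,
        )
    if mk.polarity is PolarityValue.NEGATIVE and not mk.clues.get(Dimension.POLARITY):
        add(
            "POLARITY_CLUE_REQUIRED",
            "Polarity=Negative requires a clue expression",
            Dimension.POLARITY,
        )
    if mk.manner in (MannerValue.HIGH, MannerValue.LOW) and not mk.clues.get(
        Dimension.MANNER
    ):
        add(
            "MANNER_CLUE_REQUIRED",
            f"Manner={mk.manner.value} requires a clue expression",
            Dimension.MANNER,
        )

    if mk.cl is not CLValue.L3 and mk.kt is not KTValue.ANALYSIS:
        add(
            "CL_OUTSIDE_ANALYSIS",
            f"CL={mk.cl.value} on a KT={mk.kt.value} event",
            Dimension.CL,
            Severity.WARNING,
        )

    for dim, spans in mk.clues.items():
        for span in spans:
            if not _span_in_text(span, doc.text):
                add(
                    "SPAN_OUT_OF_RANGE",
                    f"{dim.value} clue {span} outside document text",
                    dim,
                )
            elif trigger_sentence is not None and not trigger_sentence.contains(span):
                add(
                    "CLUE_OUTSIDE_SENTENCE",
                    f"{dim.value} clue {span} outside the trigger's sentence",
                    dim,
                    Severity.WARNING,
                )

    if _context is None:
        known_ids = {e.id for e in doc.entities} | {e.id for e in doc.events}
        events_map = {e.id: e for e in doc.events}
    else:
        known_ids, events_map = _context
    for part in event.participants:
        if part.ref not in known_ids:
            add(
                "UNRESOLVED_PARTICIPANT",
                f"participant {part.role}={part.ref!r} does not resolve",
            )
    if event.participants and _participant_cycle(event, events_map):
        add("PARTICIPANT_CYCLE", "event participates in a reference cycle")

    return out


def _participant_cycle(
    event: AnnotatedEvent, events: dict[str, AnnotatedEvent]
) -> bool:
    seen: set[str] = set()

    def walk(eid: str) -> bool:
        if eid in seen:
            return True
        seen.add(eid)
        ev = events.get(eid)
        if ev is not None:
            for p in ev.participants:
                if p.ref in events and walk(p.ref):
                    return True
        seen.discard(eid)
        return False

    return walk(event.id)


def validate_corpus(corpus: Corpus) -> list[Violation]:
    """Structural plus per-event violations, ordered by (document, event)."""
    out: list[Violation] = []
    seen_docs: set[str] = set()
    for doc in sorted(corpus.documents, key=lambda d: d.id):
        if doc.id in seen_docs:
            out.append(
                Violation("DUPLICATE_DOC_ID", f"duplicate document id {doc.id!r}",
                          document_id=doc.id)
            )
        seen_docs.add(doc.id)
        prev_end = -1
        for sent in doc.sentences:
            if not _span_in_text(sent, doc.text):
                out.append(
                    Violation("SPAN_OUT_OF_RANGE", f"sentence {sent} outside text",
                              document_id=doc.id)
                )
            if sent.start < prev_end:
                out.append(
                    Violation("SENTENCE_ORDER",
                              "sentence spans overlap or are unordered",
                              document_id=doc.id)
                )
            prev_end = max(prev_end, sent.end)
        for ent in doc.entities:
            if not _span_in_text(ent.span, doc.text):
                out.append(
                    Violation("SPAN_OUT_OF_RANGE",
                              f"entity {ent.id} span outside text",
                              document_id=doc.id)
                )
        context = (
            {e.id for e in doc.entities} | {e.id for e in doc.events},
            {e.id: e for e in doc.events},
        )
        seen_events: set[str] = set()
        for ev in sorted(doc.events, key=lambda e: e.id):
            if ev.id in seen_events:
                out.append(
                    Violation("DUPLICATE_ID", f"duplicate event id {ev.id!r}",
                              document_id=doc.id, event_id=ev.id)
                )
                continue
            seen_events.add(ev.id)
            out.extend(validate_event(ev, doc, _context=context))
    return out


def validation_errors(violations: list[Violation]) -> list[Violation]:
    """Only the hard errors (warnings excluded)."""
    return [v for v in violations if v.severity is Severity.ERROR]
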