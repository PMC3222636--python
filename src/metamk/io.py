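"""Corpus I/O: GENIA-MK XML dialect and a JSON-lines interchange format.

The XML dialect::

    <corpus>
      <document id="d1">
        <text>...</text>
        <sentence from="0" to="40"/>
        <term id="T1" from="0" to="6" type="Protein"/>
        <event id="e1" type="Positive_Regulation"
               trigger_from="20" trigger_to="29"
               kt="Analysis" cl="L2">
          <participant role="Theme" ref="T1"/>
          <clue dim="KT" from="12" to="19"/>
        </event>
      </document>
    </corpus>

All five dimension attributes are optional; a missing attribute means the
scheme default, and the writer omits default values accordingly.  Derived
hyper-dimension values are never serialized.  The writer is
deterministic: identical corpora produce byte-identical files.

The JSONL dialect stores one document per line (UTF-8, LF), with keys
mirroring the data model and numeric offsets only.

Readers are tolerant of unknown elements/attributes (logged warning) but
strict about category labels and span ranges (hard parse errors naming
the document and element).
"""

from __future__ import annotations

import enum
import json
import logging
from pathlib import Path

from lxml import etree

from .model import (
    DIMENSION_DEFAULTS,
    DIMENSION_VALUES,
    AnnotatedEvent,
    Corpus,
    Dimension,
    Document,
    Entity,
    MetaKnowledge,
    Participant,
    Span,
    validate_corpus,
    validation_errors,
)

logger = logging.getLogger(__name__)

_MK_ATTRS = {
    "kt": Dimension.KT,
    "cl": Dimension.CL,
    "polarity": Dimension.POLARITY,
    "manner": Dimension.MANNER,
    "source": Dimension.SOURCE,
}

_KNOWN_EVENT_ATTRS = {"id", "type", "trigger_from", "trigger_to"} | set(_MK_ATTRS)


class FormatDialect(enum.Enum):
    GENIA_MK_XML = "genia-mk-xml"
    EVENT_JSONL = "jsonl"


class CorpusFormatError(ValueError):
    """Malformed input: bad XML/JSON, unknown category, span out of range."""


def read_corpus(path, dialect: FormatDialect) -> Corpus:
    path = Path(path)
    if dialect is FormatDialect.GENIA_MK_XML:
        return _read_xml(path)
    return _read_jsonl(path)


def write_corpus(corpus: Corpus, path, dialect: FormatDialect) -> None:
    """Serialize a corpus; refuses corpora with validation *errors*."""
    errors = validation_errors(validate_corpus(corpus))
    if errors:
        first = errors[0]
        raise ValueError(
            f"refusing to write invalid corpus: {first.code} ({first.message})"
        )
    path = Path(path)
    if dialect is FormatDialect.GENIA_MK_XML:
        _write_xml(corpus, path)
    else:
        _write_jsonl(corpus, path)


# ---------------------------------------------------------------- XML


def _parse_category(doc_id: str, where: str, dimension: Dimension, label: str):
    enum_cls = DIMENSION_VALUES[dimension]
    try:
        return enum_cls(label)
    except ValueError as exc:
        raise CorpusFormatError(
            f"document {doc_id!r}, {where}: unknown {dimension.value} "
            f"category {label!r}"
        ) from exc


def _parse_span(doc_id: str, where: str, start: str, end: str, text: str) -> Span:
    try:
        span = Span(int(start), int(end))
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(
            f"document {doc_id!r}, {where}: bad span ({start!r}, {end!r})"
        ) from exc
    if span.end > len(text):
        raise CorpusFormatError(
            f"document {doc_id!r}, {where}: span {span} outside text "
            f"(length {len(text)})"
        )
    return span


def _read_xml(path: Path) -> Corpus:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusFormatError(f"{path}: root element is {root.tag!r}, not 'corpus'")
    corpus = Corpus()
    for doc_el in root:
        if doc_el.tag is etree.Comment:
            continue
        if doc_el.tag != "document":
            logger.warning("ignoring unknown element <%s>", doc_el.tag)
            continue
        doc_id = doc_el.get("id", "")
        text_el = doc_el.find("text")
        text = text_el.text or "" if text_el is not None else ""
        doc = Document(id=doc_id, text=text)
        for child in doc_el:
            if child.tag == "text":
                continue
            if child.tag == "sentence":
                doc.sentences.append(
                    _parse_span(doc_id, "<sentence>", child.get("from"),
                                child.get("to"), text)
                )
            elif child.tag == "term":
                doc.entities.append(
                    Entity(
                        id=child.get("id", ""),
                        span=_parse_span(doc_id, f"<term {child.get('id')}>",
                                         child.get("from"), child.get("to"), text),
                        semantic_type=child.get("type", ""),
                    )
                )
            elif child.tag == "event":
                doc.events.append(_read_xml_event(child, doc_id, text))
            else:
                logger.warning(
                    "document %r: ignoring unknown element <%s>", doc_id, child.tag
                )
        corpus.documents.append(doc)
    return corpus


def _read_xml_event(el, doc_id: str, text: str) -> AnnotatedEvent:
    event_id = el.get("id", "")
    where = f"<event {event_id}>"
    for attr in el.keys():
        if attr not in _KNOWN_EVENT_ATTRS:
            logger.warning(
                "document %r, %s: ignoring unknown attribute %r", doc_id, where, attr
            )
    trigger = None
    if el.get("trigger_from") is not None:
        trigger = _parse_span(doc_id, where, el.get("trigger_from"),
                              el.get("trigger_to"), text)
    mk = MetaKnowledge()
    for attr, dim in _MK_ATTRS.items():
        label = el.get(attr)
        if label is not None:
            mk = mk.with_value(dim, _parse_category(doc_id, f"{where} @{attr}",
                                                    dim, label))
    event = AnnotatedEvent(id=event_id, event_type=el.get("type", ""),
                           trigger=trigger, mk=mk)
    for child in el:
        if child.tag == "participant":
            event.participants.append(
                Participant(role=child.get("role", ""), ref=child.get("ref", ""))
            )
        elif child.tag == "clue":
            dim_label = child.get("dim", "")
            try:
                dim = Dimension(dim_label)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"document {doc_id!r}, {where}: unknown clue dimension "
                    f"{dim_label!r}"
                ) from exc
            mk.clues[dim].append(
                _parse_span(doc_id, f"{where} <clue>", child.get("from"),
                            child.get("to"), text)
            )
        else:
            logger.warning(
                "document %r, %s: ignoring unknown element <%s>",
                doc_id, where, child.tag,
            )
    return event


def _write_xml(corpus: Corpus, path: Path) -> None:
    root = etree.Element("corpus")
    for doc in corpus.documents:
        doc_el = etree.SubElement(root, "document", id=doc.id)
        text_el = etree.SubElement(doc_el, "text")
        text_el.text = doc.text
        for sent in doc.sentences:
            etree.SubElement(doc_el, "sentence",
                             {"from": str(sent.start), "to": str(sent.end)})
        for ent in doc.entities:
            etree.SubElement(
                doc_el, "term",
                {"id": ent.id, "from": str(ent.span.start),
                 "to": str(ent.span.end), "type": ent.semantic_type},
            )
        for event in doc.events:
            attrs = {"id": event.id, "type": event.event_type}
            if event.trigger is not None:
                attrs["trigger_from"] = str(event.trigger.start)
                attrs["trigger_to"] = str(event.trigger.end)
            for attr, dim in _MK_ATTRS.items():
                value = event.mk.value(dim)
                if value is not DIMENSION_DEFAULTS[dim]:
                    attrs[attr] = value.value
            ev_el = etree.SubElement(doc_el, "event", attrs)
            for part in event.participants:
                etree.SubElement(ev_el, "participant",
                                 {"role": part.role, "ref": part.ref})
            for dim in Dimension:
                for span in event.mk.clues[dim]:
                    etree.SubElement(
                        ev_el, "clue",
                        {"dim": dim.value, "from": str(span.start),
                         "to": str(span.end)},
                    )
    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    path.write_bytes(payload)


# -------------------------------------------------------------- JSONL


def _doc_to_obj(doc: Document) -> dict:
    return {
        "id": doc.id,
        "text": doc.text,
        "sentences": [[s.start, s.end] for s in doc.sentences],
        "entities": [
            {"id": e.id, "span": [e.span.start, e.span.end],
             "type": e.semantic_type}
            for e in doc.entities
        ],
        "events": [
            {
                "id": ev.id,
                "type": ev.event_type,
                "trigger": (
                    [ev.trigger.start, ev.trigger.end]
                    if ev.trigger is not None else None
                ),
                "participants": [
                    {"role": p.role, "ref": p.ref} for p in ev.participants
                ],
                "mk": {
                    "kt": ev.mk.kt.value,
                    "cl": ev.mk.cl.value,
                    "polarity": ev.mk.polarity.value,
                    "manner": ev.mk.manner.value,
                    "source": ev.mk.source.value,
                    "clues": {
                        dim.value: [[s.start, s.end] for s in spans]
                        for dim, spans in ev.mk.clues.items()
                        if spans
                    },
                },
            }
            for ev in doc.events
        ],
    }


def _doc_from_obj(obj: dict) -> Document:
    doc_id = obj.get("id", "")
    text = obj.get("text", "")

    def span(pair, where) -> Span:
        return _parse_span(doc_id, where, str(pair[0]), str(pair[1]), text)

    doc = Document(
        id=doc_id,
        text=text,
        sentences=[span(p, "sentence") for p in obj.get("sentences", [])],
        entities=[
            Entity(id=e["id"], span=span(e["span"], f"entity {e['id']}"),
                   semantic_type=e.get("type", ""))
            for e in obj.get("entities", [])
        ],
    )
    for ev_obj in obj.get("events", []):
        mk_obj = ev_obj.get("mk", {})
        mk = MetaKnowledge()
        for key, dim in _MK_ATTRS.items():
            if key in mk_obj:
                mk = mk.with_value(
                    dim,
                    _parse_category(doc_id, f"event {ev_obj.get('id')}", dim,
                                    mk_obj[key]),
                )
        for dim_label, spans in mk_obj.get("clues", {}).items():
            try:
                dim = Dimension(dim_label)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"document {doc_id!r}, event {ev_obj.get('id')!r}: "
                    f"unknown clue dimension {dim_label!r}"
                ) from exc
            mk.clues[dim] = [span(p, "clue") for p in spans]
        doc.events.append(
            AnnotatedEvent(
                id=ev_obj.get("id", ""),
                event_type=ev_obj.get("type", ""),
                trigger=(
                    span(ev_obj["trigger"], "trigger")
                    if ev_obj.get("trigger") is not None else None
                ),
                participants=[
                    Participant(role=p["role"], ref=p["ref"])
                    for p in ev_obj.get("participants", [])
                ],
                mk=mk,
            )
        )
    return doc


def _read_jsonl(path: Path) -> Corpus:
    corpus = Corpus()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: bad JSON: {exc}") from exc
            corpus.documents.append(_doc_from_obj(obj))
    return corpus


def _write_jsonl(corpus: Corpus, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for doc in corpus.documents:
            handle.write(json.dumps(_doc_to_obj(doc), ensure_ascii=False))
            handle.write("\n")
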