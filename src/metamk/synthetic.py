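"""Seeded generator of valid annotated corpora, with ground truth.

The generator emulates the statistical shape of a meta-knowledge
annotated abstract collection — marginal and KT-conditional category
distributions, clue expressions placed in the trigger's sentence — not
its language.  Sentences are template-built::

    PROT12 then <clue...> then <clue...> activates PROT13 .

which is enough to make every span textually real (the validity of
offsets is the point; linguistic realism is a non-goal).  Each event
occupies its own sentence, with two protein entities as Cause and Theme.

Clue insertion is engineered so the assigned labels are exactly
recoverable from the text: the per-(dimension, value) clue pools contain
only lexicon patterns that are unconditioned, fully literal, unique to
that dimension and value, and not a contiguous sub-sequence of any
longer pattern; consecutive clues are separated by a neutral filler
token.  A distractor option adds event-free sentences containing clue
words, which a sentence-scoped tagger must ignore.

``default_paper_spec`` encodes the category proportions of the annotated
GENIA event corpus (36,858 events over 1000 abstracts): Observation
34.8% / Other 31.3% / Analysis 17.8% / Fact 8.1% / Investigation 5.3% /
Method 2.6% for KT; non-L3 certainty confined to Analysis (L2 = 2216 and
L1 = 766 of 6578 Analysis events); per-KT negation rates of 1.0-10.6%;
per-KT explicit-manner rates of 0.2-8.9% split High:Low as 1392:323;
and 1.5% Other-source events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lexicon import PLACEHOLDERS, ClueEntry, ClueLexicon, load_default_lexicon
from .model import (
    DIMENSION_DEFAULTS,
    AnnotatedEvent,
    CLValue,
    Corpus,
    Dimension,
    Document,
    Entity,
    KTValue,
    MannerValue,
    MetaKnowledge,
    Participant,
    PolarityValue,
    SourceValue,
    Span,
)

#: Corpus-wide totals of the reference annotation effort.
TOTAL_EVENTS = 36858
KT_COUNTS = {
    KTValue.OBSERVATION: 12821,
    KTValue.OTHER: 11537,
    KTValue.ANALYSIS: 6578,
    KTValue.FACT: 2998,
    KTValue.INVESTIGATION: 1948,
    KTValue.METHOD: 976,
}
CL_COUNTS = {CLValue.L3: 33876, CLValue.L2: 2216, CLValue.L1: 766}
NEGATED_BY_KT = {
    KTValue.OBSERVATION: 1364,
    KTValue.ANALYSIS: 577,
    KTValue.FACT: 105,
    KTValue.OTHER: 187,
    KTValue.METHOD: 10,
    KTValue.INVESTIGATION: 20,
}
EXPLICIT_MANNER_BY_KT = {
    KTValue.OBSERVATION: 1141,
    KTValue.ANALYSIS: 276,
    KTValue.FACT: 120,
    KTValue.OTHER: 171,
    KTValue.INVESTIGATION: 5,
    KTValue.METHOD: 2,
}
MANNER_HIGH_TOTAL = 1392
MANNER_LOW_TOTAL = 323
SOURCE_OTHER_TOTAL = 545

_TRIGGERS = ("activates", "binds", "phosphorylates", "regulates", "modulates")
_EVENT_TYPES = (
    "Positive_Regulation",
    "Negative_Regulation",
    "Regulation",
    "Gene_Expression",
    "Binding",
    "Correlation",
    "Phosphorylation",
)
_FILLER = "then"  # appears in no lexicon pattern


@dataclass
class GenerationSpec:
    """Study conditions for corpus generation (all distributions explicit)."""

    n_documents: int = 1000
    events_per_doc: float = TOTAL_EVENTS / 1000  # Poisson mean, min 1
    kt_marginal: dict[KTValue, float] = field(default_factory=dict)
    cl_given_kt: dict[KTValue, dict[CLValue, float]] = field(default_factory=dict)
    polarity_given_kt: dict[KTValue, dict[PolarityValue, float]] = field(
        default_factory=dict
    )
    manner_given_kt: dict[KTValue, dict[MannerValue, float]] = field(
        default_factory=dict
    )
    source_marginal: dict[SourceValue, float] = field(default_factory=dict)
    clue_insertion_prob: dict[Dimension, float] = field(
        default_factory=lambda: {d: 1.0 for d in Dimension}
    )
    distractor_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        def check(vec: dict, what: str) -> None:
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} sums to {total}, not 1")
            if any(p < 0 for p in vec.values()):
                raise ValueError(f"{what} has negative mass")

        check(self.kt_marginal, "kt_marginal")
        check(self.source_marginal, "source_marginal")
        for kt in self.kt_marginal:
            check(self.cl_given_kt[kt], f"cl_given_kt[{kt.value}]")
            check(self.polarity_given_kt[kt], f"polarity_given_kt[{kt.value}]")
            check(self.manner_given_kt[kt], f"manner_given_kt[{kt.value}]")
        for dim, p in self.clue_insertion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"clue_insertion_prob[{dim.value}] = {p}")
        if not 0.0 <= self.distractor_prob <= 1.0:
            raise ValueError(f"distractor_prob = {self.distractor_prob}")


def default_paper_spec(
    n_documents: int = 1000, seed: int = 0
) -> GenerationSpec:
    """Generation spec whose marginals equal the reference proportions.

    Non-L3 certainty mass is confined to Analysis events (certainty
    grading is an Analysis phenomenon in the reference annotation), and
    the per-KT explicit-manner mass is split between High and Low by the
    corpus-wide 1392:323 ratio, since no per-KT split is available.
    """
    kt_marginal = {kt: n / TOTAL_EVENTS for kt, n in KT_COUNTS.items()}
    cl_given_kt = {}
    for kt in KT_COUNTS:
        if kt is KTValue.ANALYSIS:
            n_analysis = KT_COUNTS[kt]
            l2 = CL_COUNTS[CLValue.L2] / n_analysis
            l1 = CL_COUNTS[CLValue.L1] / n_analysis
            cl_given_kt[kt] = {
                CLValue.L3: 1.0 - l2 - l1, CLValue.L2: l2, CLValue.L1: l1,
            }
        else:
            cl_given_kt[kt] = {CLValue.L3: 1.0, CLValue.L2: 0.0, CLValue.L1: 0.0}
    polarity_given_kt = {
        kt: {
            PolarityValue.NEGATIVE: NEGATED_BY_KT[kt] / n,
            PolarityValue.POSITIVE: 1.0 - NEGATED_BY_KT[kt] / n,
        }
        for kt, n in KT_COUNTS.items()
    }
    high_share = MANNER_HIGH_TOTAL / (MANNER_HIGH_TOTAL + MANNER_LOW_TOTAL)
    manner_given_kt = {}
    for kt, n in KT_COUNTS.items():
        explicit = EXPLICIT_MANNER_BY_KT[kt] / n
        manner_given_kt[kt] = {
            MannerValue.HIGH: explicit * high_share,
            MannerValue.LOW: explicit * (1.0 - high_share),
            MannerValue.NEUTRAL: 1.0 - explicit,
        }
    source_marginal = {
        SourceValue.OTHER: SOURCE_OTHER_TOTAL / TOTAL_EVENTS,
        SourceValue.CURRENT: 1.0 - SOURCE_OTHER_TOTAL / TOTAL_EVENTS,
    }
    return GenerationSpec(
        n_documents=n_documents,
        kt_marginal=kt_marginal,
        cl_given_kt=cl_given_kt,
        polarity_given_kt=polarity_given_kt,
        manner_given_kt=manner_given_kt,
        source_marginal=source_marginal,
        seed=seed,
    )


# ------------------------------------------------------- clue pools


def _safe_clue_pools(lexicon: ClueLexicon) -> dict[tuple[Dimension, object], list[str]]:
    """Unambiguous clue surfaces per (dimension, value).

    A pattern qualifies iff it is unconditioned, contains no placeholder,
    maps to exactly one (dimension, value) in the lexicon, and its token
    sequence is not contained contiguously in any longer pattern.  Such
    clues can be dropped into a sentence without licensing any reading
    other than the intended one.
    """
    by_tokens: dict[tuple[str, ...], list[ClueEntry]] = {}
    for entry in lexicon.entries:
        by_tokens.setdefault(entry.pattern.tokens, []).append(entry)
    all_token_seqs = list(by_tokens)

    def contained_in_longer(tokens: tuple[str, ...]) -> bool:
        n = len(tokens)
        for other in all_token_seqs:
            if len(other) <= n:
                continue
            if any(other[i : i + n] == tokens for i in range(len(other) - n + 1)):
                return True
        return False

    pools: dict[tuple[Dimension, object], list[str]] = {}
    for tokens, entries in by_tokens.items():
        if len(entries) != 1:
            continue
        entry = entries[0]
        if entry.event_types is not None:
            continue
        if any(t in PLACEHOLDERS for t in tokens):
            continue
        if contained_in_longer(tokens):
            continue
        pools.setdefault((entry.dimension, entry.value), []).append(" ".join(tokens))
    for surfaces in pools.values():
        surfaces.sort()
    return pools


_CLUE_OPTIONAL_KT = frozenset({KTValue.FACT, KTValue.OBSERVATION})


def _sample(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


# --------------------------------------------------------- generate


def generate(spec: GenerationSpec) -> Corpus:
    """Deterministically generate a valid annotated corpus.

    The annotations stored on the events *are* the ground truth; the
    corpus files themselves never carry derived hyper-dimension values.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lexicon = load_default_lexicon()
    pools = _safe_clue_pools(lexicon)
    distractor_surfaces = sorted(
        {s for surfaces in pools.values() for s in surfaces}
    )
    corpus = Corpus()
    for doc_index in range(spec.n_documents):
        doc = Document(id=f"d{doc_index + 1:04d}")
        n_events = max(1, int(rng.poisson(spec.events_per_doc)))
        parts: list[str] = []
        cursor = 0
        entity_counter = 0

        def add_word(word: str) -> tuple[int, int]:
            nonlocal cursor
            if parts and not parts[-1].endswith(" "):
                parts.append(" ")
                cursor += 1
            start = cursor
            parts.append(word)
            cursor += len(word)
            return start, cursor

        for ev_index in range(n_events):
            mk, clue_phrases = _sample_event_mk(spec, rng, pools)
            sent_start = cursor + 1 if parts else 0
            if parts:
                parts.append(" ")
                cursor += 1
            entity_counter += 1
            subj_name = f"PROT{doc_index + 1}x{entity_counter}"
            subj_span = Span(*add_word(subj_name))
            clue_spans: dict[Dimension, Span] = {}
            for i, (dim, phrase) in enumerate(clue_phrases):
                if i > 0:
                    add_word(_FILLER)
                first = last = None
                for w in phrase.split():
                    s, e = add_word(w)
                    first = s if first is None else first
                    last = e
                clue_spans[dim] = Span(first, last)
            trigger_word = _TRIGGERS[int(rng.integers(len(_TRIGGERS)))]
            trig_span = Span(*add_word(trigger_word))
            entity_counter += 1
            obj_name = f"PROT{doc_index + 1}x{entity_counter}"
            obj_span = Span(*add_word(obj_name))
            _, sent_end = add_word(".")
            doc.sentences.append(Span(sent_start, sent_end))
            subj = Entity(f"T{len(doc.entities) + 1}", subj_span, "Protein")
            doc.entities.append(subj)
            obj = Entity(f"T{len(doc.entities) + 1}", obj_span, "Protein")
            doc.entities.append(obj)
            for dim, span in clue_spans.items():
                mk.clues[dim].append(span)
            event_type = _pick_event_type(rng, mk)
            doc.events.append(
                AnnotatedEvent(
                    id=f"e{ev_index + 1}",
                    event_type=event_type,
                    trigger=trig_span,
                    participants=[
                        Participant("Cause", subj.id),
                        Participant("Theme", obj.id),
                    ],
                    mk=mk,
                )
            )
            if spec.distractor_prob > 0 and rng.random() < spec.distractor_prob:
                d_start = cursor + 1
                parts.append(" ")
                cursor += 1
                add_word("It")
                add_word("was")
                surface = distractor_surfaces[
                    int(rng.integers(len(distractor_surfaces)))
                ]
                for w in surface.split():
                    add_word(w)
                add_word("overall")
                _, d_end = add_word(".")
                doc.sentences.append(Span(d_start, d_end))
        doc.text = "".join(parts)
        corpus.documents.append(doc)
    return corpus


def _sample_event_mk(
    spec: GenerationSpec,
    rng: np.random.Generator,
    pools: dict[tuple[Dimension, object], list[str]],
) -> tuple[MetaKnowledge, list[tuple[Dimension, str]]]:
    """Sample one event's labels and the clue phrases to realize them.

    For a non-default value whose clue fails the insertion coin: values
    that *require* a clue revert to the dimension default (keeping the
    corpus valid by construction); clue-optional KT values (Fact,
    Observation) are kept without a clue.
    """
    kt = _sample(rng, spec.kt_marginal)
    cl = _sample(rng, spec.cl_given_kt[kt])
    polarity = _sample(rng, spec.polarity_given_kt[kt])
    manner = _sample(rng, spec.manner_given_kt[kt])
    source = _sample(rng, spec.source_marginal)
    mk = MetaKnowledge(kt=kt, cl=cl, polarity=polarity, manner=manner, source=source)
    clue_phrases: list[tuple[Dimension, str]] = []
    kt_reverted = False
    for dim in Dimension:
        value = mk.value(dim)
        if value is DIMENSION_DEFAULTS[dim]:
            continue
        if dim is Dimension.CL and kt_reverted:
            # keep non-L3 certainty confined to Analysis events
            mk = mk.with_value(dim, DIMENSION_DEFAULTS[dim])
            continue
        wants_clue = rng.random() < spec.clue_insertion_prob[dim]
        if wants_clue:
            pool = pools[(dim, value)]
            clue_phrases.append((dim, pool[int(rng.integers(len(pool)))]))
        elif not (dim is Dimension.KT and value in _CLUE_OPTIONAL_KT):
            mk = mk.with_value(dim, DIMENSION_DEFAULTS[dim])
            if dim is Dimension.KT and kt is KTValue.ANALYSIS:
                kt_reverted = True
    return mk, clue_phrases


def _pick_event_type(rng: np.random.Generator, mk: MetaKnowledge) -> str:
    return _EVENT_TYPES[int(rng.integers(len(_EVENT_TYPES)))]


# ---------------------------------------------------------- perturb


def perturb_annotations(
    corpus: Corpus,
    confusion: dict[Dimension, dict[object, dict[object, float]]],
    seed: int,
) -> Corpus:
    """Independently relabel events through per-dimension confusion matrices.

    ``confusion[dim][true][observed]`` is the probability that an event
    whose true value is ``true`` is annotated ``observed``; rows must sum
    to 1 and omitted dimensions are left untouched.  Clue spans are
    adjusted to keep the result valid: the clue is dropped when a value
    becomes the default, and an unambiguous lexicon clue is inserted into
    the trigger's sentence when a value becomes non-default.
    """
    import copy

    for dim, matrix in confusion.items():
        for true_value, row in matrix.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"confusion row {dim.value}/{true_value} does not sum to 1"
                )
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(corpus)
    lexicon = load_default_lexicon()
    pools = _safe_clue_pools(lexicon)
    for doc in out.documents:
        for event in doc.events:
            for dim, matrix in confusion.items():
                old = event.mk.value(dim)
                row = matrix.get(old)
                if row is None:
                    continue
                new = _sample(rng, row)
                if new is old:
                    continue
                event.mk = event.mk.with_value(dim, new)
                if new is DIMENSION_DEFAULTS[dim]:
                    event.mk.clues[dim] = []
                else:
                    pool = pools[(dim, new)]
                    phrase = pool[int(rng.integers(len(pool)))]
                    span = _insert_clue(doc, event, phrase)
                    event.mk.clues[dim] = [span]
    return out


def _insert_clue(doc: Document, event: AnnotatedEvent, phrase: str) -> Span:
    """Insert ``phrase`` just before the event's trigger, shifting spans."""
    if event.trigger is None:
        pos = len(doc.text)
        inserted = (" " if doc.text else "") + phrase
        doc.text += inserted
        start = pos + (1 if inserted.startswith(" ") else 0)
        if doc.sentences:
            last = doc.sentences[-1]
            doc.sentences[-1] = Span(last.start, len(doc.text))
        return Span(start, len(doc.text))
    pos = event.trigger.start
    inserted = phrase + " "
    shift = len(inserted)
    doc.text = doc.text[:pos] + inserted + doc.text[pos:]

    def shift_span(span: Span) -> Span:
        if span.end <= pos:
            return span
        if span.start >= pos:
            return Span(span.start + shift, span.end + shift)
        return Span(span.start, span.end + shift)  # straddles insertion point

    doc.sentences = [shift_span(s) for s in doc.sentences]
    for ent in doc.entities:
        ent.span = shift_span(ent.span)
    for ev in doc.events:
        if ev.trigger is not None:
            ev.trigger = shift_span(ev.trigger)
        for dim, spans in ev.mk.clues.items():
            ev.mk.clues[dim] = [shift_span(s) for s in spans]
    return Span(pos, pos + len(phrase))


def spec_from_dict(data: dict) -> GenerationSpec:
    """Build a GenerationSpec from plain-string keys (YAML config files).

    Unspecified distributions fall back to the reference proportions.
    """
    spec = default_paper_spec()
    if "n_documents" in data:
        spec = replace(spec, n_documents=int(data["n_documents"]))
    if "events_per_doc" in data:
        spec = replace(spec, events_per_doc=float(data["events_per_doc"]))
    if "seed" in data:
        spec = replace(spec, seed=int(data["seed"]))
    if "distractor_prob" in data:
        spec = replace(spec, distractor_prob=float(data["distractor_prob"]))
    if "clue_insertion_prob" in data:
        value = data["clue_insertion_prob"]
        if isinstance(value, dict):
            probs = {Dimension(k): float(v) for k, v in value.items()}
            merged = dict(spec.clue_insertion_prob)
            merged.update(probs)
            spec = replace(spec, clue_insertion_prob=merged)
        else:
            spec = replace(
                spec,
                clue_insertion_prob={d: float(value) for d in Dimension},
            )
    if "kt_marginal" in data:
        spec = replace(
            spec,
            kt_marginal={KTValue(k): float(v) for k, v in data["kt_marginal"].items()},
        )
    if "source_marginal" in data:
        spec = replace(
            spec,
            source_marginal={
                SourceValue(k): float(v) for k, v in data["source_marginal"].items()
            },
        )
    return spec
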