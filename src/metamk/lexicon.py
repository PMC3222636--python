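"""Clue lexicon: patterns, loading, and sentence-level matching.

Clue expressions are the lexical markers that license non-default
meta-knowledge values (*suggest* -> Analysis/L2, *not* -> Negative,
*partially* -> Low, *previously* -> Other-source, ...).  The packaged
default lexicon compiles the most frequent annotated clue expressions per
dimension together with the handful of clues that are conditioned on the
event type: *independent(ly)* only negates Correlation/Regulation events,
*overexpression* expresses High manner only for Gene_Expression, and
*normal* / *silent* negate only the regulation type they contrast with.

Patterns are token sequences.  Tokens are lower-cased words or numerals
(hyphens split tokens, so *3-fold* tokenises as ``3 fold``); the
placeholders ``{NUM}`` and ``{PCT}`` match a numeral or a percentage at
token level, covering the productive *n-fold* / *by n%* manner patterns.
Matching is case-insensitive, left to right; a match overlapped by a
strictly longer match is suppressed, so *no significant* blocks both the
negation reading of *no* and the High-manner reading of *significant*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .model import DIMENSION_VALUES, Dimension, Span

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?%|\d+(?:\.\d+)?|[A-Za-z]+")
_NUM_RE = re.compile(r"\d+(?:\.\d+)?\Z")
_PCT_RE = re.compile(r"\d+(?:\.\d+)?%\Z")

PLACEHOLDERS = ("{NUM}", "{PCT}")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lower-cased word/numeral tokens with character offsets."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass(frozen=True)
class CluePattern:
    """A clue surface pattern: literal tokens and/or placeholders."""

    tokens: tuple[str, ...]
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty pattern")
        if all(t in PLACEHOLDERS for t in self.tokens):
            raise ValueError("pattern needs at least one literal token")
        for a, b in zip(self.tokens, self.tokens[1:]):
            if a in PLACEHOLDERS and b in PLACEHOLDERS:
                raise ValueError("adjacent placeholders are ambiguous")

    @classmethod
    def parse(cls, text: str) -> "CluePattern":
        parts: list[str] = []
        for chunk in text.split():
            if chunk in PLACEHOLDERS:
                parts.append(chunk)
                continue
            for sub in chunk.split("-"):
                if not sub:
                    continue
                parts.append(sub if sub in PLACEHOLDERS else sub.lower())
        return cls(tuple(parts))

    @property
    def surface(self) -> str:
        return " ".join(self.tokens)

    def token_matches(self, index: int, token: str) -> bool:
        pat = self.tokens[index]
        if pat == "{NUM}":
            return _NUM_RE.match(token) is not None
        if pat == "{PCT}":
            return _PCT_RE.match(token) is not None
        return pat == token

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class ClueEntry:
    """One lexicon row."""

    pattern: CluePattern
    dimension: Dimension
    value: object  # the category enum member assigned by this clue
    event_types: frozenset[str] | None = None  # None = unconditioned
    priority: int = 0

    def __post_init__(self) -> None:
        enum_cls = DIMENSION_VALUES[self.dimension]
        if not isinstance(self.value, enum_cls):
            raise ValueError(
                f"{self.value!r} is not a legal {self.dimension.value} value"
            )

    def applies_to(self, event_type: str) -> bool:
        return self.event_types is None or event_type in self.event_types


@dataclass
class ClueLexicon:
    entries: list[ClueEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[tuple[str, ...], Dimension]] = set()
        for entry in self.entries:
            key = (entry.pattern.tokens, entry.dimension)
            if key in seen:
                raise ValueError(
                    f"duplicate lexicon entry {entry.pattern.surface!r} "
                    f"for {entry.dimension.value}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def for_dimension(self, dimension: Dimension) -> list[ClueEntry]:
        return [e for e in self.entries if e.dimension is dimension]


@dataclass(frozen=True)
class ClueMatch:
    """A lexicon hit: document-coordinate span plus the firing entry."""

    span: Span
    entry: ClueEntry
    token_start: int = 0
    token_end: int = 0  # exclusive, in sentence token indices


def parse_lexicon(lines) -> ClueLexicon:
    """Parse the tab-separated lexicon format (see the packaged file)."""
    entries: list[ClueEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"lexicon line {lineno}: expected 5 columns")
        pattern_text, dim_text, value_text, types_text, priority_text = fields
        try:
            dimension = Dimension(dim_text)
        except ValueError as exc:
            raise ValueError(f"lexicon line {lineno}: unknown dimension {dim_text!r}") from exc
        enum_cls = DIMENSION_VALUES[dimension]
        try:
            value = enum_cls(value_text)
        except ValueError as exc:
            raise ValueError(
                f"lexicon line {lineno}: {value_text!r} is not a {dimension.value} value"
            ) from exc
        event_types = (
            None if types_text == "*" else frozenset(types_text.split(","))
        )
        entries.append(
            ClueEntry(
                pattern=CluePattern.parse(pattern_text),
                dimension=dimension,
                value=value,
                event_types=event_types,
                priority=int(priority_text),
            )
        )
    return ClueLexicon(entries)


def load_lexicon(path) -> ClueLexicon:
    with open(path, encoding="utf-8") as handle:
        return parse_lexicon(handle)


def load_default_lexicon() -> ClueLexicon:
    """The packaged default lexicon.

    Dual-role clues (*suggest*, *indicate* and their inflections express
    Analysis and slight speculation simultaneously) appear as one entry
    per dimension, so a single surface hit can set both KT and CL.
    """
    ref = resources.files("metamk.data").joinpath("default_lexicon.tsv")
    with ref.open("r", encoding="utf-8") as handle:
        return parse_lexicon(handle)


def match_clues(
    sentence_text: str, sentence_span: Span, lexicon: ClueLexicon
) -> list[ClueMatch]:
    """All clue matches in one sentence, longest-match filtered.

    ``sentence_text`` must be the document substring at ``sentence_span``;
    returned spans are in document coordinates.  At each token position
    every entry is tried; afterwards any match strictly shorter than an
    overlapping match (in tokens) is suppressed, regardless of dimension.
    Equal-length overlapping matches are all kept, which is what lets one
    clue word serve two dimensions.
    """
    tokens = tokenize(sentence_text)
    if not tokens:
        return []
    raw: list[ClueMatch] = []
    for start in range(len(tokens)):
        for entry in lexicon.entries:
            n = len(entry.pattern)
            if start + n > len(tokens):
                continue
            if all(
                entry.pattern.token_matches(i, tokens[start + i][0]) for i in range(n)
            ):
                char_start = sentence_span.start + tokens[start][1]
                char_end = sentence_span.start + tokens[start + n - 1][2]
                raw.append(
                    ClueMatch(
                        span=Span(char_start, char_end),
                        entry=entry,
                        token_start=start,
                        token_end=start + n,
                    )
                )
    kept: list[ClueMatch] = []
    for m in raw:
        suppressed = any(
            other is not m
            and (other.token_end - other.token_start) > (m.token_end - m.token_start)
            and other.token_start < m.token_end
            and m.token_start < other.token_end
            for other in raw
        )
        if not suppressed:
            kept.append(m)
    kept.sort(key=lambda m: (m.token_start, m.token_end, m.entry.dimension.value))
    return kept
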