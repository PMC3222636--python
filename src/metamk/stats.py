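"""Corpus statistics: category distributions, cross-tabulations, clue
frequencies and hyper-dimension frequencies.

Percentages use a single shared rounding rule — round half up, one
decimal — so every table in a report is rounded consistently.  Zero-count
categories are always listed: the scheme's design argument is that no
category is redundant, and a report should make an empty one visible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from . import hyperdim
from .model import DIMENSION_VALUES, Corpus, Dimension


def round_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator``, rounded half-up.

    The shared rounding rule for every table.  Returns 0.0 for an empty
    denominator (callers flag that case explicitly).
    """
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DistributionRow:
    category: str
    count: int
    pct_of_total: float
    pct_within: float | None = None
    undefined_pct: bool = False  # set when a denominator was zero


def dimension_distribution(corpus: Corpus, dimension: Dimension) -> list[DistributionRow]:
    """One row per category of ``dimension``, sorted by count descending.

    ``pct_of_total`` is the share of all events in the corpus.
    """
    total = corpus.n_events()
    counts = Counter(ev.mk.value(dimension) for ev in corpus.events)
    rows = [
        DistributionRow(
            category=value.value,
            count=counts.get(value, 0),
            pct_of_total=round_pct(counts.get(value, 0), total),
            undefined_pct=total == 0,
        )
        for value in DIMENSION_VALUES[dimension]
    ]
    rows.sort(key=lambda r: (-r.count, r.category))
    return rows


def kt_cross_tab(
    corpus: Corpus, dimension: Dimension, categories
) -> list[DistributionRow]:
    """Per Knowledge Type, how many events carry a value in ``categories``.

    ``pct_within`` is the share within each KT category (e.g. the fraction
    of Observation events that are negated); ``pct_of_total`` is the share
    of all events.  KT categories with no events are flagged.
    """
    if dimension is Dimension.KT:
        raise ValueError("cross-tabulation dimension must differ from KT")
    categories = set(categories)
    total = corpus.n_events()
    kt_sizes: Counter = Counter()
    hits: Counter = Counter()
    for ev in corpus.events:
        kt_sizes[ev.mk.kt] += 1
        if ev.mk.value(dimension) in categories:
            hits[ev.mk.kt] += 1
    rows = [
        DistributionRow(
            category=kt.value,
            count=hits.get(kt, 0),
            pct_of_total=round_pct(hits.get(kt, 0), total),
            pct_within=round_pct(hits.get(kt, 0), kt_sizes.get(kt, 0)),
            undefined_pct=kt_sizes.get(kt, 0) == 0,
        )
        for kt in DIMENSION_VALUES[Dimension.KT]
    ]
    rows.sort(key=lambda r: (-r.count, r.category))
    return rows


def clue_frequency(
    corpus: Corpus, dimension: Dimension, value
) -> tuple[list[tuple[str, int]], int]:
    """Ranked clue surface forms for events with ``dimension`` = ``value``.

    Surface forms are taken verbatim from the clue spans, lower-cased with
    whitespace collapsed; ranked by count then alphabetically.  Also
    returns the number of distinct forms.
    """
    counts: Counter = Counter()
    for doc in corpus.documents:
        for ev in doc.events:
            if ev.mk.value(dimension) is not value:
                continue
            for span in ev.mk.clues.get(dimension, []):
                surface = " ".join(doc.text[span.start : span.end].lower().split())
                if surface:
                    counts[surface] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked, len(ranked)


def hyperdim_distribution(corpus: Corpus) -> list[DistributionRow]:
    """Yes/No frequencies for both derived hyper-dimensions.

    Hyper-dimension values are recomputed from each event's (Source, KT,
    CL) — they are never stored — so this reflects the inference rules
    exactly.
    """
    total = corpus.n_events()
    nk_yes = 0
    hyp_yes = 0
    for ev in corpus.events:
        hd = hyperdim.infer_event(ev)
        nk_yes += hd.new_knowledge
        hyp_yes += hd.hypothesis
    rows = []
    for name, yes in (("New Knowledge", nk_yes), ("Hypothesis", hyp_yes)):
        for label, count in (("Yes", yes), ("No", total - yes)):
            rows.append(
                DistributionRow(
                    category=f"{name} {label}",
                    count=count,
                    pct_of_total=round_pct(count, total),
                    undefined_pct=total == 0,
                )
            )
    return rows
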