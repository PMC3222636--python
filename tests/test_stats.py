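"""Corpus statistics against the reference annotation's printed tables."""

from conftest import corpus_from_mk, counts_corpus

from metamk.model import (
    CLValue,
    Corpus,
    Dimension,
    KTValue,
    MannerValue,
    MetaKnowledge,
    PolarityValue,
)
from metamk.stats import (
    clue_frequency,
    dimension_distribution,
    hyperdim_distribution,
    kt_cross_tab,
    round_pct,
)
from metamk.synthetic import KT_COUNTS, NEGATED_BY_KT


def rows_by_category(rows):
    return {r.category: r for r in rows}


def test_rounding_is_half_up_to_one_decimal():
    assert round_pct(11537, 36858) == 31.3
    assert round_pct(1948, 36858) == 5.3  # 5.285 rounds up
    assert round_pct(1, 16) == 6.3  # 6.25 rounds half up
    assert round_pct(5, 0) == 0.0  # guarded empty denominator


def test_kt_distribution_matches_reference_counts():
    corpus = counts_corpus([(MetaKnowledge(kt=kt), n) for kt, n in KT_COUNTS.items()])
    rows = rows_by_category(dimension_distribution(corpus, Dimension.KT))
    assert rows["Other"].count == 11537
    assert rows["Other"].pct_of_total == 31.3
    assert rows["Analysis"].pct_of_total == 17.8
    assert rows["Fact"].pct_of_total == 8.1
    assert rows["Investigation"].pct_of_total == 5.3
    assert rows["Method"].pct_of_total == 2.6


def test_polarity_distribution_reference_share():
    corpus = counts_corpus(
        [
            (MetaKnowledge(), 36858 - 2263),
            (MetaKnowledge(polarity=PolarityValue.NEGATIVE), 2263),
        ]
    )
    rows = rows_by_category(dimension_distribution(corpus, Dimension.POLARITY))
    assert rows["Negative"].pct_of_total == 6.1
    assert rows["Positive"].pct_of_total == 93.9


def test_single_event_corpus_is_all_of_total():
    corpus = corpus_from_mk([MetaKnowledge(kt=KTValue.OBSERVATION)])
    rows = rows_by_category(dimension_distribution(corpus, Dimension.KT))
    assert rows["Observation"].pct_of_total == 100.0
    assert rows["Other"].count == 0
    assert rows["Other"].pct_of_total == 0.0
    assert len(rows) == 6  # zero-count categories always listed


def test_counts_conserve_event_total(paper_corpus):
    total = paper_corpus.n_events()
    for dim in Dimension:
        rows = dimension_distribution(paper_corpus, dim)
        assert sum(r.count for r in rows) == total


def test_negation_cross_tab_within_category_shares():
    counts = []
    for kt, n in KT_COUNTS.items():
        neg = NEGATED_BY_KT[kt]
        counts.append((MetaKnowledge(kt=kt, polarity=PolarityValue.NEGATIVE), neg))
        counts.append((MetaKnowledge(kt=kt), n - neg))
    corpus = counts_corpus(counts)
    rows = rows_by_category(
        kt_cross_tab(corpus, Dimension.POLARITY, {PolarityValue.NEGATIVE})
    )
    assert rows["Observation"].count == 1364
    assert rows["Observation"].pct_within == 10.6
    assert rows["Fact"].pct_within == 3.5
    assert rows["Method"].pct_within == 1.0


def test_cross_tab_handles_empty_categories():
    corpus = corpus_from_mk([MetaKnowledge(kt=KTValue.OBSERVATION)])
    rows = rows_by_category(
        kt_cross_tab(corpus, Dimension.POLARITY, {PolarityValue.NEGATIVE})
    )
    assert rows["Method"].pct_within == 0.0
    assert rows["Method"].undefined_pct
    assert all(r.count == 0 for r in rows.values())


def test_clue_frequency_ranks_surface_forms():
    mks = []
    for _ in range(3):
        mk = MetaKnowledge(polarity=PolarityValue.NEGATIVE)
        mks.append(mk)
    mk_no = MetaKnowledge(polarity=PolarityValue.NEGATIVE)
    corpus = corpus_from_mk(mks + [mk_no])
    # conftest anchors all Negative clues at "not"; repoint one at "no"
    doc = corpus.documents[0]
    from metamk.model import Span

    doc.events[-1].mk.clues[Dimension.POLARITY] = [Span(12, 14)]
    ranked, distinct = clue_frequency(
        corpus, Dimension.POLARITY, PolarityValue.NEGATIVE
    )
    assert ranked == [("not", 3), ("no", 1)]
    assert distinct == 2


def test_clue_frequency_empty_corpus():
    ranked, distinct = clue_frequency(
        Corpus(), Dimension.POLARITY, PolarityValue.NEGATIVE
    )
    assert ranked == []
    assert distinct == 0


def test_distinct_l1_forms_cover_the_packaged_lexicon(lexicon):
    """A corpus exercising every packaged L1 clue once yields exactly one
    distinct surface form per packaged L1 pattern."""
    from metamk.model import AnnotatedEvent, Document, Span

    l1_entries = [
        e
        for e in lexicon.entries
        if e.dimension is Dimension.CL and e.value is CLValue.L1
    ]
    text = " ".join(e.pattern.surface for e in l1_entries)
    doc = Document(id="d1", text=text, sentences=[Span(0, len(text))])
    pos = 0
    for i, entry in enumerate(l1_entries):
        surface = entry.pattern.surface
        mk = MetaKnowledge(kt=KTValue.ANALYSIS, cl=CLValue.L1)
        mk.clues[Dimension.KT] = [Span(pos, pos + len(surface))]
        mk.clues[Dimension.CL] = [Span(pos, pos + len(surface))]
        doc.events.append(AnnotatedEvent(id=f"e{i}", mk=mk))
        pos += len(surface) + 1
    ranked, distinct = clue_frequency(Corpus([doc]), Dimension.CL, CLValue.L1)
    assert distinct == len(l1_entries)
    assert all(count == 1 for _, count in ranked)


def test_hyperdim_distribution_all_new_knowledge():
    corpus = corpus_from_mk(
        [MetaKnowledge(kt=KTValue.OBSERVATION) for _ in range(10)]
    )
    rows = rows_by_category(hyperdim_distribution(corpus))
    assert rows["New Knowledge Yes"].pct_of_total == 100.0
    assert rows["Hypothesis Yes"].count == 0


def test_hyperdim_distribution_reconstruction(reconstruction_corpus):
    rows = rows_by_category(hyperdim_distribution(reconstruction_corpus))
    assert rows["Hypothesis Yes"].pct_of_total == 13.4
    assert rows["Hypothesis No"].pct_of_total == 86.6
    total = reconstruction_corpus.n_events()
    assert rows["Hypothesis Yes"].count + rows["Hypothesis No"].count == total


def test_hyperdim_distribution_empty_corpus():
    rows = hyperdim_distribution(Corpus())
    assert all(r.undefined_pct for r in rows)
    assert all(r.count == 0 for r in rows)


def test_explicit_manner_sources_mostly_observations(paper_corpus):
    rows = rows_by_category(
        kt_cross_tab(
            paper_corpus, Dimension.MANNER, {MannerValue.HIGH, MannerValue.LOW}
        )
    )
    # Observation carries by far the largest share of explicit manner
    assert rows["Observation"].count == max(r.count for r in rows.values())


def test_source_distribution_on_synthetic_corpus(paper_corpus):
    rows = rows_by_category(
        dimension_distribution(paper_corpus, Dimension.SOURCE)
    )
    assert rows["Current"].count + rows["Other"].count == paper_corpus.n_events()
    assert rows["Current"].count > rows["Other"].count
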