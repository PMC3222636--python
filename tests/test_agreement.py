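"""Cohen's kappa and per-dimension agreement reporting."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from metamk.agreement import align_events, cohens_kappa, per_dimension_agreement
from metamk.model import Dimension, PolarityValue
from metamk.synthetic import default_paper_spec, generate, perturb_annotations


def test_perfect_agreement_is_kappa_one():
    kappa, p_o, p_e = cohens_kappa(list("abcabc"), list("abcabc"), set("abc"))
    assert kappa == 1.0
    assert p_o == 1.0


def test_perfect_disagreement_with_swapped_marginals_is_minus_one():
    kappa, p_o, p_e = cohens_kappa(
        ["x", "x", "y", "y"], ["y", "y", "x", "x"], {"x", "y"}
    )
    assert p_o == 0.0
    assert p_e == pytest.approx(0.5, abs=1e-15)
    assert kappa == pytest.approx(-1.0, abs=1e-12)


def test_balanced_confusion_counts_give_point_eight():
    # contingency [[45, 5], [5, 45]]
    a = ["p"] * 50 + ["n"] * 50
    b = ["p"] * 45 + ["n"] * 5 + ["p"] * 5 + ["n"] * 45
    kappa, p_o, p_e = cohens_kappa(a, b, {"p", "n"})
    assert p_o == pytest.approx(0.9, abs=1e-12)
    assert p_e == pytest.approx(0.5, abs=1e-12)
    assert kappa == pytest.approx(0.8, abs=1e-12)


def test_single_category_edge_cases():
    kappa, p_o, p_e = cohens_kappa(["a", "a"], ["a", "a"], {"a"})
    assert (kappa, p_o, p_e) == (1.0, 1.0, 1.0)
    kappa, p_o, p_e = cohens_kappa(["a", "a"], ["a", "b"], {"a", "b"})
    assert not math.isnan(kappa)  # mixed labels keep p_e < 1


def test_input_contract_errors():
    with pytest.raises(ValueError, match="length"):
        cohens_kappa(["a"], ["a", "b"], {"a", "b"})
    with pytest.raises(ValueError, match="at least one"):
        cohens_kappa([], [], {"a"})
    with pytest.raises(ValueError, match="category"):
        cohens_kappa(["z"], ["z"], {"a"})


@settings(derandomize=True, max_examples=50)
@given(
    labels=st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
        min_size=2,
        max_size=60,
    )
)
def test_kappa_symmetry_and_relabelling_invariance(labels):
    a = [x for x, _ in labels]
    b = [y for _, y in labels]
    kappa_ab, _, _ = cohens_kappa(a, b, set("abc"))
    kappa_ba, _, _ = cohens_kappa(b, a, set("abc"))
    if not math.isnan(kappa_ab):
        assert kappa_ab == pytest.approx(kappa_ba, abs=1e-12)
        mapping = {"a": "q", "b": "r", "c": "s"}
        kappa_rel, _, _ = cohens_kappa(
            [mapping[x] for x in a], [mapping[y] for y in b], set("qrs")
        )
        assert kappa_rel == pytest.approx(kappa_ab, abs=1e-12)


@settings(derandomize=True, max_examples=30)
@given(
    labels=st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
        min_size=2,
        max_size=60,
    )
)
def test_kappa_agrees_with_sklearn(labels):
    a = [x for x, _ in labels]
    b = [y for _, y in labels]
    kappa, _, p_e = cohens_kappa(a, b, set("abc"))
    reference = cohen_kappa_score(a, b, labels=["a", "b", "c"])
    if not math.isnan(kappa) and not math.isnan(reference):
        assert kappa == pytest.approx(reference, abs=1e-10)


def test_align_identical_corpora_pairs_everything(paper_corpus):
    alignment = align_events(paper_corpus, paper_corpus)
    assert len(alignment.pairs) == paper_corpus.n_events()
    assert alignment.unmatched_a == alignment.unmatched_b == []


def test_align_reports_extra_events():
    import copy

    from metamk.model import AnnotatedEvent

    corpus_a = generate(default_paper_spec(n_documents=2, seed=5))
    corpus_b = copy.deepcopy(corpus_a)
    corpus_b.documents[0].events.append(AnnotatedEvent(id="extra"))
    alignment = align_events(corpus_a, corpus_b)
    assert alignment.unmatched_b == [(corpus_b.documents[0].id, "extra")]


def test_align_falls_back_to_trigger_and_type():
    import copy

    corpus_a = generate(default_paper_spec(n_documents=2, seed=6))
    corpus_b = copy.deepcopy(corpus_a)
    for doc in corpus_b.documents:
        for ev in doc.events:
            ev.id = "x" + ev.id
    alignment = align_events(corpus_a, corpus_b)
    assert len(alignment.pairs) == corpus_a.n_events()


def test_align_requires_same_documents():
    corpus_a = generate(default_paper_spec(n_documents=2, seed=7))
    corpus_b = generate(default_paper_spec(n_documents=3, seed=7))
    with pytest.raises(ValueError, match="document sets differ"):
        align_events(corpus_a, corpus_b)


def test_self_agreement_is_unity(paper_corpus):
    report = per_dimension_agreement(paper_corpus, paper_corpus)
    for agg in report.dimensions.values():
        assert agg.kappa == 1.0
    assert report.discrepancies == []


def test_polarity_confusion_lowers_only_polarity_kappa(paper_corpus):
    epsilon = 0.05
    confusion = {
        Dimension.POLARITY: {
            PolarityValue.POSITIVE: {
                PolarityValue.POSITIVE: 1 - epsilon,
                PolarityValue.NEGATIVE: epsilon,
            },
            PolarityValue.NEGATIVE: {
                PolarityValue.NEGATIVE: 1 - epsilon,
                PolarityValue.POSITIVE: epsilon,
            },
        }
    }
    perturbed = perturb_annotations(paper_corpus, confusion, seed=31)
    report = per_dimension_agreement(paper_corpus, perturbed)
    assert report.dimensions[Dimension.POLARITY].kappa < 0.95
    for dim in Dimension:
        if dim is not Dimension.POLARITY:
            assert report.dimensions[dim].kappa == 1.0
    assert all(d.dimension is Dimension.POLARITY for d in report.discrepancies)
    clued = [d for d in report.discrepancies if d.value_b == "Negative"]
    assert all(d.clue_b for d in clued)  # inserted clues are reported


def test_estimated_kappa_matches_confusion_closed_form():
    """Symmetric flip noise on Polarity: the estimated kappa converges to
    the value implied by the flip rate and the true marginals."""
    corpus = generate(default_paper_spec(n_documents=550, seed=77))
    n = corpus.n_events()
    assert n >= 20000
    epsilon = 0.05
    confusion = {
        Dimension.POLARITY: {
            PolarityValue.POSITIVE: {
                PolarityValue.POSITIVE: 1 - epsilon,
                PolarityValue.NEGATIVE: epsilon,
            },
            PolarityValue.NEGATIVE: {
                PolarityValue.NEGATIVE: 1 - epsilon,
                PolarityValue.POSITIVE: epsilon,
            },
        }
    }
    perturbed = perturb_annotations(corpus, confusion, seed=78)
    report = per_dimension_agreement(corpus, perturbed)
    agg = report.dimensions[Dimension.POLARITY]

    p_pos = (
        sum(ev.mk.polarity is PolarityValue.POSITIVE for ev in corpus.events) / n
    )
    p_o_expected = 1 - epsilon
    q_pos = p_pos * (1 - epsilon) + (1 - p_pos) * epsilon
    p_e_expected = p_pos * q_pos + (1 - p_pos) * (1 - q_pos)
    kappa_expected = (p_o_expected - p_e_expected) / (1 - p_e_expected)

    sigma_po = math.sqrt(epsilon * (1 - epsilon) / n)
    tolerance = 3 * sigma_po / (1 - p_e_expected)
    assert agg.n == n
    assert abs(agg.p_o - p_o_expected) <= 3 * sigma_po
    assert abs(agg.kappa - kappa_expected) <= tolerance


def test_no_alignable_events_is_an_error():
    from metamk.model import Corpus, Document

    a = Corpus([Document(id="d1", text="")])
    b = Corpus([Document(id="d1", text="")])
    with pytest.raises(ValueError, match="aligned"):
        per_dimension_agreement(a, b)
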