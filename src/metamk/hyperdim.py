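"""Hyper-dimension inference.

Two further annotations are derivable deterministically from combinations
of the annotated dimensions and are therefore never stored on events:

* **New Knowledge** — a definite observation or analysis attributable to
  the current study.  Yes iff Source=Current, KT in {Observation,
  Analysis} and CL=L3.
* **Hypothesis** — an enquiry or a speculative analysis.  Yes iff
  KT=Investigation, or KT=Analysis with CL in {L1, L2}.

Both rule sets are kept in two forms: an ordered wildcard rule table
(authoritative; ``None`` means "any value") and a closed-form predicate.
The exhaustive equivalence of the two over all 36 (source, kt, cl)
combinations is asserted in the test suite, guarding the tables against
transcription drift.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotatedEvent, CLValue, KTValue, SourceValue


@dataclass(frozen=True)
class HyperDimensions:
    new_knowledge: bool
    hypothesis: bool


# Ordered wildcard rows (source, kt, cl) -> inferred value; first match wins.
NEW_KNOWLEDGE_RULES: tuple[tuple[SourceValue | None, KTValue | None, CLValue | None, bool], ...] = (
    (SourceValue.OTHER, None, None, False),
    (None, None, CLValue.L2, False),
    (None, None, CLValue.L1, False),
    (SourceValue.CURRENT, KTValue.OBSERVATION, CLValue.L3, True),
    (SourceValue.CURRENT, KTValue.ANALYSIS, CLValue.L3, True),
    (None, KTValue.FACT, None, False),
    (None, KTValue.METHOD, None, False),
    (None, KTValue.OTHER, None, False),
    (None, KTValue.INVESTIGATION, None, False),
)

HYPOTHESIS_RULES: tuple[tuple[KTValue | None, CLValue | None, bool], ...] = (
    (KTValue.FACT, None, False),
    (KTValue.METHOD, None, False),
    (KTValue.OTHER, None, False),
    (KTValue.OBSERVATION, None, False),
    (KTValue.ANALYSIS, CLValue.L3, False),
    (KTValue.ANALYSIS, CLValue.L2, True),
    (KTValue.ANALYSIS, CLValue.L1, True),
    (KTValue.INVESTIGATION, None, True),
)


def _matches(cell, value) -> bool:
    return cell is None or cell is value


def infer_new_knowledge(source: SourceValue, kt: KTValue, cl: CLValue) -> bool:
    """New Knowledge, via first-match lookup in the ordered rule table."""
    for rule_source, rule_kt, rule_cl, result in NEW_KNOWLEDGE_RULES:
        if (
            _matches(rule_source, source)
            and _matches(rule_kt, kt)
            and _matches(rule_cl, cl)
        ):
            return result
    raise ValueError(f"no rule matches ({source}, {kt}, {cl})")


def infer_hypothesis(kt: KTValue, cl: CLValue) -> bool:
    """Hypothesis, via first-match lookup in the ordered rule table."""
    for rule_kt, rule_cl, result in HYPOTHESIS_RULES:
        if _matches(rule_kt, kt) and _matches(rule_cl, cl):
            return result
    raise ValueError(f"no rule matches ({kt}, {cl})")


def new_knowledge_predicate(source: SourceValue, kt: KTValue, cl: CLValue) -> bool:
    """Closed-form simplification of the New Knowledge rule table."""
    return (
        source is SourceValue.CURRENT
        and kt in (KTValue.OBSERVATION, KTValue.ANALYSIS)
        and cl is CLValue.L3
    )


def hypothesis_predicate(kt: KTValue, cl: CLValue) -> bool:
    """Closed-form simplification of the Hypothesis rule table."""
    return kt is KTValue.INVESTIGATION or (
        kt is KTValue.ANALYSIS and cl in (CLValue.L1, CLValue.L2)
    )


def infer_event(event: AnnotatedEvent) -> HyperDimensions:
    """Apply both inferences to an event's (source, kt, cl)."""
    mk = event.mk
    return HyperDimensions(
        new_knowledge=infer_new_knowledge(mk.source, mk.kt, mk.cl),
        hypothesis=infer_hypothesis(mk.kt, mk.cl),
    )
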