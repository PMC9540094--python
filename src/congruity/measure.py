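"""The Congruity measure: how well a new instance is represented in the
training data, read off the concept lattice.

Given a lattice ``L`` built on the training context and a new instance
``X`` with attribute set Attr(X), scoring proceeds in three steps:

1. *Candidate set* ``G'``: the training objects sharing at least one
   attribute with X.  Its size is the support denominator.
2. *Matching concepts* ``C̃``: concepts with non-empty extent whose intent
   shares strictly more than ``|Attr(X)| / 2`` attributes with X.
3. *Combination*: per matching concept, support
   ``S = |own objects ∩ G'| / |G'|`` (own objects — training items whose
   complete profile equals the intent) and the F-measure of the
   precision/recall of intent vs Attr(X).  Congruity is the convex
   combination ``α1·S + α2·F``:

   - **exact** — some matching concept's intent equals Attr(X); then F = 1
     and the score is ``α1·S(C̃*) + α2`` at that single concept;
   - **partial** — otherwise, the mean of ``α1·S + α2·F`` over C̃;
   - **none** — no matching concept; the score is 0.

Support counts *own* objects, not the whole extent: it measures how often
the concept's exact profile occurred in training, so a concept that exists
only as a generalization (no training item has exactly its intent)
contributes support 0.

Two arithmetic modes are provided.  ``full`` (default) carries exact
floats.  ``printed`` mimics hand-computation on printed two-decimal tables:
S and F are rounded half-away-from-zero to 2 decimals before combining and
the final score to 3 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .formal_context import FormalContext, Instance
from .lattice import ConceptLattice, FormalConcept

__all__ = [
    "InvalidInstanceError",
    "UndefinedMeasureError",
    "CongruityParams",
    "ConceptMatch",
    "CongruityResult",
    "candidate_objects",
    "matching_concepts",
    "support",
    "precision",
    "recall",
    "f_measure",
    "congruity_score",
    "round_half_up",
]


class InvalidInstanceError(ValueError):
    """The instance cannot be scored (empty attribute set)."""


class UndefinedMeasureError(ValueError):
    """A component measure has an empty denominator."""


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero (0.9125 → 0.913 at 3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CongruityParams:
    """Weights and arithmetic mode of the score.

    ``alpha1`` weighs support, ``alpha2`` the F-measure; they must form a
    convex combination (non-negative, summing to 1) so the score stays in
    [0, 1].  ``rounding`` is ``"full"`` or ``"printed"`` (see module docs).
    """

    alpha1: float = 0.1
    alpha2: float = 0.9
    rounding: str = "full"

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha weights must be non-negative")
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            raise ValueError("alpha1 + alpha2 must equal 1 (convex combination)")
        if self.rounding not in ("full", "printed"):
            raise ValueError("rounding must be 'full' or 'printed'")


@dataclass(frozen=True)
class ConceptMatch:
    """Per-concept breakdown of a score (the explainability payload)."""

    concept_id: int
    intent: frozenset[str]
    shared: int
    support: float
    precision: float
    recall: float
    f_measure: float
    term: float  # alpha1 * S + alpha2 * F as entered into the combination


@dataclass(frozen=True)
class CongruityResult:
    instance_id: str
    value: float
    case: str  # "exact" | "partial" | "none"
    candidates: frozenset[str]
    matches: tuple[ConceptMatch, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "value": self.value,
            "case": self.case,
            "candidates": sorted(self.candidates),
            "matches": [
                {
                    "concept_id": m.concept_id,
                    "intent": sorted(m.intent),
                    "shared": m.shared,
                    "support": m.support,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "term": m.term,
                }
                for m in self.matches
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def candidate_objects(context: FormalContext, instance: Instance) -> frozenset[str]:
    """G′: training objects sharing at least one attribute with the instance.

    Instance attributes absent from the context's M simply never match.
    """
    attrs = instance.attributes
    return frozenset(
        g for g in context.objects if attrs & context.incidence[g]
    )


def matching_concepts(
    lattice: ConceptLattice, instance: Instance
) -> list[FormalConcept]:
    """C̃: non-empty-extent concepts sharing strictly more than half of the
    instance's attributes (a 3-attribute instance needs ≥ 2 shared)."""
    attrs = instance.attributes
    if not attrs:
        raise InvalidInstanceError(
            f"instance {instance.id!r} has no attributes; the matching "
            "threshold |Attr(X)|/2 is undefined"
        )
    threshold = len(attrs) / 2
    return [
        c
        for c in lattice.concepts
        if c.extent and len(attrs & c.intent) > threshold
    ]


def support(concept: FormalConcept, candidates: frozenset[str]) -> float:
    """S(C) = |own objects of C within G′| / |G′|."""
    if not candidates:
        raise UndefinedMeasureError("support undefined for an empty candidate set")
    return len(concept.own_objects & candidates) / len(candidates)


def precision(concept: FormalConcept, instance: Instance) -> float:
    """P = |Attr(X) ∩ intent| / |intent|: how much of the concept X covers."""
    if not concept.intent:
        raise UndefinedMeasureError(
            "precision undefined for an empty intent (top concept)"
        )
    return len(instance.attributes & concept.intent) / len(concept.intent)


def recall(concept: FormalConcept, instance: Instance) -> float:
    """R = |Attr(X) ∩ intent| / |Attr(X)|: how much of X the concept covers."""
    if not instance.attributes:
        raise InvalidInstanceError("recall undefined for an empty attribute set")
    return len(instance.attributes & concept.intent) / len(instance.attributes)


def f_measure(concept: FormalConcept, instance: Instance) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p = precision(concept, instance)
    r = recall(concept, instance)
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def congruity_score(
    lattice: ConceptLattice,
    instance: Instance,
    params: CongruityParams = CongruityParams(),
) -> CongruityResult:
    """Score one instance against the lattice; see the module docstring."""
    attrs = instance.attributes
    if not attrs:
        raise InvalidInstanceError(f"instance {instance.id!r} has no attributes")

    candidates = candidate_objects(lattice.context, instance)
    matched = matching_concepts(lattice, instance)
    if not matched:
        return CongruityResult(instance.id, 0.0, "none", candidates, ())

    printed = params.rounding == "printed"

    def prep(x: float) -> float:
        return round_half_up(x, 2) if printed else x

    exact = next((c for c in matched if c.intent == attrs), None)
    if exact is not None:
        s = prep(support(exact, candidates))
        value = params.alpha1 * s + params.alpha2  # F-measure is exactly 1
        match = ConceptMatch(
            exact.id, exact.intent, len(attrs), s, 1.0, 1.0, 1.0, value
        )
        matches = (match,)
    else:
        matches = []
        for c in sorted(matched, key=lambda c: c.id):
            s = prep(support(c, candidates))
            f = prep(f_measure(c, instance))
            term = params.alpha1 * s + params.alpha2 * f
            matches.append(
                ConceptMatch(
                    c.id,
                    c.intent,
                    len(attrs & c.intent),
                    s,
                    precision(c, instance),
                    recall(c, instance),
                    f,
                    term,
                )
            )
        matches = tuple(matches)
        value = sum(m.term for m in matches) / len(matches)

    if printed:
        value = round_half_up(value, 3)
    return CongruityResult(
        instance.id,
        value,
        "exact" if exact is not None else "partial",
        candidates,
        matches,
    )
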