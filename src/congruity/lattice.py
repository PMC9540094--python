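"""Concept lattice construction.

A formal concept of a context ``K = (G, M, I)`` is a pair ``(A, B)`` with
``A' = B`` and ``B' = A`` under the derivation operators (``A'`` = common
attributes of the objects in A, ``B'`` = common objects of the attributes
in B).  Ordered by extent inclusion, the concepts form a complete lattice.

Enumeration uses Ganter's NextClosure over attribute sets, on integer
bitmasks; correctness is defined against brute-force closure of every
attribute subset (see the test suite), not by the algorithm choice.

Reduced labeling: an object is an *own object* of the unique concept whose
intent equals the object's full attribute set; an attribute is an *own
attribute* of the concept that is the closure of that single attribute.
Own objects partition G across the lattice and give the support numerator
of the congruity measure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .formal_context import FormalContext

__all__ = [
    "FormalConcept",
    "ConceptLattice",
    "derive_extent",
    "derive_intent",
    "closure",
    "build_lattice",
    "concepts_by_attribute",
]


def derive_extent(context: FormalContext, attrs) -> frozenset[str]:
    """B′: all objects holding every attribute in ``attrs`` (∅ → all of G)."""
    attrs = frozenset(attrs)
    unknown = attrs - set(context.attributes)
    if unknown:
        raise KeyError(f"unknown attributes {sorted(unknown)}")
    return frozenset(
        g for g in context.objects if attrs <= context.incidence[g]
    )


def derive_intent(context: FormalContext, objects) -> frozenset[str]:
    """A′: attributes common to every object in ``objects`` (∅ → all of M)."""
    objects = frozenset(objects)
    unknown = objects - set(context.objects)
    if unknown:
        raise KeyError(f"unknown objects {sorted(unknown)}")
    common = set(context.attributes)
    for g in objects:
        common &= context.incidence[g]
    return frozenset(common)


def closure(context: FormalContext, attrs) -> frozenset[str]:
    """The closure B″ of an attribute set: idempotent, extensive, monotone."""
    return derive_intent(context, derive_extent(context, attrs))


@dataclass(frozen=True)
class FormalConcept:
    """A closed (extent, intent) pair with its reduced labels."""

    id: int
    extent: frozenset[str]
    intent: frozenset[str]
    own_objects: frozenset[str]
    own_attributes: frozenset[str]

    def __repr__(self):
        return (
            f"FormalConcept(id={self.id}, extent={sorted(self.extent)}, "
            f"intent={sorted(self.intent)})"
        )


class ConceptLattice:
    """All concepts of a context, with the cover (Hasse) relation.

    Concepts are ordered canonically by ``(|intent|, sorted intent)`` so ids
    are stable across runs; id 0 is the top concept (maximal extent) and the
    last id is the bottom (maximal intent).  Only cover edges are stored;
    the full order is answered from extent inclusion.
    """

    def __init__(self, context: FormalContext, concepts: list[FormalConcept],
                 covers: dict[int, tuple[int, ...]]):
        self.context = context
        self.concepts = concepts
        self.covers = covers  # concept id -> ids of its lower covers
        self._by_intent = {c.intent: c for c in concepts}
        intents = [c.intent for c in concepts]
        if len(set(intents)) != len(intents):
            raise ValueError("concept intents must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    @property
    def top(self) -> FormalConcept:
        return self.concepts[0]

    @property
    def bottom(self) -> FormalConcept:
        return self.concepts[-1]

    def concept_with_intent(self, intent) -> FormalConcept | None:
        return self._by_intent.get(frozenset(intent))

    def le(self, c1: FormalConcept, c2: FormalConcept) -> bool:
        """Subconcept order: C1 ≤ C2 iff extent(C1) ⊆ extent(C2)."""
        return c1.extent <= c2.extent

    def lower_covers(self, concept: FormalConcept) -> list[FormalConcept]:
        return [self.concepts[i] for i in self.covers[concept.id]]

    # -- serialization ------------------------------------------------------

    def context_hash(self) -> str:
        payload = json.dumps(
            {
                "objects": list(self.context.objects),
                "attributes": list(self.context.attributes),
                "incidence": {
                    g: sorted(self.context.incidence[g]) for g in self.context.objects
                },
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        doc = {
            "context": {
                "objects": list(self.context.objects),
                "attributes": list(self.context.attributes),
                "incidence": {
                    g: sorted(self.context.incidence[g]) for g in self.context.objects
                },
            },
            "context_hash": self.context_hash(),
            "concepts": [
                {
                    "id": c.id,
                    "extent": sorted(c.extent),
                    "intent": sorted(c.intent),
                    "own_objects": sorted(c.own_objects),
                    "own_attributes": sorted(c.own_attributes),
                }
                for c in self.concepts
            ],
            "covers": {str(i): list(self.covers[i]) for i in sorted(self.covers)},
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "ConceptLattice":
        doc = json.loads(text)
        ctx = FormalContext(
            tuple(doc["context"]["objects"]),
            tuple(doc["context"]["attributes"]),
            {g: frozenset(a) for g, a in doc["context"]["incidence"].items()},
        )
        concepts = [
            FormalConcept(
                id=c["id"],
                extent=frozenset(c["extent"]),
                intent=frozenset(c["intent"]),
                own_objects=frozenset(c["own_objects"]),
                own_attributes=frozenset(c["own_attributes"]),
            )
            for c in doc["concepts"]
        ]
        covers = {int(i): tuple(v) for i, v in doc["covers"].items()}
        return cls(ctx, concepts, covers)

    @classmethod
    def load(cls, path) -> "ConceptLattice":
        return cls.from_json(Path(path).read_text())


def _closed_attribute_sets(context: FormalContext) -> list[int]:
    """NextClosure enumeration of all closed intents, as attribute bitmasks."""
    m = len(context.attributes)
    attr_index = {a: i for i, a in enumerate(context.attributes)}
    full_objs = (1 << len(context.objects)) - 1
    full_attrs = (1 << m) - 1
    # column masks: objects holding each attribute; row masks: each object's intent
    row_masks = [
        sum(1 << attr_index[a] for a in context.incidence[g]) for g in context.objects
    ]
    col_masks = [0] * m
    for oi, rm in enumerate(row_masks):
        for ai in range(m):
            if rm >> ai & 1:
                col_masks[ai] |= 1 << oi

    def close(mask: int) -> int:
        extent = full_objs
        for ai in range(m):
            if mask >> ai & 1:
                extent &= col_masks[ai]
        intent = full_attrs
        rest = extent
        while rest:
            low = rest & -rest
            intent &= row_masks[low.bit_length() - 1]
            rest ^= low
        return intent

    closed = []
    current = close(0)
    closed.append(current)
    while current != full_attrs:
        # lectic successor: try adding attribute i (largest index first),
        # keep the closure only if it introduces nothing below i
        for i in range(m - 1, -1, -1):
            if current >> i & 1:
                current &= ~(1 << i)
                continue
            candidate = close(current | (1 << i))
            below = (1 << i) - 1
            if (candidate & below) == (current & below):
                current = candidate
                closed.append(current)
                break
        else:  # pragma: no cover - full_attrs always terminates the loop
            break
    return closed


def build_lattice(context: FormalContext) -> ConceptLattice:
    """Enumerate every formal concept of ``context`` and its cover relation."""
    m = len(context.attributes)
    attr_index = {a: i for i, a in enumerate(context.attributes)}
    attr_list = list(context.attributes)

    def mask_to_attrs(mask: int) -> frozenset[str]:
        return frozenset(attr_list[i] for i in range(m) if mask >> i & 1)

    closed_masks = _closed_attribute_sets(context)
    # canonical order: by intent size, then lexicographic on sorted names
    intents = sorted(
        (mask_to_attrs(mask) for mask in closed_masks),
        key=lambda s: (len(s), tuple(sorted(s))),
    )

    object_intents = {g: context.incidence[g] for g in context.objects}
    concepts: list[FormalConcept] = []
    for cid, intent in enumerate(intents):
        extent = derive_extent(context, intent)
        own_objects = frozenset(g for g in extent if object_intents[g] == intent)
        concepts.append(
            FormalConcept(
                id=cid,
                extent=extent,
                intent=intent,
                own_objects=own_objects,
                own_attributes=frozenset(),  # filled below
            )
        )
    # own attribute m: attached to the concept whose intent is closure({m})
    by_intent = {c.intent: c for c in concepts}
    own_attrs: dict[int, set[str]] = {c.id: set() for c in concepts}
    for a in context.attributes:
        host = by_intent[closure(context, {a})]
        own_attrs[host.id].add(a)
    concepts = [
        FormalConcept(c.id, c.extent, c.intent, c.own_objects,
                      frozenset(own_attrs[c.id]))
        for c in concepts
    ]

    # lower covers: C2 covers C1 iff C1 < C2 with nothing strictly between
    n = len(concepts)
    extents = [c.extent for c in concepts]
    covers: dict[int, tuple[int, ...]] = {}
    for i in range(n):
        subs = [j for j in range(n) if j != i and extents[j] < extents[i]]
        lower = []
        for j in subs:
            if not any(
                extents[j] < extents[k] and extents[k] < extents[i] for k in subs
            ):
                lower.append(j)
        covers[i] = tuple(sorted(lower))
    return ConceptLattice(context, concepts, covers)


def concepts_by_attribute(lattice: ConceptLattice) -> dict[str, tuple[int, ...]]:
    """Inverted index: attribute → ids of concepts whose intent contains it.

    Serves the role of the external concept index in deployment: matching
    candidates for an instance are the union of the postings of its
    attributes, never a scan of the whole lattice.
    """
    index: dict[str, list[int]] = {a: [] for a in lattice.context.attributes}
    for c in lattice.concepts:
        for a in c.intent:
            index[a].append(c.id)
    return {a: tuple(ids) for a, ids in index.items()}
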