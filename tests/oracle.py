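"""Brute-force reference implementations used as independent oracles.

Everything here works by exhaustive enumeration over the power set of
attributes and deliberately shares no code with the lattice construction
or scoring paths it is used to check.
"""

from itertools import combinations

import numpy as np

from congruity.formal_context import FormalContext


def enumerate_concepts_bruteforce(context: FormalContext) -> set:
    """All closed (extent, intent) pairs, by closing every attribute subset."""
    M = list(context.attributes)
    found = set()
    for r in range(len(M) + 1):
        for subset in combinations(M, r):
            attrs = frozenset(subset)
            extent = frozenset(
                g for g in context.objects if attrs <= context.incidence[g]
            )
            intent = set(M)
            for g in extent:
                intent &= context.incidence[g]
            found.add((extent, frozenset(intent)))
    return found


def congruity_bruteforce(
    context: FormalContext,
    instance_attrs: frozenset,
    alpha1: float = 0.1,
    alpha2: float = 0.9,
) -> float:
    """Direct transcription of the scoring case logic over enumerated concepts."""
    attrs = frozenset(instance_attrs)
    assert attrs, "reference undefined for empty attribute sets"
    candidates = {g for g in context.objects if attrs & context.incidence[g]}
    matching = [
        (A, B)
        for (A, B) in enumerate_concepts_bruteforce(context)
        if A and len(attrs & B) > len(attrs) / 2
    ]
    if not matching:
        return 0.0

    def sup(A, B):
        own = {g for g in A if context.incidence[g] == B}
        return len(own & candidates) / len(candidates)

    exact = [(A, B) for (A, B) in matching if B == attrs]
    if exact:
        A, B = exact[0]
        return alpha1 * sup(A, B) + alpha2

    total = 0.0
    for A, B in matching:
        p = len(attrs & B) / len(B)
        r = len(attrs & B) / len(attrs)
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        total += alpha1 * sup(A, B) + alpha2 * f
    return total / len(matching)


def random_context(
    rng: np.random.Generator, max_objects: int = 15, max_attributes: int = 10
) -> FormalContext:
    """A random context with at least one object and attribute."""
    n_g = int(rng.integers(1, max_objects + 1))
    n_m = int(rng.integers(1, max_attributes + 1))
    density = float(rng.uniform(0.2, 0.8))
    objects = tuple(f"g{i}" for i in range(n_g))
    attributes = tuple(f"m{j}" for j in range(n_m))
    incidence = {
        g: frozenset(a for a in attributes if rng.random() < density)
        for g in objects
    }
    return FormalContext(objects, attributes, incidence)
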