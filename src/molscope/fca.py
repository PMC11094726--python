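"""Formal concept analysis over a compound x fingerprint-bit context.

A formal context is a triple (U, A, R): objects U (compounds), attributes A
(fingerprint bits) and a binary relation R saying which compound has which bit
set.  A formal concept is a closed pair (extent, intent): the compounds in the
extent share exactly the bits of the intent, and no further compound has them
all.  Concepts ordered by extent inclusion form the concept lattice (Hasse
diagram); descending it trades specificity (more bits) for support (more
compounds).

Enumeration uses the classical intersection-closure construction: the set of
intents is exactly the set of intersections of subsets of object intents (plus
the full attribute set), built incrementally object by object with attribute
bitmasks.  Contexts here are small (tens of strongly-activating compounds by a
few hundred selected bits), but lattices are exponential in the worst case, so
both a context-size guard and a concept-count guard abort loudly rather than
hang.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "FormalContext",
    "FormalConcept",
    "FCAError",
    "build_context",
    "enumerate_concepts",
    "order_by_support",
]


class FCAError(ValueError):
    """Context exceeds the configured enumeration guards."""


@dataclass
class FormalContext:
    objects: list[Hashable]
    attributes: list[Hashable]
    relation: np.ndarray  # bool matrix, objects x attributes

    def __post_init__(self):
        self.relation = np.asarray(self.relation, dtype=bool)
        if self.relation.shape != (len(self.objects), len(self.attributes)):
            raise ValueError("relation shape does not match object/attribute lists")
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("duplicate object ids")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("duplicate attribute ids")


@dataclass(frozen=True)
class FormalConcept:
    extent: frozenset
    intent: frozenset

    @property
    def support(self) -> int:
        return len(self.extent)


def build_context(compounds: Sequence[tuple[Hashable, "Fingerprint"]], bits) -> FormalContext:
    """Context with R[c][b] = 1 iff bit ``b`` is on in compound ``c``.

    ``compounds`` is a sequence of (id, fingerprint) pairs; ``bits`` a set of
    bit ids (kept in sorted order as the attribute list).  Compounds with no
    selected bit keep their all-zero row.
    """
    if not compounds:
        raise ValueError("empty compound list")
    bit_list = sorted(int(b) for b in bits)
    if not bit_list:
        raise ValueError("empty bit set")
    rel = np.zeros((len(compounds), len(bit_list)), dtype=bool)
    col = {b: j for j, b in enumerate(bit_list)}
    for i, (_, fp) in enumerate(compounds):
        for b in fp.env_map:
            j = col.get(int(b))
            if j is not None:
                rel[i, j] = True
    return FormalContext([cid for cid, _ in compounds], bit_list, rel)


def enumerate_concepts(
    ctx: FormalContext,
    max_objects: int = 500,
    max_attributes: int = 300,
    max_concepts: int = 200_000,
) -> list[FormalConcept]:
    """All formal concepts of the context.

    Includes the top concept (intent = attributes common to every object,
    possibly empty) and the bottom concept (extent = objects carrying every
    attribute, possibly empty).
    """
    n_obj, n_attr = ctx.relation.shape
    if n_obj > max_objects or n_attr > max_attributes:
        raise FCAError(
            f"context {n_obj}x{n_attr} exceeds guard {max_objects}x{max_attributes}"
        )
    full = (1 << n_attr) - 1
    rows = []
    for i in range(n_obj):
        mask = 0
        for j in np.flatnonzero(ctx.relation[i]):
            mask |= 1 << int(j)
        rows.append(mask)
    # intents = all intersections of subsets of rows (empty subset -> full set)
    intents = {full}
    for r in rows:
        intents |= {s & r for s in intents}
        if len(intents) > max_concepts:
            raise FCAError(f"more than {max_concepts} concepts; aborting")
    concepts = []
    for intent_mask in intents:
        extent = frozenset(
            ctx.objects[i] for i, r in enumerate(rows) if r & intent_mask == intent_mask
        )
        intent = frozenset(
            ctx.attributes[j] for j in range(n_attr) if intent_mask >> j & 1
        )
        concepts.append(FormalConcept(extent=extent, intent=intent))
    return concepts


def order_by_support(concepts: Sequence[FormalConcept]) -> list[FormalConcept]:
    """Sort by decreasing support; ties broken toward the more generic concept
    (smaller intent first), then lexicographically on the sorted intent ids."""
    return sorted(
        concepts,
        key=lambda c: (-c.support, len(c.intent), tuple(sorted(map(str, c.intent)))),
    )


def concept_to_dict(c: FormalConcept) -> dict:
    return {"extent": sorted(map(str, c.extent)), "intent": sorted(c.intent)}


def hasse_edges(concepts: Sequence[FormalConcept]) -> list[tuple[int, int]]:
    """Cover relations (i -> j means concept i is an immediate superconcept of j,
    i.e. extent_j < extent_i with nothing in between).  For DOT export only."""
    edges = []
    n = len(concepts)
    for i in range(n):
        for j in range(n):
            if i == j or not concepts[j].extent < concepts[i].extent:
                continue
            if any(
                concepts[j].extent < concepts[k].extent < concepts[i].extent
                for k in range(n)
                if k not in (i, j)
            ):
                continue
            edges.append((i, j))
    return edges


def to_dot(concepts: Sequence[FormalConcept]) -> str:
    """DOT rendering of the Hasse diagram (top concept at the top)."""
    lines = ["digraph lattice {", "  rankdir=TB;"]
    for i, c in enumerate(concepts):
        ext = ",".join(sorted(map(str, c.extent))) or "{}"
        inten = ",".join(str(a) for a in sorted(c.intent)) or "{}"
        lines.append(f'  n{i} [shape=box, label="{ext}\\n{inten}"];')
    for i, j in hasse_edges(concepts):
        lines.append(f"  n{i} -> n{j};")
    lines.append("}")
    return "\n".join(lines)
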