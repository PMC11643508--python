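"""Synthetic hypergraphs with a tunable, planted inclusion structure.

The planted-inclusion model draws a set of "intended maximal" edges (sizes
from a user distribution, members uniform without replacement) and then
adds each allowed subface of each drawn edge independently with
probability ``q``.  At ``q = 1`` the output is its own induced restricted
simplicial complex (all measures 1); at ``q = 0`` with mutually
non-including drawn edges there are no inclusions at all (all measures 0).
Sweeping ``q`` therefore traces the whole simpliciality spectrum and is
the workhorse for calibrating and sanity-checking the measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Hypergraph, SizeRestriction, restricted_powerset, sort_key

__all__ = ["PlantedInclusionSpec", "generate_planted_inclusion"]


@dataclass(frozen=True)
class PlantedInclusionSpec:
    """Parameters of the planted-inclusion model.

    ``size_distribution`` maps edge size (within 2..max_size of the
    restriction) to probability; ``inclusion_probability`` is the chance
    ``q`` that any given allowed subface of a drawn edge is present.
    """

    n_nodes: int = 50
    n_maximal_edges: int = 20
    size_distribution: dict = field(default_factory=lambda: {3: 0.5, 4: 0.3, 5: 0.2})
    inclusion_probability: float = 0.5
    seed: int | None = None
    restriction: SizeRestriction = field(default_factory=SizeRestriction)

    def __post_init__(self):
        total = sum(self.size_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"size probabilities must sum to 1 (got {total})")
        if not 0.0 <= self.inclusion_probability <= 1.0:
            raise ValueError("inclusion_probability must lie in [0, 1]")
        for s in self.size_distribution:
            if s < 2 or s > self.restriction.max_size:
                raise ValueError(
                    f"edge size {s} outside 2..{self.restriction.max_size}"
                )
            if s > self.n_nodes:
                raise ValueError(f"requested size {s} exceeds n_nodes={self.n_nodes}")


def generate_planted_inclusion(spec: PlantedInclusionSpec) -> Hypergraph:
    """Draw one hypergraph from the planted-inclusion model.

    Deterministic given ``spec.seed``.  The result is canonicalised: a
    subface present both as a drawn edge and as an included face appears
    once.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = sorted(spec.size_distribution)
    probs = [spec.size_distribution[s] for s in sizes]
    nodes = list(range(spec.n_nodes))
    q = spec.inclusion_probability

    edges = []
    for _ in range(spec.n_maximal_edges):
        s = int(rng.choice(sizes, p=probs))
        base = frozenset(int(v) for v in rng.choice(nodes, size=s, replace=False))
        edges.append(base)
        subfaces = [
            f for f in restricted_powerset(base, spec.restriction) if f != base
        ]
        # sorted for draw-order determinism across platforms
        subfaces.sort(key=lambda f: (len(f), [sort_key(x) for x in sorted(f, key=sort_key)]))
        if q >= 1.0:
            edges.extend(subfaces)
        elif q > 0.0:
            keep = rng.random(len(subfaces)) < q
            edges.extend(f for f, k in zip(subfaces, keep) if k)
    return Hypergraph(edges)
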