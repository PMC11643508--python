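"""Hypergraph data model and the combinatorial primitives behind simpliciality.

A hypergraph is a pair ``H = (V, E)``: a set of nodes and a set of
hyperedges, each hyperedge an arbitrary-size subset of the nodes.  We work
exclusively with *simple* hypergraphs — no repeated edges, no repeated
nodes within an edge.  The measures in :mod:`simpliciality.measures` are
built on four primitives defined here:

* *maximal edges* — edges not strictly contained in any other edge;
* the *size-restricted power set* ``P_K(e)`` — subsets of an edge whose
  size lies in an allowed set ``K`` (by default ``{2, …, 11}``, excluding
  the empty set and singletons);
* *minimal faces* — edges of size ``min(K)``, which are trivially
  simplices because no smaller allowed subface exists;
* the *induced simplicial complex* ``C`` — the union of the restricted
  power sets of all maximal edges, i.e. the smallest edge set containing
  the maximal edges that satisfies (size-restricted) downward closure.

Edges are canonicalised to :class:`frozenset` so membership tests are
O(1) expected; node labels are opaque and only compared for equality
(integer and string labels both work, including mixed).
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Collection, Hashable, Iterable, Iterator

Node = Hashable
Edge = frozenset

__all__ = [
    "Hypergraph",
    "SizeRestriction",
    "build_hypergraph",
    "preprocess",
    "maximal_edges",
    "restricted_powerset",
    "restricted_powerset_size",
    "minimal_faces",
    "is_simplex",
    "induced_simplicial_complex",
    "sort_key",
]


def sort_key(label: Node):
    """Deterministic ordering key for possibly mixed-type node labels."""
    return (str(label), type(label).__name__)


@dataclass(frozen=True)
class SizeRestriction:
    """The allowed subface sizes ``K`` plus a hard cap on edge size.

    Parameters
    ----------
    allowed_sizes
        The finite set ``K`` of subface sizes that count toward downward
        closure.  The default analysis uses ``K = {2, …, 11}``: singletons
        and the empty set are excluded because many datasets (proximity
        contacts, emails) cannot contain them by construction.
    max_size
        Edges larger than this are dropped during preprocessing — the
        number of potential subfaces grows as ``2^|e|``, so a cap keeps
        the measures computable.  Default 11.
    """

    allowed_sizes: frozenset = field(default_factory=lambda: frozenset(range(2, 12)))
    max_size: int = 11

    def __post_init__(self):
        sizes = frozenset(int(s) for s in self.allowed_sizes)
        if not sizes:
            raise ValueError("allowed_sizes must be non-empty")
        if min(sizes) < 1:
            raise ValueError("allowed_sizes must be positive integers")
        object.__setattr__(self, "allowed_sizes", sizes)
        if self.max_size < max(sizes):
            raise ValueError(
                f"max_size={self.max_size} is below max(allowed_sizes)={max(sizes)}"
            )

    @classmethod
    def from_bounds(cls, min_size: int = 2, max_size: int = 11) -> "SizeRestriction":
        """``K = {min_size, …, max_size}`` — the common contiguous case."""
        if min_size < 1 or max_size < min_size:
            raise ValueError("need 1 <= min_size <= max_size")
        return cls(frozenset(range(min_size, max_size + 1)), max_size)

    @property
    def min_allowed(self) -> int:
        return min(self.allowed_sizes)


DEFAULT_RESTRICTION = SizeRestriction()


class Hypergraph:
    """A simple hypergraph: node set ``V`` plus a set of canonical edges ``E``.

    Construct directly from an iterable of node collections (duplicates
    and within-edge repetitions are collapsed), or via
    :func:`build_hypergraph`.  Nodes with no incident edge may be carried
    explicitly through ``extra_nodes``.
    """

    __slots__ = ("_edges", "_nodes", "_incidence")

    def __init__(
        self,
        edges: Iterable[Collection[Node]] = (),
        extra_nodes: Iterable[Node] = (),
    ):
        self._edges: frozenset = frozenset(frozenset(e) for e in edges if len(e) > 0)
        nodes = set(extra_nodes)
        incidence: dict = defaultdict(set)
        for e in self._edges:
            for v in e:
                incidence[v].add(e)
        nodes.update(incidence)
        self._nodes = frozenset(nodes)
        self._incidence = dict(incidence)

    # -- basic container protocol ------------------------------------
    @property
    def nodes(self) -> frozenset:
        return self._nodes

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def num_nodes(self) -> int:
        return len(self._nodes)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, edge: Collection[Node]) -> bool:
        return frozenset(edge) in self._edges

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self):
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:
        return f"Hypergraph(|V|={self.num_nodes}, |E|={self.num_edges})"

    # -- structure ----------------------------------------------------
    def incident_edges(self, v: Node) -> frozenset:
        """Edges containing node ``v`` (empty for isolated nodes)."""
        if v not in self._nodes:
            raise KeyError(f"node {v!r} not in hypergraph")
        return frozenset(self._incidence.get(v, ()))

    def degree(self, v: Node) -> int:
        if v not in self._nodes:
            raise KeyError(f"node {v!r} not in hypergraph")
        return len(self._incidence.get(v, ()))

    def degrees(self) -> dict:
        return {v: len(self._incidence.get(v, ())) for v in self._nodes}

    def edge_sizes(self) -> list:
        return sorted(len(e) for e in self._edges)

    def mean_degree(self) -> float:
        if not self._nodes:
            return float("nan")
        return sum(len(e) for e in self._edges) / self.num_nodes

    def mean_edge_size(self) -> float:
        if not self._edges:
            return float("nan")
        return sum(len(e) for e in self._edges) / self.num_edges

    def sorted_edges(self) -> list:
        """Edges as sorted tuples, deterministically ordered — for writers."""
        return sorted(
            (tuple(sorted(e, key=sort_key)) for e in self._edges),
            key=lambda t: (len(t), [sort_key(x) for x in t]),
        )


def build_hypergraph(raw_edges: Iterable[Collection[Node]]) -> Hypergraph:
    """Canonicalise raw edge data into a simple :class:`Hypergraph`.

    Repeated nodes within an edge and duplicate edges collapse under set
    semantics; the node set is the union of edge members.  An empty input
    yields a valid empty hypergraph (on which every measure is undefined).
    """
    return Hypergraph(raw_edges)


def preprocess(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> Hypergraph:
    """Apply the standard cleaning used before measuring simpliciality.

    Removes singleton edges, edges larger than ``restriction.max_size``
    (the size cap is applied first), and then nodes left without any
    incident edge.  Idempotent.
    """
    kept = [e for e in h.edges if 2 <= len(e) <= restriction.max_size]
    return Hypergraph(kept)


def maximal_edges(h: Hypergraph) -> frozenset:
    """The edges of ``h`` not strictly contained in any other edge.

    Uses the per-node incidence index: an edge can only be contained in a
    larger edge incident to (any) one of its nodes, so each edge is tested
    against the incident edges of its lowest-degree member rather than
    against all of ``E``.
    """
    out = []
    for e in h.edges:
        pivot = min(e, key=h.degree)
        if not any(
            len(f) > len(e) and e < f for f in h.incident_edges(pivot)
        ):
            out.append(e)
    return frozenset(out)


def restricted_powerset(
    e: Collection[Node], restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> set:
    """``P_K(e)``: all subsets of ``e`` whose size lies in ``K``.

    Includes ``e`` itself iff ``|e|`` is in ``K``.  Raises if ``e`` exceeds
    the size cap — oversized edges must be filtered by :func:`preprocess`
    before subface enumeration is attempted.
    """
    e = frozenset(e)
    if len(e) > restriction.max_size:
        raise ValueError(
            f"edge of size {len(e)} exceeds max_size={restriction.max_size}; "
            "preprocess the hypergraph first"
        )
    members = tuple(e)
    out = set()
    for m in restriction.allowed_sizes:
        if m <= len(members):
            out.update(map(frozenset, itertools.combinations(members, m)))
    return out


def restricted_powerset_size(
    size: int, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> int:
    """``|P_K(e)|`` for ``|e| = size``, without enumerating subsets."""
    return sum(
        math.comb(size, m) for m in restriction.allowed_sizes if m <= size
    )


def minimal_faces(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> frozenset:
    """Edges of size ``min(K)`` — trivially simplices under the restriction."""
    m = restriction.min_allowed
    return frozenset(e for e in h.edges if len(e) == m)


def is_simplex(
    e: Collection[Node],
    h: Hypergraph,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
) -> bool:
    """Whether edge ``e`` of ``h`` has every allowed subface present.

    ``e`` is a simplex iff every subset of ``e`` with size in
    ``K ∩ {1, …, |e|}`` is itself an edge of ``h``.  Requires ``e ∈ E``.
    """
    e = frozenset(e)
    if e not in h.edges:
        raise KeyError(f"edge {set(e)!r} is not an edge of the hypergraph")
    members = tuple(e)
    for m in restriction.allowed_sizes:
        if m < len(members):
            for sub in itertools.combinations(members, m):
                if frozenset(sub) not in h.edges:
                    return False
    return True


def induced_simplicial_complex(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> set:
    """The induced (size-restricted) simplicial complex ``C`` of ``h``.

    ``C = ⋃_{ẽ ∈ Ẽ} P_K(ẽ)`` — the smallest downward-closed edge set (under
    the restriction) covering all maximal edges.  Empty for an empty
    hypergraph.
    """
    out: set = set()
    for e in maximal_edges(h):
        out |= restricted_powerset(e, restriction)
    return out
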