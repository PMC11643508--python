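"""Local simpliciality: ego-hypergraphs, nodal values and simplicial assortativity.

The neighbourhood of a node ``v`` is ``n(v) = {u : u, v share an edge}``;
its *ego-hypergraph* is the subhypergraph on ``V̂ = {v} ∪ n(v)`` whose edge
set is every edge of ``E`` fully contained in ``V̂`` (including edges that
do not touch ``v`` itself).  The nodal simpliciality of ``v`` under a
measure is that measure evaluated on the ego-hypergraph; it inherits the
measure's undefined cases (isolated nodes, ego-hypergraphs containing only
minimal faces).

*Simplicial assortativity* asks whether adjacent nodes have similar local
simpliciality: it is the Pearson correlation of nodal values over ordered
pairs of nodes that share at least one hyperedge — equivalently, the
attribute assortativity coefficient of the nodal values on the unweighted
pairwise projection of the hypergraph.  Pairs with an undefined endpoint
are dropped rather than imputed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse, stats

from .core import DEFAULT_RESTRICTION, Hypergraph, SizeRestriction, sort_key
from .measures import MEASURES, Undefined, is_defined

__all__ = [
    "EgoHypergraph",
    "ego_hypergraph",
    "nodal_simpliciality",
    "incidence_matrix",
    "projection_adjacency",
    "adjacent_pairs",
    "simplicial_assortativity",
    "measure_correlations",
]

ISOLATED = "isolated-node"
TOO_FEW_PAIRS = "too-few-pairs"
ZERO_VARIANCE = "zero-variance"


@dataclass(frozen=True)
class EgoHypergraph:
    """The subhypergraph induced on a node's neighbourhood."""

    center: object
    neighborhood: frozenset
    hypergraph: Hypergraph

    @property
    def nodes(self) -> frozenset:
        return self.hypergraph.nodes | {self.center}

    @property
    def edges(self) -> frozenset:
        return self.hypergraph.edges


def ego_hypergraph(h: Hypergraph, v) -> EgoHypergraph:
    """Extract the ego-hypergraph of node ``v``.

    ``Ê`` contains every edge of ``E`` included in ``{v} ∪ n(v)`` — not only
    the edges incident on ``v``.  An isolated node yields an empty edge set.
    """
    if v not in h.nodes:
        raise KeyError(f"node {v!r} not in hypergraph")
    neighborhood = set()
    for e in h.incident_edges(v):
        neighborhood |= e
    neighborhood.discard(v)
    hat_v = neighborhood | {v}
    hat_e = [e for e in h.edges if e <= hat_v]
    return EgoHypergraph(v, frozenset(neighborhood), Hypergraph(hat_e, extra_nodes=hat_v))


def nodal_simpliciality(
    h: Hypergraph,
    measure: str = "fes",
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
) -> dict:
    """Per-node local simpliciality under ``measure`` ∈ {'sf', 'es', 'fes'}.

    Returns a mapping node → Fraction or :class:`Undefined`.  Isolated
    nodes are flagged rather than scored.
    """
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    out = {}
    for v in h.nodes:
        if h.degree(v) == 0:
            out[v] = Undefined(ISOLATED)
            continue
        out[v] = fn(ego_hypergraph(h, v).hypergraph, restriction)
    return out


def incidence_matrix(h: Hypergraph):
    """Sparse node-edge incidence matrix B plus the node/edge orderings."""
    nodes = sorted(h.nodes, key=sort_key)
    edges = h.sorted_edges()
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for j, e in enumerate(edges):
        for v in e:
            rows.append(index[v])
            cols.append(j)
    b = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(nodes), len(edges)),
    )
    return b, nodes, edges


def projection_adjacency(h: Hypergraph):
    """Unweighted pairwise projection: A_ij = 1 iff i ≠ j share an edge.

    Computed as the binarised, zero-diagonal pattern of B Bᵀ.  Returns
    ``(A, nodes)`` with A a sparse CSR matrix over the sorted node order.
    """
    b, nodes, _ = incidence_matrix(h)
    a = (b @ b.T).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    a.data = np.ones_like(a.data)
    return a, nodes


def adjacent_pairs(h: Hypergraph):
    """All unordered node pairs sharing at least one edge."""
    pairs = set()
    for e in h.edges:
        pairs.update(frozenset(p) for p in itertools.combinations(e, 2))
    return pairs


def simplicial_assortativity(
    h: Hypergraph,
    measure: str = "fes",
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
    nodal_values: dict | None = None,
):
    """Pearson correlation of nodal simpliciality across adjacent node pairs.

    Every unordered adjacent pair with both endpoints defined contributes
    both orientations (i, j) and (j, i), which makes the statistic the
    standard attribute assortativity coefficient on the projection.
    Returns a float, or :class:`Undefined` when fewer than two usable
    pairs remain or the endpoint values have zero variance.
    """
    if nodal_values is None:
        nodal_values = nodal_simpliciality(h, measure, restriction)
    xs, ys = [], []
    for pair in adjacent_pairs(h):
        i, j = tuple(pair)
        si, sj = nodal_values.get(i), nodal_values.get(j)
        if si is None or sj is None or not (is_defined(si) and is_defined(sj)):
            continue
        xs.extend((float(si), float(sj)))
        ys.extend((float(sj), float(si)))
    if len(xs) < 4:  # fewer than 2 unordered pairs
        return Undefined(TOO_FEW_PAIRS)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return Undefined(ZERO_VARIANCE)
    return float(stats.pearsonr(x, y).statistic)


def measure_correlations(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "pearson",
):
    """Correlation between two measure series with a two-sided p-value.

    ``method`` is 'pearson' (product-moment) or 'spearman' (rank).
    Returns ``(coefficient, p_value)``; :class:`Undefined` on zero-variance
    input or fewer than three observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("input sequences must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return Undefined(ZERO_VARIANCE), None
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
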