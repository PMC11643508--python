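"""Global simpliciality measures: how far a hypergraph is from downward closure.

Three normalised measures, each in [0, 1] when defined:

* **Simplicial fraction** (SF): the fraction of edges that are simplices,
  ``σ_SF = |S| / |E|``, where ``S`` is the set of edges all of whose allowed
  subfaces are present.
* **Edit simpliciality** (ES): one minus the normalised number of edges
  that must be added to reach the induced simplicial complex ``C``,
  ``σ_ES = (|E| − |Ẽ|) / (|C| − |Ẽ|)`` with ``Ẽ`` the maximal edges.
* **Face edit simpliciality** (FES): the mean, over maximal edges, of the
  per-face completeness ``1 − d_FES(e) / (|P_K(e)| − 1)``, where
  ``d_FES(e)`` counts the allowed subfaces of ``e`` missing from ``E``.

Minimal faces — edges of size ``min(K)`` — are trivially simplices (no
smaller allowed subface exists), so they are excluded wherever they would
inflate a measure: SF drops them from both numerator and denominator, ES
and FES drop maximal edges that are also minimal faces.  For ES the
excluded maximal-minimal faces are removed from ``Ẽ``, from ``C`` *and*
from the edge count, which keeps the ratio within [0, 1].

Degenerate denominators (empty hypergraph, no candidate edge, only
minimal-sized maximal edges) yield an explicit :class:`Undefined` value
carrying a reason code — never a silent 0 or 1.  All ratios are computed
as exact :class:`fractions.Fraction` and only converted to float at the
reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Union

from .core import (
    DEFAULT_RESTRICTION,
    Hypergraph,
    SizeRestriction,
    is_simplex,
    maximal_edges,
    restricted_powerset,
    restricted_powerset_size,
)

__all__ = [
    "Undefined",
    "is_defined",
    "as_float",
    "SimplicialityReport",
    "simplicial_fraction",
    "edit_simpliciality",
    "simplicial_edit_distance",
    "face_edit_distance",
    "face_edit_simpliciality",
    "mean_face_edit_distance",
    "full_report",
    "MEASURES",
]


@dataclass(frozen=True)
class Undefined:
    """Explicit not-a-value for measures with a degenerate denominator."""

    reason: str

    def __repr__(self) -> str:
        return f"Undefined({self.reason!r})"


MeasureValue = Union[Fraction, Undefined]

#: reason codes
EMPTY = "empty-hypergraph"
NO_CANDIDATES = "no-candidate-edges"
DEGENERATE = "degenerate-denominator"


def is_defined(x) -> bool:
    return not isinstance(x, Undefined)


def as_float(x) -> float:
    """Float view of a measure value; Undefined maps to NaN."""
    return float("nan") if isinstance(x, Undefined) else float(x)


def _candidate_edges(h: Hypergraph, restriction: SizeRestriction):
    """Edges that could be non-trivial simplices: size strictly above min(K)."""
    m = restriction.min_allowed
    return [e for e in h.edges if len(e) > m]


def _nonminimal_maximal(h: Hypergraph, restriction: SizeRestriction, _maximal=None):
    m = restriction.min_allowed
    if _maximal is None:
        _maximal = maximal_edges(h)
    return frozenset(e for e in _maximal if len(e) > m)


def simplicial_fraction(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> MeasureValue:
    """σ_SF: the fraction of non-minimal edges that are simplices.

    Undefined when the hypergraph is empty or every edge is a minimal
    face (nothing could be a non-trivial simplex).
    """
    if h.num_edges == 0:
        return Undefined(EMPTY)
    candidates = _candidate_edges(h, restriction)
    if not candidates:
        return Undefined(NO_CANDIDATES)
    n_simplices = sum(1 for e in candidates if is_simplex(e, h, restriction))
    return Fraction(n_simplices, len(candidates))


def _es_counts(h: Hypergraph, restriction: SizeRestriction, _maximal=None):
    """(|E'|, |Ẽ'|, |C'|) with maximal-minimal faces excluded throughout.

    Ẽ' is the set of maximal edges larger than min(K); C' the union of
    their restricted power sets; E' the edges (with allowed size) included
    in some member of Ẽ'.  E' ⊆ C' by construction, so the ES ratio cannot
    exceed 1.
    """
    tilde = _nonminimal_maximal(h, restriction, _maximal)
    complex_edges: set = set()
    for e in tilde:
        complex_edges |= restricted_powerset(e, restriction)
    by_node: dict = {}
    for t in tilde:
        for v in t:
            by_node.setdefault(v, []).append(t)
    n_included = 0
    for e in h.edges:
        if len(e) not in restriction.allowed_sizes:
            continue
        pivot = min(e, key=lambda v: len(by_node.get(v, ())))
        if any(e <= t for t in by_node.get(pivot, ())):
            n_included += 1
    return n_included, len(tilde), len(complex_edges)


def edit_simpliciality(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> MeasureValue:
    """σ_ES = (|E'| − |Ẽ'|) / (|C'| − |Ẽ'|).

    Counts how much of the induced simplicial complex is already present,
    discounting the maximal edges themselves (so a hypergraph with no
    inclusions scores 0).  Undefined when the hypergraph is empty or every
    maximal edge is a minimal face.
    """
    if h.num_edges == 0:
        return Undefined(EMPTY)
    n_edges, n_tilde, n_complex = _es_counts(h, restriction)
    if n_complex == n_tilde:
        return Undefined(DEGENERATE)
    return Fraction(n_edges - n_tilde, n_complex - n_tilde)


def simplicial_edit_distance(
    h: Hypergraph,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
    normalized: bool = False,
) -> MeasureValue:
    """d_ES = |C'| − |E'| (edges to add); normalised form is 1 − σ_ES."""
    if normalized:
        es = edit_simpliciality(h, restriction)
        return es if isinstance(es, Undefined) else 1 - es
    if h.num_edges == 0:
        return Undefined(EMPTY)
    n_edges, _, n_complex = _es_counts(h, restriction)
    return Fraction(n_complex - n_edges)


def face_edit_distance(
    e,
    h: Hypergraph,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
) -> int:
    """d_FES(e) = |P_K(e)| − |{f ∈ E : f ⊆ e, |f| ∈ K}|.

    The number of allowed subfaces of ``e`` (including ``e`` itself when
    its size is allowed) missing from the edge set.  Zero iff ``e`` is a
    simplex.  Requires ``e ∈ E``.
    """
    e = frozenset(e)
    if e not in h.edges:
        raise KeyError(f"edge {set(e)!r} is not an edge of the hypergraph")
    subfaces = restricted_powerset(e, restriction)
    present = sum(1 for f in subfaces if f in h.edges)
    return len(subfaces) - present


def _fes_terms(h: Hypergraph, restriction: SizeRestriction, _maximal=None):
    """Per-face (d_FES(e), |P_K(e)| − 1) over F = non-minimal maximal edges."""
    faces = _nonminimal_maximal(h, restriction, _maximal)
    return [
        (face_edit_distance(e, h, restriction),
         restricted_powerset_size(len(e), restriction) - 1)
        for e in faces
    ]


def face_edit_simpliciality(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> MeasureValue:
    """σ_FES: mean per-face completeness over non-minimal maximal edges.

    Each maximal edge contributes ``1 − d_FES(e)/(|P_K(e)| − 1)``; the −1
    discounts the face itself so an edge with no subfaces present scores 0.
    Undefined when no maximal edge exceeds the minimal size.
    """
    if h.num_edges == 0:
        return Undefined(EMPTY)
    terms = _fes_terms(h, restriction)
    if not terms:
        return Undefined(DEGENERATE)
    total = sum(1 - Fraction(d, denom) for d, denom in terms)
    return total / len(terms)


def mean_face_edit_distance(
    h: Hypergraph,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
    normalized: bool = False,
) -> MeasureValue:
    """d̄_FES (mean missing-subface count per maximal face) or d̄_NFES = 1 − σ_FES."""
    if h.num_edges == 0:
        return Undefined(EMPTY)
    terms = _fes_terms(h, restriction)
    if not terms:
        return Undefined(DEGENERATE)
    if normalized:
        return sum(Fraction(d, denom) for d, denom in terms) / len(terms)
    return Fraction(sum(d for d, _ in terms), len(terms))


@dataclass(frozen=True)
class SimplicialityReport:
    """All global measures of one hypergraph, plus the counts behind them.

    ``counts`` records |E|, |Ẽ|, and the primed quantities entering each
    ratio (|E'|, |Ẽ'|, |C'|, |S'|, number of SF candidates) so that any
    discrepancy with an external computation can be diagnosed.
    """

    sf: MeasureValue
    es: MeasureValue
    fes: MeasureValue
    es_distance: MeasureValue
    es_distance_normalized: MeasureValue
    mean_face_edit_distance: MeasureValue
    mean_normalized_face_edit_distance: MeasureValue
    counts: dict = field(default_factory=dict)

    def as_dict(self, floats: bool = True) -> dict:
        """Plain-dict view; with ``floats`` undefined values become None
        and a companion ``<name>_undefined_reason`` key is added."""
        out = {}
        for name in (
            "sf",
            "es",
            "fes",
            "es_distance",
            "es_distance_normalized",
            "mean_face_edit_distance",
            "mean_normalized_face_edit_distance",
        ):
            val = getattr(self, name)
            if isinstance(val, Undefined):
                out[name] = None
                out[f"{name}_undefined_reason"] = val.reason
            else:
                out[name] = float(val) if floats else val
        out["counts"] = dict(self.counts)
        return out


def full_report(
    h: Hypergraph, restriction: SizeRestriction = DEFAULT_RESTRICTION
) -> SimplicialityReport:
    """Compute every global measure once, sharing the maximal-edge work."""
    if h.num_edges == 0:
        u = Undefined(EMPTY)
        return SimplicialityReport(u, u, u, u, u, u, u, {"n_edges": 0, "n_nodes": h.num_nodes})

    maximal = maximal_edges(h)
    candidates = _candidate_edges(h, restriction)
    n_simplices = sum(1 for e in candidates if is_simplex(e, h, restriction))
    sf = (
        Fraction(n_simplices, len(candidates))
        if candidates
        else Undefined(NO_CANDIDATES)
    )

    n_edges, n_tilde, n_complex = _es_counts(h, restriction, maximal)
    if n_complex == n_tilde:
        es: MeasureValue = Undefined(DEGENERATE)
        d_es: MeasureValue = Undefined(DEGENERATE)
        d_nes: MeasureValue = Undefined(DEGENERATE)
    else:
        es = Fraction(n_edges - n_tilde, n_complex - n_tilde)
        d_es = Fraction(n_complex - n_edges)
        d_nes = 1 - es

    terms = _fes_terms(h, restriction, maximal)
    if not terms:
        fes: MeasureValue = Undefined(DEGENERATE)
        d_fes: MeasureValue = Undefined(DEGENERATE)
        d_nfes: MeasureValue = Undefined(DEGENERATE)
    else:
        d_nfes = sum(Fraction(d, denom) for d, denom in terms) / len(terms)
        fes = 1 - d_nfes
        d_fes = Fraction(sum(d for d, _ in terms), len(terms))

    counts = {
        "n_nodes": h.num_nodes,
        "n_edges": h.num_edges,
        "n_maximal": len(maximal),
        "n_sf_candidates": len(candidates),
        "n_simplices": n_simplices,
        "n_es_edges": n_edges,
        "n_es_maximal": n_tilde,
        "n_es_complex": n_complex,
        "n_fes_faces": len(terms),
    }
    return SimplicialityReport(sf, es, fes, d_es, d_nes, d_fes, d_nfes, counts)


#: name → callable, for measure selection by string key
MEASURES = {
    "sf": simplicial_fraction,
    "es": edit_simpliciality,
    "fes": face_edit_simpliciality,
}
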