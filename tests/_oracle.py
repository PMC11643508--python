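"""Brute-force reference implementations used only as test oracles.

Everything here enumerates the full power set of every edge with
:mod:`itertools` and filters by size afterwards — deliberately naive and
independent of the package's per-size combination enumeration, incidence
indexes and shared-computation paths.  All ratios are exact Fractions.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def full_powerset(e):
    members = tuple(e)
    out = []
    for r in range(len(members) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(members, r))
    return out


def powerset_k(e, allowed_sizes):
    return {x for x in full_powerset(e) if len(x) in allowed_sizes}


def brute_maximal(edges):
    edges = [frozenset(e) for e in edges]
    return {e for e in edges if not any(e < f for f in edges)}


def brute_is_simplex(e, edges, allowed_sizes):
    required = {x for x in full_powerset(e) if len(x) in allowed_sizes and len(x) <= len(e)}
    return required <= set(edges)


def brute_sf(edges, allowed_sizes):
    edges = {frozenset(e) for e in edges}
    mink = min(allowed_sizes)
    candidates = [e for e in edges if len(e) > mink]
    if not candidates:
        return None
    simplices = [e for e in candidates if brute_is_simplex(e, edges, allowed_sizes)]
    return Fraction(len(simplices), len(candidates))


def brute_es(edges, allowed_sizes):
    edges = {frozenset(e) for e in edges}
    mink = min(allowed_sizes)
    tilde = {e for e in brute_maximal(edges) if len(e) > mink}
    complex_edges = set()
    for t in tilde:
        complex_edges |= powerset_k(t, allowed_sizes)
    covered = {
        e for e in edges if len(e) in allowed_sizes and any(e <= t for t in tilde)
    }
    if len(complex_edges) == len(tilde):
        return None
    return Fraction(len(covered) - len(tilde), len(complex_edges) - len(tilde))


def brute_fes(edges, allowed_sizes):
    edges = {frozenset(e) for e in edges}
    mink = min(allowed_sizes)
    faces = {e for e in brute_maximal(edges) if len(e) > mink}
    if not faces:
        return None
    total = Fraction(0)
    for e in faces:
        pk = powerset_k(e, allowed_sizes)
        present = {f for f in pk if f in edges}
        d = len(pk) - len(present)
        total += 1 - Fraction(d, len(pk) - 1)
    return total / len(faces)
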