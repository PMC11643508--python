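"""Hypergraph data model and combinatorial primitives."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from simpliciality import (
    Hypergraph,
    SizeRestriction,
    build_hypergraph,
    induced_simplicial_complex,
    is_simplex,
    maximal_edges,
    minimal_faces,
    preprocess,
    restricted_powerset,
)
from simpliciality.core import restricted_powerset_size

from _oracle import brute_maximal, powerset_k

from conftest import random_hypergraph


class TestBuild:
    def test_set_semantics_collapse_duplicates(self):
        h = build_hypergraph([[1, 2], [2, 1], [1, 1, 2, 3]])
        assert h.edges == {frozenset({1, 2}), frozenset({1, 2, 3})}
        assert h.nodes == {1, 2, 3}

    def test_empty_input_is_valid_empty_hypergraph(self):
        h = build_hypergraph([])
        assert h.num_nodes == 0 and h.num_edges == 0

    def test_random_dedup_matches_brute_force(self, rng):
        raw = []
        for _ in range(100):
            s = int(rng.integers(2, 5))
            e = rng.integers(0, 8, size=s).tolist()  # repeats within edges likely
            raw.append(e)
            if rng.random() < 0.3:
                raw.append(list(reversed(e)))  # injected duplicate
        h = build_hypergraph(raw)
        distinct = {frozenset(e) for e in raw if len(frozenset(e)) > 0}
        assert h.edges == distinct

    def test_mixed_label_types(self):
        h = build_hypergraph([["a", 1], [1, 2]])
        assert h.num_edges == 2
        assert frozenset({"a", 1}) in h.edges


class TestPreprocess:
    def test_stated_filters(self):
        h = build_hypergraph([[1], [1, 2], list(range(1, 13))])
        clean = preprocess(h, SizeRestriction.from_bounds(2, 11))
        assert clean.edges == {frozenset({1, 2})}
        assert clean.nodes == {1, 2}

    def test_fixed_point_on_clean_input(self, two_triangles, restriction):
        assert preprocess(two_triangles, restriction) == two_triangles

    def test_random_input_matches_independent_filter(self, rng, restriction):
        h = random_hypergraph(rng, max_edge_size=6)
        # plant violations
        raw = list(h.edges) + [[0], [1], list(range(15))]
        dirty = Hypergraph(raw)
        clean = preprocess(dirty, restriction)
        survivors = {
            frozenset(e) for e in raw if 2 <= len(frozenset(e)) <= restriction.max_size
        }
        assert clean.edges == survivors
        assert all(any(v in e for e in clean.edges) for v in clean.nodes)


class TestMaximalEdges:
    def test_strict_inclusion(self):
        h = build_hypergraph([[1, 2], [1, 2, 3]])
        assert maximal_edges(h) == {frozenset({1, 2, 3})}

    def test_disjoint_edges_all_maximal(self):
        h = build_hypergraph([[1, 2], [3, 4]])
        assert maximal_edges(h) == h.edges

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hypergraph(rng, max_nodes=12, max_edges=200, max_edge_size=6)
        assert maximal_edges(h) == brute_maximal(h.edges)

    def test_output_is_antichain(self, rng):
        h = random_hypergraph(rng, max_edges=100)
        tilde = maximal_edges(h)
        assert not any(a < b for a in tilde for b in tilde)

    def test_every_edge_under_some_maximal(self, rng):
        h = random_hypergraph(rng, max_edges=60)
        tilde = maximal_edges(h)
        assert all(any(e <= t for t in tilde) for e in h.edges)


class TestRestrictedPowerset:
    def test_pairs_only(self):
        out = restricted_powerset({1, 2, 3}, SizeRestriction(frozenset({2}), 11))
        assert out == {frozenset(p) for p in [(1, 2), (1, 3), (2, 3)]}

    def test_proper_subface_count_formula(self):
        # |P_{2..n-1}(e)| = 2^|e| - |e| - 2 (drops empty set, singletons, e)
        e = frozenset(range(4))
        out = restricted_powerset(e, SizeRestriction(frozenset({2, 3}), 11))
        assert len(out) == 2**4 - 4 - 2 == 10

    def test_includes_edge_itself_iff_size_allowed(self):
        e = frozenset({1, 2, 3})
        with_self = restricted_powerset(e, SizeRestriction(frozenset({2, 3}), 11))
        assert e in with_self and len(with_self) == 4
        without_self = restricted_powerset(e, SizeRestriction(frozenset({2}), 11))
        assert e not in without_self

    def test_oversized_edge_rejected(self):
        with pytest.raises(ValueError, match="preprocess"):
            restricted_powerset(frozenset(range(12)), SizeRestriction.from_bounds(2, 11))

    @given(size=st.integers(2, 9), mink=st.integers(1, 3), maxk=st.integers(4, 9))
    def test_size_matches_binomial_sum(self, size, mink, maxk):
        r = SizeRestriction(frozenset(range(mink, maxk + 1)), 11)
        e = frozenset(range(size))
        out = restricted_powerset(e, r)
        expected = sum(math.comb(size, m) for m in r.allowed_sizes if m <= size)
        assert len(out) == expected == restricted_powerset_size(size, r)
        assert out == powerset_k(e, r.allowed_sizes)


class TestMinimalFaces:
    def test_size_two_edges_flagged(self, two_triangles, restriction):
        assert minimal_faces(two_triangles, restriction) == {
            frozenset({1, 2}),
            frozenset({1, 3}),
            frozenset({2, 3}),
        }

    def test_empty_when_no_edge_attains_min(self, restriction):
        h = build_hypergraph([[1, 2, 3], [1, 2, 3, 4]])
        assert minimal_faces(h, restriction) == frozenset()

    def test_matches_size_scan(self, rng, restriction):
        h = random_hypergraph(rng)
        assert minimal_faces(h, restriction) == {e for e in h.edges if len(e) == 2}


class TestIsSimplex:
    def test_closed_triangle(self, closed_triangle, restriction):
        assert is_simplex({1, 2, 3}, closed_triangle, restriction)

    def test_open_triangle(self, open_triangle, restriction):
        assert not is_simplex({1, 2, 3}, open_triangle, restriction)

    def test_non_edge_raises(self, open_triangle, restriction):
        with pytest.raises(KeyError):
            is_simplex({1, 3}, open_triangle, restriction)

    def test_matches_exhaustive_membership_check(self, rng, restriction):
        from _oracle import brute_is_simplex

        h = random_hypergraph(rng)
        for e in h.edges:
            assert is_simplex(e, h, restriction) == brute_is_simplex(
                e, h.edges, restriction.allowed_sizes
            )

    def test_singleton_requirement_honored_when_k_includes_one(self):
        h = build_hypergraph([[1, 2], [1]])
        # singleton edges survive only if built directly (preprocess drops them)
        strict = SizeRestriction(frozenset({1, 2}), 11)
        assert not is_simplex({1, 2}, h, strict)  # {2} missing
        h2 = build_hypergraph([[1, 2], [1], [2]])
        assert is_simplex({1, 2}, h2, strict)


class TestInducedComplex:
    def test_hand_enumeration(self):
        h = build_hypergraph([[1, 2, 3], [1, 2]])
        r = SizeRestriction(frozenset({2, 3}), 11)
        c = induced_simplicial_complex(h, r)
        assert c == {
            frozenset({1, 2, 3}),
            frozenset({1, 2}),
            frozenset({1, 3}),
            frozenset({2, 3}),
        }

    def test_fixed_point_on_complex(self, closed_triangle, restriction):
        assert induced_simplicial_complex(closed_triangle, restriction) == closed_triangle.edges

    def test_two_disjoint_open_triangles(self, restriction):
        h = build_hypergraph([[1, 2, 3], [4, 5, 6]])
        assert len(induced_simplicial_complex(h, restriction)) == 8

    def test_idempotent(self, rng, restriction):
        h = random_hypergraph(rng)
        c = induced_simplicial_complex(h, restriction)
        again = induced_simplicial_complex(Hypergraph(c), restriction)
        assert again == c


class TestSizeRestriction:
    def test_default_is_2_to_11(self):
        r = SizeRestriction()
        assert r.allowed_sizes == frozenset(range(2, 12)) and r.max_size == 11

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SizeRestriction(frozenset(), 11)
        with pytest.raises(ValueError):
            SizeRestriction(frozenset({0, 2}), 11)
        with pytest.raises(ValueError):
            SizeRestriction(frozenset({2, 12}), 11)
        with pytest.raises(ValueError):
            SizeRestriction.from_bounds(3, 2)
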