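"""Nodal simpliciality and simplicial assortativity.

Two closed triangles bridged by an extra triangle give nodes at two
distinct levels of local downward closure; the assortativity asks whether
adjacent nodes sit at similar levels.
"""

from simpliciality import (
    build_hypergraph,
    nodal_simpliciality,
    simplicial_assortativity,
    as_float,
)

h = build_hypergraph(
    [[1, 2, 3], [1, 2], [1, 3], [2, 3],
     [4, 5, 6], [4, 5], [4, 6], [5, 6],
     [3, 4], [2, 3, 4]]
)

values = nodal_simpliciality(h, measure="fes")
for v in sorted(values):
    print(f"node {v}: local FES = {as_float(values[v]):.4f}")

rho = simplicial_assortativity(h, measure="fes")
print(f"simplicial assortativity (FES): {as_float(rho):+.4f}")

# Nodes inside a closed triangle whose ego-hypergraph is exactly that
# triangle score 1; nodes whose neighbourhood includes the bridge edge see
# the unclosed triangle {2,3,4} and score lower.  A positive coefficient
# means similar nodes tend to share edges.
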