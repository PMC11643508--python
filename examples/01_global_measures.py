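"""Global simpliciality of two toy hypergraphs.

An "open" triangle (a 3-edge with only one of its three pairs present)
and a pair of triangles, one fully closed and one with no pairs at all.
The three measures answer different questions: SF counts edges that are
already simplices, ES counts how much of the induced simplicial complex
is present, FES averages per-face subface completeness.
"""

from simpliciality import build_hypergraph, full_report

open_triangle = build_hypergraph([[1, 2, 3], [1, 2]])
two_triangles = build_hypergraph([[1, 2, 3], [4, 5, 6], [1, 2], [1, 3], [2, 3]])

for name, h in [("open triangle", open_triangle), ("two triangles", two_triangles)]:
    rep = full_report(h)
    print(f"{name}: |V|={h.num_nodes} |E|={h.num_edges}")
    print(f"  SF={float(rep.sf):.4f}  ES={float(rep.es):.4f}  FES={float(rep.fes):.4f}")
    print(f"  edges to add for downward closure (d_ES): {int(rep.es_distance)}")

# The open triangle is 0/1 simplices (SF=0) but already holds 2 of the 4
# faces of its closure, hence ES=1/3 after discounting the maximal edge.
# In the second hypergraph each measure splits the difference between the
# closed triangle (fully simplicial) and the bare one (no inclusions).
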