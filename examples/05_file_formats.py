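"""Reading and writing hypergraph files.

Three formats: plain hyperedge lists, bipartite node/edge-id incidence
lists, and the JSON dialect used by the public xgi-data repository.  The
same CLI workflow: `simpliciality compute <file>`.
"""

import tempfile
from pathlib import Path

from simpliciality import build_hypergraph, read_hypergraph, summarize, write_hypergraph

h = build_hypergraph([[1, 2, 3], [1, 2], [1, 3], [2, 3], [3, 4]])

with tempfile.TemporaryDirectory() as tmp:
    for fmt, suffix in [("edgelist", "txt"), ("bipartite", "tsv"), ("json", "json")]:
        path = Path(tmp) / f"toy.{suffix}"
        write_hypergraph(h, path, fmt)
        back = read_hypergraph(path, fmt)
        print(f"{fmt:9s}: {path.name} round-trips -> {back.edges == h.edges}")

row = summarize(h, name="toy")
print(
    "summary row: |V|={n_nodes} |E|={n_edges} SF={sf:.3f} ES={es:.3f} FES={fes:.3f}".format(**row)
)
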