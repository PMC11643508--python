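"""End-to-end analysis recipes for empirical hypergraph datasets.

These wrap the library into the exact workflows used for dataset
summaries:

* :func:`summarize` — preprocess (drop singletons, drop edges larger than
  the size cap, drop isolated nodes) and report basic structure plus the
  three global measures: one summary-table row per dataset.
* :func:`local_profile` — restrict to interaction sizes {2, 3}, then
  compute all three nodal simpliciality values per node (the per-node CSV
  behind local-structure maps and histograms).
* :func:`assortativity_profile` — the simplicial assortativity of the
  size-{2, 3}-filtered hypergraph under each measure.

Datasets are not bundled.  The ten public datasets analysed in the
original study (contact-primary-school, contact-high-school,
hospital-lyon, email-enron, email-eu, diseasome, disgenenet,
ndc-substances, congress-bills, tags-ask-ubuntu) live in the xgi-data
repository; fetch any of them as JSON, e.g.::

    curl -L -o email-enron.json \
        https://gitlab.com/complexgroupinteractions/xgi-data/-/raw/main/data/email-enron/email-enron.json

and load with ``read_hypergraph(path, format="json")``.
"""

from __future__ import annotations

from .core import (
    DEFAULT_RESTRICTION,
    Hypergraph,
    SizeRestriction,
    preprocess,
)
from .local import nodal_simpliciality, simplicial_assortativity
from .measures import Undefined, as_float, full_report

__all__ = ["summarize", "size_filter", "local_profile", "assortativity_profile"]

#: size filter used for nodal/assortativity analyses, where enumerating
#: subfaces of every ego-hypergraph must stay tractable
PAIRS_AND_TRIPLES = SizeRestriction.from_bounds(2, 3)


def summarize(
    h: Hypergraph,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
    name: str = "",
) -> dict:
    """One summary-table row: structure and global simpliciality.

    Preprocessing (singleton removal, size cap, isolated-node removal) is
    applied here; pass raw data.
    """
    clean = preprocess(h, restriction)
    report = full_report(clean, restriction)
    row = {
        "dataset": name,
        "n_nodes": clean.num_nodes,
        "n_edges": clean.num_edges,
        "mean_degree": clean.mean_degree(),
        "mean_edge_size": clean.mean_edge_size(),
        "sf": as_float(report.sf),
        "es": as_float(report.es),
        "fes": as_float(report.fes),
    }
    row["counts"] = report.counts
    return row


def size_filter(h: Hypergraph, sizes=(2, 3)) -> Hypergraph:
    """Keep only edges whose size is in ``sizes``; drop isolated nodes.

    Applied *before* nodal analyses so that ego-hypergraph subface
    enumeration stays tractable on large datasets.
    """
    allowed = set(sizes)
    return Hypergraph(e for e in h.edges if len(e) in allowed)


def local_profile(
    h: Hypergraph,
    restriction: SizeRestriction = PAIRS_AND_TRIPLES,
) -> "pandas.DataFrame":
    """Per-node nodal simpliciality under all three measures.

    Input is size-filtered to the restriction's bounds first.  Returns a
    DataFrame with columns node, sf, es, fes, and per-measure
    undefined-reason columns (empty string when defined).
    """
    import pandas as pd

    from .core import sort_key

    sizes = [s for s in restriction.allowed_sizes]
    filtered = size_filter(h, sizes)
    per_measure = {
        m: nodal_simpliciality(filtered, m, restriction) for m in ("sf", "es", "fes")
    }
    rows = []
    for v in sorted(filtered.nodes, key=sort_key):
        row = {"node": v}
        for m in ("sf", "es", "fes"):
            val = per_measure[m][v]
            if isinstance(val, Undefined):
                row[m] = float("nan")
                row[f"{m}_undefined"] = val.reason
            else:
                row[m] = float(val)
                row[f"{m}_undefined"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def assortativity_profile(
    h: Hypergraph,
    restriction: SizeRestriction = PAIRS_AND_TRIPLES,
) -> dict:
    """Simplicial assortativity (ρ_SF, ρ_ES, ρ_FES) of the size-filtered
    hypergraph; NaN-valued entries carry their undefined reason."""
    sizes = [s for s in restriction.allowed_sizes]
    filtered = size_filter(h, sizes)
    out = {}
    for m in ("sf", "es", "fes"):
        rho = simplicial_assortativity(filtered, m, restriction)
        if isinstance(rho, Undefined):
            out[f"rho_{m}"] = float("nan")
            out[f"rho_{m}_undefined"] = rho.reason
        else:
            out[f"rho_{m}"] = rho
            out[f"rho_{m}_undefined"] = ""
    return out
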