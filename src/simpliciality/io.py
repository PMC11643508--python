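"""Readers and writers for the three hypergraph exchange formats.

* **edgelist** — one hyperedge per line, node labels separated by
  whitespace or commas; blank lines and ``#`` comments ignored.
* **bipartite** — two columns ``node-label  edge-id``; hyperedges are
  assembled by grouping rows on the edge id.
* **json** — the JSON dialect used by the public xgi-data repository
  (an ``edge-dict`` mapping edge id → member list, with optional
  ``node-data``); a flat ``{"nodes": [...], "edges": {...}}`` layout is
  also accepted.

Node labels are parsed as integers when every label in the file looks
like one, else kept as strings (the public JSON datasets store ids as
strings; the coercion makes the formats interchangeable).  Writers emit
nodes and edges in sorted order so output is deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .core import Hypergraph, sort_key

logger = logging.getLogger(__name__)

__all__ = ["read_hypergraph", "write_hypergraph", "FORMATS"]

FORMATS = ("edgelist", "bipartite", "json")


class HypergraphParseError(ValueError):
    """Malformed input file; carries the offending line number."""


def _coerce_labels(edges: list) -> list:
    """Convert all labels to int iff every label is integer-like."""
    flat = [v for e in edges for v in e]
    try:
        if all(isinstance(v, str) for v in flat):
            as_int = {v: int(v) for v in set(flat)}
            return [[as_int[v] for v in e] for e in edges]
    except ValueError:
        pass
    return edges


def _tokenize(line: str) -> list:
    return line.replace(",", " ").split()


def _read_edgelist(path: Path) -> list:
    edges = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            n_lines += 1
            edges.append(_tokenize(line))
    logger.info("read %d edge lines from %s", n_lines, path)
    return _coerce_labels(edges)


def _read_bipartite(path: Path) -> list:
    groups: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = _tokenize(line)
            if len(tokens) != 2:
                raise HypergraphParseError(
                    f"{path}:{lineno}: expected 'node edge-id', got {raw.strip()!r}"
                )
            node, edge_id = tokens
            groups.setdefault(edge_id, []).append(node)
    logger.info("assembled %d edges from incidence list %s", len(groups), path)
    return _coerce_labels(list(groups.values()))


def _read_json(path: Path) -> list:
    with open(path) as fh:
        data = json.load(fh)
    if "edge-dict" in data:  # xgi-data layout
        edge_map = data["edge-dict"]
    elif "edges" in data and isinstance(data["edges"], dict):
        edge_map = data["edges"]
    elif "edges" in data and isinstance(data["edges"], list):
        edge_map = dict(enumerate(data["edges"]))
    else:
        raise HypergraphParseError(
            f"{path}: no 'edge-dict' or 'edges' object found"
        )
    edges = [[str(v) for v in members] for members in edge_map.values()]
    return _coerce_labels(edges)


def read_hypergraph(path, format: str = "edgelist") -> Hypergraph:
    """Read a hypergraph file into a canonical simple :class:`Hypergraph`.

    ``format`` is one of 'edgelist', 'bipartite' or 'json'.  Duplicate
    edges collapse; the number collapsed is logged.
    """
    path = Path(path)
    if format == "edgelist":
        edges = _read_edgelist(path)
    elif format == "bipartite":
        edges = _read_bipartite(path)
    elif format == "json":
        edges = _read_json(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    h = Hypergraph(edges)
    collapsed = len(edges) - h.num_edges
    if collapsed:
        logger.info("collapsed %d duplicate/empty edges", collapsed)
    return h


def write_hypergraph(h: Hypergraph, path, format: str = "edgelist") -> None:
    """Write a hypergraph deterministically (sorted nodes within edges,
    sorted edge order) in any of the supported formats."""
    path = Path(path)
    edges = h.sorted_edges()
    if format == "edgelist":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(" ".join(str(v) for v in e) + "\n")
    elif format == "bipartite":
        with open(path, "w") as fh:
            for j, e in enumerate(edges):
                for v in e:
                    fh.write(f"{v} {j}\n")
    elif format == "json":
        payload = {
            "hypergraph-data": {},
            "node-data": {str(v): {} for v in sorted(h.nodes, key=sort_key)},
            "edge-dict": {str(j): [str(v) for v in e] for j, e in enumerate(edges)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
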