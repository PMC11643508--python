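"""Randomised baselines for simpliciality: what would the measures be if
only the degree and edge-size sequences were specified?

Two samplers are provided:

* :func:`configuration_model_sample` — a micro-canonical configuration
  model.  The hypergraph is viewed as a bipartite node-edge graph and
  randomised by *double edge swaps*: two (node, edge) incidences are picked
  uniformly at random and their node endpoints exchanged.  Swaps that would
  place a node twice in one edge or create a duplicate edge are rejected
  (and retried), so every sample preserves the empirical degree sequence
  and edge-size sequence exactly while remaining a simple hypergraph.
* :func:`chung_lu_sample` — a canonical (soft) bipartite Chung-Lu model:
  node ``i`` joins an edge of size ``s`` independently with probability
  ``min(1, k_i · s / Σ_j k_j)``, so degrees and sizes are matched in
  expectation only.  Sampling uses the weight-sorted geometric-skipping
  construction, O(edges + incidences) in expectation.

:func:`ensemble_simpliciality` wraps either sampler (or externally
generated sample files, e.g. from a bipartite stochastic-block-model
sampler) into an ensemble of per-sample simpliciality reports with
summary statistics — the numeric content of a null-model comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    DEFAULT_RESTRICTION,
    Hypergraph,
    SizeRestriction,
    preprocess,
    sort_key,
)
from .measures import SimplicialityReport, as_float, full_report, is_defined

__all__ = [
    "DegreeSizeSequences",
    "extract_sequences",
    "configuration_model_sample",
    "chung_lu_sample",
    "NullModelEnsemble",
    "ensemble_simpliciality",
]


@dataclass(frozen=True)
class DegreeSizeSequences:
    """Empirical node degrees and edge sizes (the bipartite degree data)."""

    degrees: dict
    sizes: tuple

    def __post_init__(self):
        if sum(self.degrees.values()) != sum(self.sizes):
            raise ValueError(
                "inconsistent sequences: sum of degrees must equal sum of sizes "
                "(bipartite handshake)"
            )

    @property
    def total_incidences(self) -> int:
        return sum(self.sizes)


def extract_sequences(h: Hypergraph) -> DegreeSizeSequences:
    """The degree and edge-size sequences of a hypergraph."""
    return DegreeSizeSequences(h.degrees(), tuple(h.edge_sizes()))


def configuration_model_sample(
    h: Hypergraph,
    n_swaps: int | None = None,
    seed: int | None = None,
    max_attempt_factor: int = 10,
) -> Hypergraph:
    """One configuration-model draw via bipartite double edge swaps.

    Performs ``n_swaps`` *accepted* swaps (default ``10 · |E|``); rejected
    proposals (same edge twice, repeated node, duplicate edge) are retried
    up to ``max_attempt_factor × n_swaps`` total attempts.  Degree and
    edge-size sequences are preserved exactly.  Deterministic given
    ``seed``.
    """
    if h.num_edges < 2:
        warnings.warn(
            "configuration model needs at least 2 edges; returning an identical copy",
            stacklevel=2,
        )
        return Hypergraph(h.edges, extra_nodes=h.nodes)
    rng = np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = 10 * h.num_edges

    edges = [set(e) for e in h.sorted_edges()]
    edge_keys = [frozenset(e) for e in edges]
    occupied = set(edge_keys)  # current edge sets, for duplicate detection
    # flat incidence list: (edge index, node); swaps mutate node in place
    incidences = [(j, v) for j, e in enumerate(edges) for v in sorted(e, key=sort_key)]
    m = len(incidences)

    accepted = 0
    attempts = 0
    max_attempts = max(1, max_attempt_factor * n_swaps)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i1, i2 = rng.integers(0, m, size=2)
        j1, v1 = incidences[i1]
        j2, v2 = incidences[i2]
        if j1 == j2 or v1 == v2:
            continue
        e1, e2 = edges[j1], edges[j2]
        if v2 in e1 or v1 in e2:
            continue  # would repeat a node within an edge
        new1 = frozenset(e1 - {v1} | {v2})
        new2 = frozenset(e2 - {v2} | {v1})
        remaining = occupied - {edge_keys[j1], edge_keys[j2]}
        if new1 in remaining or new2 in remaining or new1 == new2:
            continue  # would create a multi-hyperedge
        e1.discard(v1)
        e1.add(v2)
        e2.discard(v2)
        e2.add(v1)
        occupied.discard(edge_keys[j1])
        occupied.discard(edge_keys[j2])
        occupied.update((new1, new2))
        edge_keys[j1], edge_keys[j2] = new1, new2
        incidences[i1] = (j1, v2)
        incidences[i2] = (j2, v1)
        accepted += 1
    if accepted < n_swaps:
        warnings.warn(
            f"only {accepted}/{n_swaps} swaps accepted within "
            f"{max_attempts} attempts; the chain may be constrained",
            stacklevel=2,
        )
    return Hypergraph(edges, extra_nodes=h.nodes)


def _chung_lu_edge(nodes, weights, s, total_weight, rng):
    """Members of one size-s edge under the sorted skipping construction.

    ``weights`` must be sorted in decreasing order.  Node ``i`` is included
    with probability min(1, w_i·s/W); the geometric skip jumps over runs of
    rejections at the current probability bound, and each visited node is
    accepted with the ratio of its true probability to the bound.
    """
    members = []
    n = len(nodes)
    i = 0
    p = min(1.0, weights[0] * s / total_weight) if n else 0.0
    while i < n and p > 0:
        if p < 1.0:
            r = 1.0 - rng.random()  # uniform on (0, 1]; keeps log(r) finite
            i += int(math.floor(math.log(r) / math.log(1.0 - p)))
        if i < n:
            q = min(1.0, weights[i] * s / total_weight)
            if rng.random() < q / p:
                members.append(nodes[i])
            p = q
            i += 1
    return members


def chung_lu_sample(
    sequences: DegreeSizeSequences,
    seed: int | None = None,
) -> Hypergraph:
    """One bipartite Chung-Lu draw matching the sequences in expectation.

    Duplicate edges produced by the independent draws are collapsed (the
    measures are defined on simple hypergraphs), slightly deflating the
    edge count; nodes that end up in no edge remain in the node set.
    """
    rng = np.random.default_rng(seed)
    order = sorted(sequences.degrees, key=sort_key)
    order.sort(key=lambda v: sequences.degrees[v], reverse=True)
    weights = [float(sequences.degrees[v]) for v in order]
    total = float(sum(weights))
    raw = []
    if total > 0:
        for s in sequences.sizes:
            raw.append(_chung_lu_edge(order, weights, s, total, rng))
    return Hypergraph((e for e in raw if e), extra_nodes=sequences.degrees)


@dataclass
class NullModelEnsemble:
    """Per-sample simpliciality of a fitted null model.

    ``reports`` holds one :class:`SimplicialityReport` per draw (after the
    same preprocessing applied to the empirical data); ``samples`` is kept
    only when requested.  ``n_undefined`` counts, per measure, the samples
    whose value was undefined and hence excluded from summaries.
    """

    model: str
    seed: int | None
    reports: list = field(default_factory=list)
    samples: list | None = None

    def values(self, measure: str) -> np.ndarray:
        """Defined per-sample values of one measure, as floats."""
        vals = [getattr(r, measure) for r in self.reports]
        return np.array([float(v) for v in vals if is_defined(v)])

    def n_undefined(self, measure: str) -> int:
        return sum(1 for r in self.reports if not is_defined(getattr(r, measure)))

    def summary(self) -> dict:
        """Mean/sd/quantiles per measure over the defined samples."""
        out = {}
        for measure in ("sf", "es", "fes"):
            vals = self.values(measure)
            entry = {"n_samples": len(self.reports), "n_undefined": self.n_undefined(measure)}
            if len(vals):
                qs = np.quantile(vals, [0.025, 0.25, 0.5, 0.75, 0.975])
                entry.update(
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    q025=float(qs[0]),
                    q25=float(qs[1]),
                    median=float(qs[2]),
                    q75=float(qs[3]),
                    q975=float(qs[4]),
                )
            out[measure] = entry
        return out

    def to_frame(self):
        """Per-sample measure values as a pandas DataFrame."""
        import pandas as pd

        rows = [
            {
                "sample": i,
                "sf": as_float(r.sf),
                "es": as_float(r.es),
                "fes": as_float(r.fes),
            }
            for i, r in enumerate(self.reports)
        ]
        return pd.DataFrame(rows)


def ensemble_simpliciality(
    h: Hypergraph,
    model: str = "configuration",
    n_samples: int = 1000,
    restriction: SizeRestriction = DEFAULT_RESTRICTION,
    seed: int | None = None,
    n_swaps: int | None = None,
    external_samples: Sequence[Hypergraph] | None = None,
    keep_samples: bool = False,
    progress: Callable[[int], None] | None = None,
) -> NullModelEnsemble:
    """Fit a null model to ``h`` and score ``n_samples`` draws.

    ``model`` is 'configuration' (exact degree/size sequences via double
    edge swaps), 'chung_lu' (sequences in expectation) or 'external'
    (pre-generated hypergraphs supplied through ``external_samples``, the
    hook for samplers not implemented here, e.g. a bipartite SBM).  Each
    draw is preprocessed identically to the empirical data before scoring.
    One master seed spawns independent per-sample seeds, so ensembles are
    reproducible and order-independent.
    """
    sequences = extract_sequences(h)
    ens = NullModelEnsemble(model=model, seed=seed, samples=[] if keep_samples else None)
    if model == "external":
        if external_samples is None:
            raise ValueError("model='external' requires external_samples")
        draws = list(external_samples)
    else:
        if model not in ("configuration", "chung_lu"):
            raise ValueError(f"unknown model {model!r}")
        master = np.random.default_rng(seed)
        sample_seeds = master.integers(0, 2**31 - 1, size=n_samples)
        draws = None

    if draws is not None:
        iterator = enumerate(draws)
    else:
        iterator = enumerate(sample_seeds)

    for i, item in iterator:
        if draws is not None:
            sample = item
        elif model == "configuration":
            sample = configuration_model_sample(h, n_swaps=n_swaps, seed=int(item))
        else:
            sample = chung_lu_sample(sequences, seed=int(item))
        sample = preprocess(sample, restriction)
        ens.reports.append(full_report(sample, restriction))
        if keep_samples:
            ens.samples.append(sample)
        if progress is not None:
            progress(i)
    return ens
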