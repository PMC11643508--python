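# Methods

## Setting and definitions

A hypergraph `H = (V, E)` is *simple*: `E` is a set of node subsets
(no repeated edges, no repeated node within an edge). An edge `f` is a
*subface* of `e` when `f ⊂ e`. A *maximal edge* `ẽ` is not included in any
other edge; the set of maximal edges is `Ẽ`. A hypergraph satisfies
*downward closure* — i.e. is a simplicial complex — when every subface of
every edge is itself an edge. The *induced simplicial complex* `C` is the
smallest downward-closed edge set containing `Ẽ`.

Strict downward closure is an unreasonable yardstick for most data:
proximity and email datasets cannot contain singleton interactions by
construction, yet the strict definition would declare them maximally
non-simplicial for that reason alone. All measures therefore use a
*size-restricted power set* `P_K(e) = {x ⊆ e : |x| ∈ K}` and demand
closure only for subface sizes in `K`.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` (`SizeRestriction.allowed_sizes`) | `{2, …, 11}` | subface sizes that count toward closure; drop 0 and 1 because singletons/empty faces are absent by construction in most data. Include 1 for domains (co-authorship) where singleton interactions are meaningful. |
| `max_size` | 11 | edges larger than this are removed during preprocessing (dropped, never truncated); the closure of an edge has `2^{|e|}` faces, so a cap is what keeps the measures computable. |
| `q` (planted generator) | 0.5 | probability each allowed subface of a drawn maximal edge is present; sweeps the output from no inclusions (0) to a simplicial complex (1). |
| `n_swaps` (configuration model) | `10·|E|` | accepted double edge swaps per sample; roughly the standard mixing heuristic for bipartite swap chains. |
| `n_samples` (ensembles) | 1000 | null-model draws per dataset. |

Preprocessing applies, in order: drop singleton edges, drop edges above
`max_size`, drop nodes left without an incident edge. The order matters
only for the reported node count; the cap is applied before isolated-node
removal so that a node incident only to an oversized edge is removed.

## The measures and the minimal-face rule

With `min(K)` the smallest allowed size, *minimal faces* (edges of size
`min(K)`) are simplices by definition — there is nothing below them to
include — so counting them as achieved simplices would inflate every
measure. They are excluded from candidacy as follows:

- **SF**: both the candidate set and the simplex count range over edges of
  size strictly above `min(K)`. `σ_SF = |S'|/|E'|`.
- **ES**: `Ẽ'` keeps only maximal edges above the minimal size; `C'` is the
  union of their restricted power sets; the edge count `E'` keeps only
  edges (of allowed size) included in some member of `Ẽ'`. The statistic
  is `(|E'| − |Ẽ'|)/(|C'| − |Ẽ'|)`. Removing the excluded faces from the
  numerator *and* the denominator is what keeps the ratio within [0, 1];
  keeping them in `|E|` while dropping them from `C` can push it above 1.
  Restricting `E'` to edges of allowed size guarantees `E' ⊆ C'` for any
  user-supplied `K`, not only the contiguous default.
- **FES**: the average runs over `F = Ẽ'`. (The library also accepts
  `F = E` programmatically via `face_edit_distance`; the shipped analyses
  use maximal faces only.)

A non-maximal minimal face (a pair inside a triangle) *does* count toward
`E'` in the ES numerator and toward the present-subface count in FES: it
is a genuine inclusion, only its candidacy as a simplex is discounted.

Degenerate denominators — the empty hypergraph, a hypergraph whose edges
are all minimal faces — yield an `Undefined` value carrying a reason code
(`empty-hypergraph`, `no-candidate-edges`, `degenerate-denominator`,
`isolated-node`, `zero-variance`). Downstream consumers (nodal maps,
assortativity) drop undefined values explicitly rather than imputing;
a silent 0 or 1 would bias the assortativity coefficient.

All three global measures are computed as exact `fractions.Fraction`
ratios and converted to float only in reports. This makes the test-suite
comparison against a brute-force subset-enumeration oracle an *equality*
check, not a tolerance check.

Known edge of the design: adding a subface always increases ES strictly
and never decreases FES (both are enforced as properties), but SF is not
monotone under subface addition — adding a non-simplex subface can
enlarge the candidate set and lower the fraction. This is inherent to
SF's definition and is documented rather than asserted.

## Local measures

The neighbourhood of `v` is `n(v) = {u : u, v ∈ e for some e ∈ E}`; the
ego-hypergraph is induced on `V̂ = {v} ∪ n(v)` and contains every edge of
`E` inside `V̂`, including edges not touching `v`. Nodal simpliciality is
a global measure applied to the ego-hypergraph. Local ES is systematically
high relative to global ES because ego-hypergraphs have smaller maximal
edges, hence exponentially smaller induced complexes in the denominator;
local SF and FES can be very low when the ego-hypergraph omits a shared
subface. These are properties of the statistics, not bugs.

Simplicial assortativity is implemented as the Pearson correlation of
nodal values over *ordered* pairs of adjacent nodes (adjacent = sharing at
least one edge, the unweighted pairwise projection `A = sign(BBᵀ)` with
zero diagonal). Using both orientations of each pair makes the statistic
the standard attribute-assortativity coefficient on the projection; it is
invariant under node relabelling and under affine transformation of the
nodal values. Pairs with an undefined endpoint are dropped; fewer than two
usable pairs, or zero variance of endpoint values, give NA.

For nodal and assortativity analyses of large datasets the hypergraph is
first filtered to interaction sizes {2, 3} (before isolated-node removal,
then measured with `K = {2, 3}`): ego-hypergraphs of hub nodes otherwise
contain large maximal edges whose closures are too big to enumerate per
node.

## Null models

The **configuration model** preserves the node-degree and edge-size
sequences exactly. The bipartite incidence structure is randomised by
double edge swaps: two (node, edge) incidences chosen uniformly exchange
node endpoints. A proposal is rejected (and retried) when both incidences
are in the same edge, when the exchange would repeat a node within an
edge, or when it would duplicate an existing edge — so every sample
remains simple. "Number of swaps" counts *accepted* swaps (default
`10·|E|`), with a safety cap of 10× that many attempts; accepted-swap
counting matches the mixing-time intent of the usual heuristic better
than counting proposals. A warning reports chains that hit the attempt
cap (tiny or highly constrained hypergraphs).

The **bipartite Chung-Lu model** matches both sequences in expectation:
node `i` joins an edge of size `s` independently with probability
`min(1, k_i·s/Σ_j k_j)`. Sampling uses the weight-sorted geometric-skip
construction, expected `O(|E| + incidences)` per draw. Duplicate edges
produced by the independent draws are collapsed (the measures are defined
on simple hypergraphs), slightly deflating the edge count; empty edges
are dropped.

The ensemble harness preprocesses each sample identically to the
empirical data before scoring, so empirical and null values are
comparable. A bipartite stochastic-block-model sampler is deliberately
not reimplemented — the harness ingests externally generated samples
(`model="external"`) in any supported format. One master seed spawns
per-sample seeds, making ensembles reproducible and order-independent.

## Synthetic data: the planted-inclusion generator

The generator draws `n_maximal_edges` node sets (sizes from a given
distribution, members uniform without replacement from `n_nodes` nodes)
and adds each allowed subface of each drawn edge independently with
probability `q`. Defaults (40–50 nodes, 10–20 planted edges, sizes 3–5)
give sparse hypergraphs in which drawn edges rarely include one another,
so `q` cleanly controls the inclusion structure: all measures are 0 at
`q = 0` (given non-including drawn edges) and 1 at `q = 1`, with FES
rising almost linearly in between and SF lagging (an edge only counts
once *all* its subfaces are present).

What the generator does *not* emulate: degree heterogeneity and hub
structure, correlated/overlapping maximal edges, the heavy-tailed edge
size distributions of empirical data, or any community structure.
Passing tests on this generator therefore demonstrate the correctness and
calibration of the measures — not that any particular empirical system is
well described by the model.

## Numerical and procedural choices

- Edge membership is O(1) (frozensets in a hash set); maximal-edge
  detection tests each edge only against larger edges incident to its
  lowest-degree member, with the all-pairs scan retained as a test oracle.
- `is_simplex` requires subfaces of every allowed size up to `|e|`; with a
  `K` containing 1, singleton subfaces are genuinely required.
- Writers emit nodes and edges in sorted order; sampler draws iterate
  over sorted structures, so all outputs are byte-stable for a fixed seed.
- Monte-Carlo problem sizes in the shipped tests and the acceptance
  script (500 oracle hypergraphs of ≤ 12 nodes / ≤ 40 edges; 10³ Chung-Lu
  draws on 20 nodes; 200 planted draws per `q`; 200-sample ensembles) were
  chosen to give stable statistics at interactive runtimes.
- The replication recipes for the ten public datasets (summary table,
  sizes-{2,3} assortativity table, the email-enron local profile) are
  implemented in `simpliciality.recipes`; the corresponding test asserts
  the published values whenever the JSON files are present under
  `data/xgi/` and fails with a pointer to the fetch recipe otherwise —
  the datasets are too large to bundle.

## Limitations

- Weighted or multi-hypergraphs, temporal aggregation, and mesoscale
  (community-level) simpliciality are out of scope.
- ES on datasets with many large maximal edges is dominated by the
  exponential closure sizes; that sensitivity is a property of the
  measure itself, and FES is the recommended alternative in that regime.
- The configuration-model swap chain is a heuristic sampler: `10·|E|`
  accepted swaps is a mixing rule of thumb, not a guarantee of uniformity
  over the sequence-preserving ensemble.
- Nodal measures on nodes with very large neighbourhoods require the
  size-{2,3} filter; unfiltered local analysis of hub-heavy datasets is
  not tractable.
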