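"""Is the inclusion structure of a dataset more than its degrees imply?

Generate a hypergraph with planted inclusions (80% of subfaces present),
then compare its simpliciality against two null models fitted to it: the
configuration model (exact degree/size sequences, randomised by double
edge swaps) and the bipartite Chung-Lu model (sequences in expectation).
"""

from simpliciality import (
    PlantedInclusionSpec,
    ensemble_simpliciality,
    full_report,
    generate_planted_inclusion,
    preprocess,
)

spec = PlantedInclusionSpec(
    n_nodes=40, n_maximal_edges=12,
    size_distribution={3: 0.5, 4: 0.5},
    inclusion_probability=0.8, seed=5,
)
h = preprocess(generate_planted_inclusion(spec))
emp = full_report(h)
print(f"empirical: SF={float(emp.sf):.3f} ES={float(emp.es):.3f} FES={float(emp.fes):.3f}")

for model in ("configuration", "chung_lu"):
    ens = ensemble_simpliciality(h, model, n_samples=200, seed=7)
    s = ens.summary()
    print(f"{model:13s}: " + "  ".join(
        f"{m.upper()}={s[m]['mean']:.3f}±{s[m]['sd']:.3f}" for m in ("sf", "es", "fes")
    ))

# Both nulls destroy most of the planted inclusions: the empirical values
# sit far above the ensemble means, which is the signature of genuine
# inclusion structure not explained by degrees and edge sizes alone.
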