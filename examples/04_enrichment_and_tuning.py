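"""Gene-set enrichment of modules and the (W, beta) selection grid.

Module nodes are orthogroups; for enrichment each module expands to the
union of its member genes over both species.  The grid scores each
(W, beta_Z) combination by the percentage of modules with uniquely
enriched sets, the percentage of differentially expressed module nodes,
and the module count.
"""

import tempfile
from pathlib import Path

import crossmod as cm
import crossmod.io as cio

workdir = Path(tempfile.mkdtemp(prefix="crossmod_example_"))
network, truth = cm.generate_fixture(
    150,
    (cm.PlantedModuleSpec(8, "conserved", 3.0), cm.PlantedModuleSpec(8, "species_a", 3.0)),
    rng_seed=5,
)
paths = cm.write_fixture(network, truth, workdir)
orthology = cio.read_orthology(paths["orthology"])
collection = cio.read_gene_sets(paths["gene_sets"]).casefolded()

bg = cm.BackgroundStats.from_network(network, rng_seed=5)
modules = cm.run_search(network, bg, cm.SearchConfig(n_seeds=12))
universe = len(orthology)

print("per-module enrichment (Bonferroni-corrected):")
results = []
for m in modules:
    res = cm.enrich_module(cm.module_genes(m, orthology), collection, universe,
                           module_id=m.id)
    results.extend(res)
    for r in res:
        if r.significant:
            print(f"  {m.id}: {r.set_name}  overlap={r.overlap}  "
                  f"p={r.pvalue:.2e}  corrected={r.corrected_p:.2e}")

unique = cm.unique_enrichment(results)
print("uniquely enriched sets per module:", unique)

points, (best_w, best_beta) = cm.parameter_grid(
    network, bg, [0.0, 0.5, 1.0], [1.0], collection, orthology,
    search_config=cm.SearchConfig(n_seeds=12),
)
print(f"\n{'W':>4s} {'beta':>5s} {'%uniq-enriched':>14s} {'%DE-nodes':>9s} {'#mod':>5s}")
for p in points:
    print(f"{p.w:4.1f} {p.beta:5.1f} {p.pct_unique_enriched:14.1f} "
          f"{p.pct_de_nodes:9.1f} {p.n_modules:5d}")
print(f"recommended: W={best_w}, beta={best_beta} "
      "(rank-sum of the first two criteria, ties toward fewer modules)")
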