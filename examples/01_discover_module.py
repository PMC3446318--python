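"""Discover a susceptibility module in a simulated disease study.

Builds a synthetic interaction network with a planted dense module,
simulates case/control expression with the differential signal
concentrated in that module, and walks the discovery chain: maximal
cliques -> Fisher enrichment -> module assembly -> ASPL -> core.
"""

from susmod import (
    SyntheticScenario,
    build_susceptibility_module,
    compute_average_shortest_path_lengths,
    enrich_cliques,
    enumerate_maximal_cliques,
    extract_core_module,
    simulate_expression,
    simulate_ppi_network,
)
from susmod.expression import de_gene_set, test_differential_expression

scn = SyntheticScenario(seed=42)
net, truth = simulate_ppi_network(scn)
expr = simulate_expression(truth, scn)

cliques = enumerate_maximal_cliques(net)
de = test_differential_expression(expr, use_adjusted=True)
universe = net.nodes & set(expr.genes)
de_genes = de_gene_set(de) & universe

records = enrich_cliques(
    [c for c in cliques if set(c) <= universe], de_genes, universe
)
module = build_susceptibility_module(records, net, "demo disease")
aspl = compute_average_shortest_path_lengths(module)
core = extract_core_module(module, aspl, fraction=0.2)

print(f"universe: {len(universe)} genes, {len(cliques)} maximal cliques")
print(f"DE genes (BH < 0.05): {len(de_genes)}")
print(f"enriched cliques: {sum(r.enriched for r in records)}")
print(f"susceptibility module: {len(module.genes)} genes "
      f"({module.n_de_in_module} DE + clique neighbours)")
print(f"core module (20% lowest ASPL): {sorted(core.genes)}")
overlap = len(core.genes & truth.core_genes)
print(f"-> {overlap}/{core.size} core genes belong to the planted dense "
      "module: the ASPL ranking concentrates on the planted structure.")
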