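"""Characterize the co-expression network of candidate genes.

Builds the induced co-expression graph on a candidate gene set, extracts
the largest connected component, fits a power-law degree distribution by
log-log regression, expands protein modules by first-degree interaction
neighbors, and scores term over-representation with Fisher + BH.
"""

from methylscape.network import (build_network, expand_modules,
                                 fisher_enrichment, fit_power_law,
                                 largest_component)
from methylscape.synthetic import (simulate_coexpression_edges,
                                   simulate_ppi_edges)

genes = [f"gene_{i:04d}" for i in range(200)]
edges = simulate_coexpression_edges(genes, seed=1, gamma=1.6)
graph, unconnected = build_network(genes, edges)
component = largest_component(graph)
print(f"co-expression network: {component.number_of_nodes()} connected "
      f"genes, {len(unconnected)} unconnected")

fit = fit_power_law([d for _, d in component.degree()])
print(f"power-law fit: gamma = {fit.gamma:.2f}, r^2 = {fit.r_squared:.3f}")

ppi, modules = simulate_ppi_edges(genes, seed=1)
expanded = expand_modules(modules, ppi)
for mod in expanded[:2]:
    print(f"module seed {mod['seed']} gained {len(mod['added'])} "
          f"first-degree neighbors")

term_sets = {"even": [g for g in genes if int(g[-1]) % 2 == 0],
             "first50": genes[:50]}
res = fisher_enrichment(genes[:40], term_sets, genes)
for r in res:
    print(f"term {r.term_id}: overlap {r.overlap}/{r.term_size}, "
          f"p = {r.p_value:.2e}, BH-adjusted = {r.adjusted_p:.2e}")
# A negative gamma near -1.6 with high r^2 indicates the scale-free
# topology expected of a co-regulated transcriptional network.
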