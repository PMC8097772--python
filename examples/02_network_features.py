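"""Building the bipartite HLA-peptide network and its centrality features.

Every allele and peptide is a node, every measured pair an edge weighted by
the transformed affinity.  Four centrality metrics (degree, closeness,
betweenness, eigenvector) are computed per node, z-scored within node class,
and concatenated into the 8-feature vector of a pair.
"""

from netbim import (
    SimConfig,
    build_network,
    compute_centralities,
    features_for_pair,
    scale_metrics,
    simulate_binding_dataset,
)

ds, _ = simulate_binding_dataset(SimConfig(n_alleles=10, peptides_per_allele=12, seed=1))
net = build_network(ds)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

table = scale_metrics(compute_centralities(net))
print("\nfirst rows of the centrality table:")
print(table.df.head(4).round(3).to_string())

allele, peptide = ds.df["allele"].iloc[0], ds.df["peptide"].iloc[0]
vec = features_for_pair(allele, peptide, table)
print(f"\n8-feature vector for ({allele}, {peptide}):")
print("  ", [round(float(v), 3) for v in vec])
print("First four entries describe the allele's position in the network,")
print("last four the peptide's; both are z-scores within their node class.")
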