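"""Gene-neighbourhood clustering and cross-species conservation.

Builds two synthetic genomes sharing a planted WD40 gene cluster, recovers
same-strand neighbourhoods (< 300 bp intergenic gaps), links the genomes by
bidirectional best hits, and reports the conserved neighbourhood.
"""

from repeatscope import (
    bbh_pairs,
    cluster_genes,
    match_conserved_clusters,
    simulate_genome_pair,
    term_frequencies,
)

gp = simulate_genome_pair(cluster_size=3, intra_gap=50, n_decoys=4, shared=True, seed=5)
clusters_a = cluster_genes(gp.genes_a)
clusters_b = cluster_genes(gp.genes_b)
pairs = bbh_pairs(gp.proteins_a, gp.proteins_b)
matched, specific_a, specific_b = match_conserved_clusters(
    clusters_a, clusters_b, pairs, gp.wd40_ids
)

print(f"genome A: {len(gp.genes_a)} genes -> {len(clusters_a)} neighbourhoods")
print(f"genome B: {len(gp.genes_b)} genes -> {len(clusters_b)} neighbourhoods")
print(f"BBH ortholog pairs: {len(pairs)}")
for ca, cb in matched:
    print(f"conserved WD40 neighbourhood: {ca.cluster_id} <-> {cb.cluster_id} "
          f"({len(ca)} vs {len(cb)} genes)")
print(f"lineage-specific WD40 neighbourhoods: {len(specific_a) + len(specific_b)}")
print("# a conserved neighbourhood needs a WD40 BBH pair plus BBH partners "
      "for every other member of the smaller cluster")

terms = term_frequencies(clusters_a + clusters_b)
print(f"top annotation phrase: {terms.iloc[0]['phrase']!r} "
      f"(count {terms.iloc[0]['count']})" if not terms.empty else "no phrases")
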