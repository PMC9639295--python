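"""Generate a synthetic paired-condition cohort and inspect its planted truth.

Builds a small panel of inbred lines with genotypes in LD blocks, paired
control/heat expression counts carrying planted cis, interaction (reQTL),
heat-only and trans-hotspot effects, plus TF-footprint intervals. Prints the
class composition of the truth table — the reference every later stage is
scored against.
"""

from reqtlkit import SimConfig, generate_expression, generate_footprints, \
    generate_gene_models, generate_genotypes

cfg = SimConfig(n_samples=80, n_variants=1500, n_genes=300, seed=1)
G = generate_genotypes(cfg)
genes = generate_gene_models(cfg)
pair, truth = generate_expression(G, genes, cfg)
footprints = generate_footprints(truth, genes, G, cfg)

print(f"{G.n_samples} lines x {G.n_variants} variants "
      f"({G.variants['is_indel'].mean():.0%} InDels)")
print(f"{len(genes)} genes, {len(footprints)} footprints "
      f"({(footprints['status'] == 'heat_enriched').sum()} heat-enriched)")
print("\nplanted gene classes:")
print(truth["class"].value_counts().to_string())
# 'null' genes have no planted effect; reqtl_* classes carry a genotype x
# condition interaction of at least 1 log2 unit per alt dose.
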