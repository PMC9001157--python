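"""Baseline K2P distance profiles and the all-genes UPGMA dendrogram.

Measures the K2P distance from one baseline sample to every other sample,
per gene and pooled over all shared genes, then clusters the all-genes
distance matrix into a dendrogram.
"""

from plastref.distances import GenePairCache, all_genes_matrix, baseline_profile, upgma_dendrogram
from plastref.simulate import SimConfig, apply_dropout, simulate_sequences

panel = ("matK", "rbcL", "ndhC")
cfg = SimConfig(
    seed=21,
    n_classes=1,
    orders_per_class=1,
    families_per_order=2,
    genera_per_family=2,
    species_per_genus=2,
    samples_per_species=2,
    gene_panel=panel,
    dropout_rate=0.1,
)
db = apply_dropout(simulate_sequences(cfg), cfg)
baseline = max(db.sample_ids, key=lambda s: len(db.genes_of(s)))
cache = GenePairCache(db)

profile = baseline_profile(db, baseline, "all", cache=cache)
print(f"baseline sample: {baseline}")
print("K2P distance to baseline (all shared genes pooled):")
print(profile.sort_values().to_string(float_format=lambda v: f"{v:.4f}"))

matrix = all_genes_matrix(db, cache=cache)
print("\nUPGMA dendrogram (newick):")
print(upgma_dendrogram(matrix))
print(
    "\nConspecific samples sit at ~0.001, congeners at ~0.02 and other\n"
    "families at ~0.08 — the simulated rank divergences; the dendrogram\n"
    "recovers the taxonomy's nesting from the distances alone."
)
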