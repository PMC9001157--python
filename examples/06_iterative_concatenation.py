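"""Iterative gene concatenation for relatedness-stratified comparisons.

Orders the panel with the common barcoding loci first (then a seeded
shuffle), builds comparison groups around a baseline sample (conspecifics,
congeners, confamilials, other families) and tracks the K2P distance to
each member as loci are added one at a time. Missing loci contribute no
comparable sites (pairwise deletion), so curves always reflect shared data.
"""

from plastref.distances import (
    comparison_groups_from_taxonomy,
    default_gene_order,
    iterative_concat,
)
from plastref.simulate import SimConfig, apply_dropout, simulate_sequences

panel = ("matK", "rbcL", "trnH-psbA", "ndhC", "psbA", "rpl16", "atpF", "accD")
cfg = SimConfig(
    seed=31,
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

order = default_gene_order(db.gene_panel, seed=1)
print("gene order:", " -> ".join(order.genes))

groups = comparison_groups_from_taxonomy(db, baseline, max_members=3)
table = iterative_concat(db, order, baseline, groups)

final = table[table.k == len(order.genes)]
print(f"\nK2P distance to baseline {baseline} after all {len(order.genes)} loci:")
for cat, sub in final.groupby("category", sort=False):
    print(f"  {cat:16s} mean={sub.distance.mean():.4f}  (n={len(sub)})")
print(
    "\nThe stratification survives concatenation: within-species stays near\n"
    "zero while between-family sits near the divergence of the lowest rank\n"
    "those pairs share (here the order, expected K2P 0.15).\n"
    "A YAML group file (see groups_example.yaml) can replace the\n"
    "taxonomy-derived groups via plastref.distances.load_groups_yaml."
)
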