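"""Leave-one-out discrimination test of a small reference database.

Simulates 16 samples (8 species in pairs) over four loci and asks, for
every (sample, gene): searching the database minus that sample, at what
taxonomic rank does the top hit agree with the query?
"""

from plastref.loo import loo_all
from plastref.simulate import SimConfig, apply_dropout, simulate_sequences

panel = ("matK", "rbcL", "ndhC", "psbA")
cfg = SimConfig(
    seed=11,
    n_classes=1,
    orders_per_class=1,
    families_per_order=2,
    genera_per_family=2,
    species_per_genus=2,
    samples_per_species=2,
    gene_panel=panel,
    dropout_rate=0.05,
)
db = apply_dropout(simulate_sequences(cfg), cfg)
report = loo_all(db)

print("per-gene % of samples assigned at each rank:")
for gene, s in report.summaries.items():
    row = ", ".join(f"{r}={s.percentages[r]:.0f}%" for r in ("species", "genus", "family"))
    print(f"  {gene:6s} (n={s.n_evaluated:2d}): {row}")
print(f"\npooled family-level-or-below: {report.pooled_family_or_below:.1f}% "
      f"of {len(report.assignments)} assignments")
print(
    "\nEvery species has a conspecific replicate and species are well\n"
    "separated, so most queries resolve at species rank; assignments at\n"
    "genus or above arise where dropout removed the conspecific's locus."
)
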