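"""End-to-end synthetic study runner.

Chains every stage of the toolkit on one simulated study: sequence
simulation, per-(sample, gene) pileup simulation and depth-masked consensus
calling, database assembly, gene-recovery accounting, leave-one-out
evaluation, baseline distance profiles with a dendrogram, and iterative
gene concatenation. All outputs are plain text (TSV/FASTA/newick/JSON) and
the whole run is a deterministic function of the configuration, so two runs
with the same config produce byte-identical output trees.

The baseline sample for the distance analyses is chosen as the sample with
the most recovered genes (ties broken lexicographically), mirroring the
practice of anchoring profiles on the most completely recovered voucher.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import AlignmentParams
from .consensus import consensus_from_frame, write_pileup
from .distances import (
    GenePairCache,
    all_genes_matrix,
    baseline_profile,
    comparison_groups_from_taxonomy,
    default_gene_order,
    iterative_concat,
    upgma_dendrogram,
)
from .loo import loo_all
from .refdb import GeneRegionSequence, ReferenceDatabase, recovery_matrix, write_db
from .simulate import _STREAM_PILEUP, SimConfig, apply_dropout, simulate_pileup, simulate_sequences

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """In-memory handles to everything a study run produced."""

    config: SimConfig
    db: ReferenceDatabase
    recovery: pd.DataFrame
    recovery_summary: object
    loo_report: object
    baseline_sample: str
    profiles: pd.DataFrame
    distance_matrix: pd.DataFrame
    dendrogram_newick: str
    iterative: pd.DataFrame
    out_dir: Path


def _consensus_stage(truth, db: ReferenceDatabase, config: SimConfig, out_dir: Path | None):
    """Replace each retained true sequence by its pileup-derived consensus."""
    called = ReferenceDatabase(taxa=db.taxa, sequences={}, gene_panel=db.gene_panel)
    sample_index = {t.sample_id: i for i, t in enumerate(db.taxa)}
    gene_index = {g: i for i, g in enumerate(db.gene_panel)}
    for sid in db.sample_ids:
        for gene in db.genes_of(sid):
            true_seq = truth.sequences[(sid, gene)]
            rng = config._rng(_STREAM_PILEUP, sample_index[sid], gene_index[gene])
            pileup = simulate_pileup(true_seq, config, rng=rng)
            if out_dir is not None:
                write_pileup(pileup, out_dir / f"pileup_{sid}_{gene}.tsv")
            cons = consensus_from_frame(pileup, length=len(true_seq), sample_id=sid)
            called.add(GeneRegionSequence(sid, gene, cons.seq))
    return called


def run_study(
    config: SimConfig,
    out_dir: str | Path,
    order_seed: int = 1,
    params: AlignmentParams | None = None,
    consensus: bool = True,
    write_pileups: bool = False,
    plots: bool = False,
) -> StudyResult:
    """Run the full pipeline on one simulated study and write its outputs.

    ``consensus=False`` skips the pileup/consensus stage and uses the true
    simulated sequences directly (useful for isolating the downstream
    analyses). ``write_pileups`` additionally persists every simulated
    pileup TSV, which is only sensible for small configurations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = simulate_sequences(config)
    db = apply_dropout(truth, config)
    if consensus:
        pileup_dir = None
        if write_pileups:
            pileup_dir = out_dir / "pileups"
            pileup_dir.mkdir(exist_ok=True)
        db = _consensus_stage(truth, db, config, pileup_dir)

    write_db(db, out_dir / "db.fasta", out_dir / "taxonomy.tsv")
    (out_dir / "true_tree.nwk").write_text(truth.tree_newick + "\n")

    rec, rec_summary = recovery_matrix(db)
    rec.astype(int).to_csv(out_dir / "recovery_matrix.tsv", sep="\t")
    summary_obj = {
        "max_recovered": rec_summary.max_recovered,
        "min_recovered": rec_summary.min_recovered,
        "mean_recovered": rec_summary.mean_recovered,
        "overall_rate": rec_summary.overall_rate,
        "per_gene_rate": {g: float(v) for g, v in rec_summary.per_gene_rate.items()},
    }

    cache = GenePairCache(db, params)
    report = loo_all(db, cache=cache)
    report.assignments.to_csv(out_dir / "loo_assignments.tsv", sep="\t", index=False)
    rank_rows = [
        {"gene": s.gene, "n_evaluated": s.n_evaluated, **s.percentages}
        for s in report.summaries.values()
    ]
    pd.DataFrame(rank_rows).to_csv(out_dir / "loo_summary.tsv", sep="\t", index=False)

    baseline = min(db.sample_ids, key=lambda s: (-len(db.genes_of(s)), s))
    profiles = pd.DataFrame(
        {
            gene: baseline_profile(db, baseline, gene, cache=cache)
            for gene in list(db.gene_panel) + ["all"]
            if gene == "all" or (baseline, gene) in db.sequences
        }
    )
    profiles.to_csv(out_dir / "baseline_profiles.tsv", sep="\t")

    matrix = all_genes_matrix(db, cache=cache)
    matrix.to_csv(out_dir / "k2p_all_genes.tsv", sep="\t")
    newick = upgma_dendrogram(matrix)
    (out_dir / "dendrogram.nwk").write_text(newick + "\n")

    order = default_gene_order(db.gene_panel, order_seed)
    groups = comparison_groups_from_taxonomy(db, baseline)
    iterative = iterative_concat(db, order, baseline, groups, cache=cache)
    iterative.to_csv(out_dir / "iterative_concat.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_samples": len(db.taxa),
        "gene_panel": list(db.gene_panel),
        "gene_order": list(order.genes),
        "order_seed": order_seed,
        "baseline_sample": baseline,
        "recovery": summary_obj,
        "loo_pooled_family_or_below": report.pooled_family_or_below,
        "loo_per_sample_family_or_below": report.per_sample_family_or_below,
    }
    (out_dir / "summary.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    if plots:
        from . import plotting

        plotting.plot_recovery_heatmap(rec, out_dir / "fig_recovery.png")
        plotting.plot_rank_summary(report, out_dir / "fig_loo_ranks.png")
        plotting.plot_baseline_profiles(profiles, out_dir / "fig_profiles.png")
        plotting.plot_iterative_curves(iterative, out_dir / "fig_iterative.png")

    return StudyResult(
        config=config,
        db=db,
        recovery=rec,
        recovery_summary=rec_summary,
        loo_report=report,
        baseline_sample=baseline,
        profiles=profiles,
        distance_matrix=matrix,
        dendrogram_newick=newick,
        iterative=iterative,
        out_dir=out_dir,
    )
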