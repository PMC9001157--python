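"""Hybridization-capture panel design.

Candidate target sequences for each gene region are clustered greedily at a
95% identity threshold, keeping the longest sequence of each cluster as the
representative, and each representative is tiled with 120-mer probes at 2X
tiling (consecutive probes overlap by half their length). The clustering is
incremental in length order, CD-HIT style: a sequence joins the first
existing cluster whose representative it matches at or above the threshold
(identity over the shorter sequence), otherwise it founds a new cluster.
Greedy clustering therefore guarantees member-to-representative identity,
not representative-to-representative dissimilarity.

Target extraction from a genome is a local-alignment search thresholded on
alignment identity and on coverage of the reference gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignmentParams, global_align, identity, local_align

logger = logging.getLogger(__name__)

__all__ = [
    "PROBE_LENGTH",
    "TargetSequence",
    "Cluster",
    "Probe",
    "PanelReport",
    "extract_targets",
    "greedy_cluster",
    "tile_probes",
    "design_panel",
    "write_probes_fasta",
]

#: Standard capture bait length in nucleotides.
PROBE_LENGTH = 120


@dataclass(frozen=True)
class TargetSequence:
    """A candidate target region: one gene from one taxon."""

    seq_id: str
    gene: str
    taxon_label: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"target {self.seq_id!r} has an empty sequence")
        if "-" in self.seq:
            raise ValueError(f"target {self.seq_id!r} contains gap characters")


@dataclass(frozen=True)
class Cluster:
    """A greedy identity cluster; the representative is its longest member."""

    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("cluster representative must be a member")


@dataclass(frozen=True)
class Probe:
    """One fixed-length capture probe window on a representative sequence."""

    source_id: str
    start: int
    seq: str
    length: int = PROBE_LENGTH

    def __post_init__(self) -> None:
        if len(self.seq) != self.length:
            raise ValueError("probe sequence length differs from declared length")


def extract_targets(
    reference_gene: TargetSequence,
    genome: str,
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
    params: AlignmentParams | None = None,
) -> TargetSequence | None:
    """Locate a gene region on a genome by local alignment.

    Returns the genome footprint as a new :class:`TargetSequence` when the
    alignment identity (over columns) reaches ``min_identity`` and the
    aligned footprint covers at least ``min_coverage`` of the reference
    gene; otherwise ``None``.
    """
    if not genome:
        raise ValueError("empty genome sequence")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    aln = local_align(reference_gene.seq, genome, params)
    if aln.n_columns == 0:
        return None
    if identity(aln, "columns") < min_identity:
        return None
    ref_cov = (aln.a_end - aln.a_start) / len(reference_gene.seq)
    if ref_cov < min_coverage:
        return None
    return TargetSequence(
        seq_id=f"{reference_gene.seq_id}|hit",
        gene=reference_gene.gene,
        taxon_label=reference_gene.taxon_label,
        seq=genome[aln.b_start : aln.b_end],
    )


def greedy_cluster(
    seqs: list[TargetSequence],
    threshold: float = 0.95,
    params: AlignmentParams | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest-first (ties by seq_id); each joins the
    first cluster whose representative it matches at ``identity(shorter) >=
    threshold`` under global alignment, else founds a new cluster.
    Representatives are therefore the longest member of their cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    genes = {s.gene for s in seqs}
    if len(genes) > 1:
        raise ValueError(f"sequences span multiple genes: {sorted(genes)}")
    ordered = sorted(seqs, key=lambda s: (-len(s.seq), s.seq_id))
    reps: list[TargetSequence] = []
    members: list[list[str]] = []
    for seq in ordered:
        for idx, rep in enumerate(reps):
            aln = global_align(rep.seq, seq.seq, params)
            if identity(aln, "shorter") >= threshold:
                members[idx].append(seq.seq_id)
                break
        else:
            reps.append(seq)
            members.append([seq.seq_id])
    return [
        Cluster(representative_id=rep.seq_id, member_ids=tuple(mem))
        for rep, mem in zip(reps, members)
    ]


def tile_probes(
    target: TargetSequence, probe_len: int = PROBE_LENGTH, step: int | None = None
) -> list[Probe]:
    """Tile a representative with fixed-length probes.

    Probes start at 0, step, 2*step, ... while they fit; if the last regular
    probe ends short of the sequence end, one extra end-anchored probe is
    appended so the 3' end is covered. The default step of half the probe
    length gives 2X tiling. Sequences shorter than ``probe_len`` yield no
    probes (logged skip).
    """
    if probe_len <= 0:
        raise ValueError("probe length must be positive")
    step = probe_len // 2 if step is None else step
    if step <= 0:
        raise ValueError("tiling step must be positive")
    L = len(target.seq)
    if L < probe_len:
        logger.warning(
            "skipping %s: length %d below probe length %d", target.seq_id, L, probe_len
        )
        return []
    starts = list(range(0, L - probe_len + 1, step))
    if starts[-1] + probe_len < L:
        starts.append(L - probe_len)
    return [
        Probe(source_id=target.seq_id, start=s, seq=target.seq[s : s + probe_len], length=probe_len)
        for s in starts
    ]


@dataclass
class PanelReport:
    """Full output of a panel design run."""

    clusters: dict[str, list[Cluster]]
    representatives: dict[str, list[TargetSequence]]
    probes: list[Probe]
    per_gene: pd.DataFrame

    @property
    def n_representatives(self) -> int:
        return sum(len(v) for v in self.representatives.values())

    @property
    def n_probes(self) -> int:
        return len(self.probes)


def design_panel(
    seqs: list[TargetSequence],
    threshold: float = 0.95,
    probe_len: int = PROBE_LENGTH,
    params: AlignmentParams | None = None,
) -> PanelReport:
    """Cluster candidates per gene and tile probes on every representative.

    The report carries, per gene and overall: input sequence count, cluster
    (= representative) count, probe count, and representative length
    min/mean/max.
    """
    by_gene: dict[str, list[TargetSequence]] = {}
    for s in seqs:
        by_gene.setdefault(s.gene, []).append(s)
    clusters: dict[str, list[Cluster]] = {}
    representatives: dict[str, list[TargetSequence]] = {}
    probes: list[Probe] = []
    rows = []
    for gene in sorted(by_gene):
        gene_seqs = by_gene[gene]
        by_id = {s.seq_id: s for s in gene_seqs}
        gene_clusters = greedy_cluster(gene_seqs, threshold, params)
        reps = [by_id[c.representative_id] for c in gene_clusters]
        gene_probes = [p for rep in reps for p in tile_probes(rep, probe_len)]
        clusters[gene] = gene_clusters
        representatives[gene] = reps
        probes.extend(gene_probes)
        lengths = [len(r.seq) for r in reps]
        rows.append(
            {
                "gene": gene,
                "n_input": len(gene_seqs),
                "n_clusters": len(gene_clusters),
                "n_probes": len(gene_probes),
                "rep_len_min": min(lengths),
                "rep_len_mean": sum(lengths) / len(lengths),
                "rep_len_max": max(lengths),
            }
        )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_input",
            "n_clusters",
            "n_probes",
            "rep_len_min",
            "rep_len_mean",
            "rep_len_max",
        ],
    )
    return PanelReport(clusters, representatives, probes, per_gene)


def write_probes_fasta(probes: list[Probe], path: str | Path) -> None:
    """Write probes as FASTA with headers ``>source_id|start``."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.source_id}|{p.start}\n{p.seq}\n")
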