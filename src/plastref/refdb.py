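"""Data model and I/O for the multi-locus reference database.

A :class:`ReferenceDatabase` couples a taxonomy table (one vouchered sample
per row, classified at species, genus, family, order and class rank plus a
collection location) with the gene-region sequences recovered for those
samples across a configurable panel of chloroplast loci. Sequences may
contain ``N`` where consensus calling masked low-depth or ambiguous
positions; gene-recovery accounting summarises how much of the panel each
sample actually yielded.

On disk the database is a plain multi-FASTA (headers ``sample_id|gene``)
plus a tab-separated taxonomy table, so it round-trips through standard
tooling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RANKS",
    "DEFAULT_GENE_PANEL",
    "TaxonRecord",
    "GeneRegionSequence",
    "ReferenceDatabase",
    "RecoverySummary",
    "read_db",
    "write_db",
    "recovery_matrix",
]

#: Taxonomic ranks from most to least specific.
RANKS = ("species", "genus", "family", "order", "class_")

#: Default 20-locus chloroplast panel. The first entries are the commonly
#: used plant barcoding regions; the panel is a configuration default and is
#: user-overridable everywhere it is consumed.
DEFAULT_GENE_PANEL = (
    "matK",
    "rbcL",
    "trnH-psbA",
    "ndhC",
    "psbA",
    "psbH",
    "psbZ",
    "rpoC1",
    "petD",
    "rpl16",
    "petA",
    "atpF",
    "atpH",
    "accD",
    "psbK",
    "ndhF",
    "psbD",
    "psbE",
    "rpoB",
    "psbC",
)

_SEQ_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class TaxonRecord:
    """One vouchered sample with its five-rank taxonomy and location."""

    sample_id: str
    species: str
    genus: str
    family: str
    order: str
    class_: str
    location: str = ""

    def __post_init__(self) -> None:
        for rank in ("sample_id",) + RANKS:
            if not getattr(self, rank):
                raise ValueError(f"{rank} must be non-empty for {self.sample_id!r}")

    def rank_value(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass(frozen=True)
class GeneRegionSequence:
    """One (sample, gene) nucleotide sequence, possibly containing Ns."""

    sample_id: str
    gene: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for ({self.sample_id}, {self.gene})")
        if not _SEQ_RE.match(self.seq):
            raise ValueError(
                f"sequence for ({self.sample_id}, {self.gene}) has characters "
                "outside A,C,G,T,N"
            )

    @property
    def unambiguous_fraction(self) -> float:
        return 1.0 - self.seq.count("N") / len(self.seq)


@dataclass
class ReferenceDatabase:
    """Taxonomy plus gene-region sequences over an ordered gene panel."""

    taxa: list[TaxonRecord]
    sequences: dict[tuple[str, str], GeneRegionSequence] = field(default_factory=dict)
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL

    def __post_init__(self) -> None:
        ids = [t.sample_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise ValueError(f"duplicate sample_id {dup!r} in taxonomy")
        self._taxa_by_id = {t.sample_id: t for t in self.taxa}
        for (sid, gene), rec in self.sequences.items():
            if (sid, gene) != (rec.sample_id, rec.gene):
                raise ValueError(f"sequence key/record mismatch for {(sid, gene)}")
            self._check_membership(rec)

    def _check_membership(self, rec: GeneRegionSequence) -> None:
        if rec.sample_id not in self._taxa_by_id:
            raise ValueError(f"sample {rec.sample_id!r} not present in taxonomy")
        if rec.gene not in self.gene_panel:
            raise ValueError(f"gene {rec.gene!r} not in the configured panel")

    # -- access -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.taxa]

    def taxon(self, sample_id: str) -> TaxonRecord:
        try:
            return self._taxa_by_id[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def get(self, sample_id: str, gene: str) -> GeneRegionSequence | None:
        return self.sequences.get((sample_id, gene))

    def add(self, rec: GeneRegionSequence) -> None:
        key = (rec.sample_id, rec.gene)
        if key in self.sequences:
            raise ValueError(f"duplicate sequence record for {key}")
        self._check_membership(rec)
        self.sequences[key] = rec

    def samples_with_gene(self, gene: str) -> list[str]:
        return [s for s in self.sample_ids if (s, gene) in self.sequences]

    def genes_of(self, sample_id: str) -> list[str]:
        return [g for g in self.gene_panel if (sample_id, g) in self.sequences]


# -- I/O -------------------------------------------------------------------

_TAX_COLUMNS = ["sample_id", "species", "genus", "family", "order", "class", "location"]


def read_taxonomy(path: str | Path) -> list[TaxonRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_TAX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    return [
        TaxonRecord(
            sample_id=row["sample_id"],
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            class_=row["class"],
            location=row["location"],
        )
        for row in df[_TAX_COLUMNS].to_dict("records")
    ]


def read_db(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL,
) -> ReferenceDatabase:
    """Load a reference database from a FASTA + taxonomy TSV pair.

    FASTA headers must parse as ``sample_id|gene``; every sample must exist
    in the taxonomy and every gene in the panel. Errors name the offending
    record.
    """
    taxa = read_taxonomy(taxonomy_path)
    db = ReferenceDatabase(taxa=taxa, sequences={}, gene_panel=tuple(gene_panel))
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"malformed FASTA header {rec.id!r}: expected sample_id|gene")
        sid, gene = parts
        db.add(GeneRegionSequence(sid, gene, str(rec.seq).upper()))
    return db


def write_db(db: ReferenceDatabase, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
    """Write the database back to FASTA + TSV (inverse of :func:`read_db`)."""
    records = [
        SeqRecord(Seq(rec.seq), id=f"{rec.sample_id}|{rec.gene}", description="")
        for sid in db.sample_ids
        for gene in db.gene_panel
        if (rec := db.sequences.get((sid, gene))) is not None
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "sample_id": t.sample_id,
            "species": t.species,
            "genus": t.genus,
            "family": t.family,
            "order": t.order,
            "class": t.class_,
            "location": t.location,
        }
        for t in db.taxa
    ]
    pd.DataFrame(rows, columns=_TAX_COLUMNS).to_csv(taxonomy_path, sep="\t", index=False)


# -- recovery accounting ---------------------------------------------------


@dataclass(frozen=True)
class RecoverySummary:
    """Per-sample recovered-gene counts and per-gene recovery rates."""

    per_sample: pd.Series
    per_gene_rate: pd.Series
    max_recovered: int
    min_recovered: int
    mean_recovered: float
    overall_rate: float


def recovery_matrix(
    db: ReferenceDatabase, min_unambiguous_fraction: float = 0.5
) -> tuple[pd.DataFrame, RecoverySummary]:
    """Samples x genes boolean recovery matrix plus summary statistics.

    A gene counts as recovered for a sample iff a sequence exists and its
    non-``N`` fraction is at least ``min_unambiguous_fraction`` (presence
    alone is not enough: a fully masked sequence carries no information).
    """
    if not db.taxa:
        raise ValueError("empty database")
    samples = db.sample_ids
    mat = pd.DataFrame(False, index=samples, columns=list(db.gene_panel))
    for (sid, gene), rec in db.sequences.items():
        if rec.unambiguous_fraction >= min_unambiguous_fraction:
            mat.loc[sid, gene] = True
    per_sample = mat.sum(axis=1)
    per_gene = mat.mean(axis=0)
    summary = RecoverySummary(
        per_sample=per_sample,
        per_gene_rate=per_gene,
        max_recovered=int(per_sample.max()),
        min_recovered=int(per_sample.min()),
        mean_recovered=float(per_sample.mean()),
        overall_rate=float(np.asarray(mat, dtype=float).mean()),
    )
    return mat, summary
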