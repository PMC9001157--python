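"""Kimura two-parameter distances and the discrimination analyses built on them.

The K2P distance corrects the observed proportions of transitions
(``P``, A<->G and C<->T) and transversions (``Q``, all other differing
pairs) for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Site counting uses pairwise deletion: any alignment column containing a gap
or an ``N`` in either sequence is excluded. Because P and Q are simple
ratios of pooled counts, the distance of a concatenated alignment equals
the distance computed from the summed site counts of its blocks — the
toolkit exploits this identity throughout: multi-locus distances are pooled
from per-gene pairwise alignments rather than by aligning a concatenation,
which gives the identical value while keeping alignment cost linear in the
number of loci.

Two analyses are provided: baseline distance profiles per gene and for the
pooled "all" panel, with a UPGMA dendrogram over the all-genes matrix; and
iterative gene concatenation, which tracks how the distance from a baseline
sample to each member of a comparison group changes as loci are added in a
fixed order (common barcoding loci first, then a seeded random tail).
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .align import AlignmentParams, global_align
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCounts",
    "site_counts",
    "k2p",
    "PairStats",
    "pair_stats",
    "GenePairCache",
    "baseline_profile",
    "all_genes_matrix",
    "upgma_dendrogram",
    "ComparisonGroup",
    "comparison_groups_from_taxonomy",
    "load_groups_yaml",
    "GeneOrder",
    "default_gene_order",
    "iterative_concat",
    "COMMON_BARCODES",
]

#: Commonly used plant barcoding loci, in priority order, used as the fixed
#: prefix of the iterative concatenation gene order.
COMMON_BARCODES = ("matK", "rbcL", "trnH-psbA")

# Byte-level classification tables for site counting.
_CLASS = np.full(256, -1, dtype=np.int8)  # A=0 C=1 G=2 T=3, N/- excluded
for _i, _c in enumerate("ACGT"):
    _CLASS[ord(_c)] = _i
    _CLASS[ord(_c.lower())] = _i
_EXCL = np.full(256, True)
for _c in "ACGTacgt":
    _EXCL[ord(_c)] = False
for _c in "Nn-":
    _EXCL[ord(_c)] = True


@dataclass(frozen=True)
class SiteCounts:
    """Comparable-site tally for one aligned sequence pair (or pooled blocks)."""

    n_valid: int = 0
    n_transition: int = 0
    n_transversion: int = 0

    def __post_init__(self) -> None:
        if min(self.n_valid, self.n_transition, self.n_transversion) < 0:
            raise ValueError("site counts must be non-negative")
        if self.n_transition + self.n_transversion > self.n_valid:
            raise ValueError("differing sites exceed comparable sites")

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.n_valid + other.n_valid,
            self.n_transition + other.n_transition,
            self.n_transversion + other.n_transversion,
        )


def site_counts(aligned_a: str, aligned_b: str) -> SiteCounts:
    """Count comparable, transition and transversion sites in an alignment.

    Columns with a gap or ``N`` in either sequence are excluded (pairwise
    deletion).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    a = np.frombuffer(aligned_a.encode("ascii", "replace"), dtype=np.uint8)
    b = np.frombuffer(aligned_b.encode("ascii", "replace"), dtype=np.uint8)
    bad = _CLASS[a] < 0
    bad |= _CLASS[b] < 0
    if (bad & ~_EXCL[a] & ~_EXCL[b]).any():
        raise ValueError("unexpected character in aligned sequence")
    keep = ~(_EXCL[a] | _EXCL[b])
    ca = _CLASS[a[keep]]
    cb = _CLASS[b[keep]]
    diff = ca != cb
    # A(0)/G(2) are even codes, C(1)/T(3) odd: a differing pair is a
    # transition iff the codes share parity.
    ts = int((diff & (((ca ^ cb) & 1) == 0)).sum())
    tv = int(diff.sum()) - ts
    return SiteCounts(int(keep.sum()), ts, tv)


def k2p(counts: SiteCounts) -> float:
    """Kimura two-parameter distance from site counts.

    Returns ``nan`` when undefined: no comparable sites, or observed
    proportions outside the formula's domain (1 - 2P - Q <= 0 or
    1 - 2Q <= 0, i.e. divergence too high to correct).
    """
    if counts.n_valid == 0:
        return math.nan
    p = counts.n_transition / counts.n_valid
    q = counts.n_transversion / counts.n_valid
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # normalise -0.0


# -- pairwise statistics cache ---------------------------------------------


@dataclass(frozen=True)
class PairStats:
    """Alignment and site statistics for one sample pair at one gene."""

    n_columns: int
    n_match: int
    n_mismatch: int
    counts: SiteCounts

    @property
    def identity_columns(self) -> float:
        return self.n_match / self.n_columns if self.n_columns else 0.0


def pair_stats(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> PairStats:
    """Globally align two sequences and collect alignment + site statistics."""
    aln = global_align(seq_a, seq_b, params)
    return PairStats(
        aln.n_columns, aln.n_match, aln.n_mismatch, site_counts(aln.aligned_a, aln.aligned_b)
    )


class GenePairCache:
    """Lazy per-gene pairwise alignment statistics over a database.

    Alignment statistics are treated as a symmetric property of a sample
    pair; each pair is aligned once in canonical (sorted sample id)
    orientation, so every consumer — leave-one-out ranking, distance
    matrices, iterative concatenation — sees identical numbers regardless
    of query direction.
    """

    def __init__(self, db: ReferenceDatabase, params: AlignmentParams | None = None):
        self.db = db
        self.params = params or AlignmentParams()
        self._stats: dict[tuple[str, str, str], PairStats] = {}

    def get(self, gene: str, sample_a: str, sample_b: str) -> PairStats | None:
        """Stats for a pair at a gene, or None if either sample lacks it."""
        if sample_a == sample_b:
            raise ValueError("pair statistics require two distinct samples")
        s1, s2 = sorted((sample_a, sample_b))
        key = (gene, s1, s2)
        hit = self._stats.get(key)
        if hit is not None:
            return hit
        ra = self.db.get(s1, gene)
        rb = self.db.get(s2, gene)
        if ra is None or rb is None:
            return None
        stats = pair_stats(ra.seq, rb.seq, self.params)
        self._stats[key] = stats
        return stats


# -- baseline profiles & distance matrix -----------------------------------


def _pooled_counts(
    cache: GenePairCache, sample_a: str, sample_b: str, genes
) -> SiteCounts:
    total = SiteCounts()
    for gene in genes:
        st = cache.get(gene, sample_a, sample_b)
        if st is not None:
            total = total + st.counts
    return total


def baseline_profile(
    db: ReferenceDatabase,
    baseline_sample: str,
    gene: str = "all",
    params: AlignmentParams | None = None,
    cache: GenePairCache | None = None,
) -> pd.Series:
    """K2P distance from one baseline sample to every sample in the database.

    ``gene='all'`` pools site counts over every gene both samples possess
    (panel order); samples sharing no usable sites get ``nan``. For a single
    gene, samples lacking it get ``nan``.
    """
    if baseline_sample not in db.sample_ids:
        raise KeyError(f"unknown baseline sample {baseline_sample!r}")
    cache = cache or GenePairCache(db, params)
    if gene == "all":
        genes = list(db.gene_panel)
        if not db.genes_of(baseline_sample):
            raise ValueError(f"baseline {baseline_sample!r} has no gene sequences")
    else:
        if (baseline_sample, gene) not in db.sequences:
            raise ValueError(f"baseline {baseline_sample!r} lacks gene {gene!r}")
        genes = [gene]
    out = {}
    for sid in db.sample_ids:
        if sid == baseline_sample:
            out[sid] = 0.0
            continue
        counts = _pooled_counts(cache, baseline_sample, sid, genes)
        out[sid] = k2p(counts)
    return pd.Series(out, name=f"k2p_{gene}")


def all_genes_matrix(
    db: ReferenceDatabase,
    params: AlignmentParams | None = None,
    cache: GenePairCache | None = None,
) -> pd.DataFrame:
    """Symmetric K2P matrix pooling every gene each pair shares.

    Entries are ``nan`` where the pair shares no comparable sites or the
    K2P formula is undefined; the diagonal is zero.
    """
    samples = db.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    cache = cache or GenePairCache(db, params)
    mat = pd.DataFrame(np.zeros((len(samples), len(samples))), index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            d = k2p(_pooled_counts(cache, si, sj, db.gene_panel))
            mat.loc[si, sj] = d
            mat.loc[sj, si] = d
    return mat


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    bl = max(node.dist / 2.0 - node.get_left().dist / 2.0, 0.0)
    br = max(node.dist / 2.0 - node.get_right().dist / 2.0, 0.0)
    return f"({left}:{bl:.6g},{right}:{br:.6g})"


def upgma_dendrogram(matrix: pd.DataFrame, method: str = "average") -> str:
    """Agglomerate a labelled distance matrix into a newick dendrogram.

    ``method='average'`` is UPGMA; ``complete`` and ``single`` are accepted
    for comparison. Undefined entries are imputed as the matrix maximum
    (logged) so agglomeration stays defined; branch lengths are ultrametric
    node heights (cluster distance / 2).
    """
    if method not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {method!r}")
    values = matrix.to_numpy(dtype=float).copy()
    if not np.isfinite(np.diag(values)).all() or (np.abs(np.diag(values)) > 1e-12).any():
        raise ValueError("distance matrix diagonal must be zero")
    off = ~np.eye(len(values), dtype=bool)
    undef = ~np.isfinite(values) & off
    if undef[off].all():
        raise ValueError("distance matrix is entirely undefined")
    if undef.any():
        mx = np.nanmax(values[off])
        logger.info("imputing %d undefined distances as matrix max %.4g", undef.sum(), mx)
        values[undef] = mx
    condensed = squareform(values, checks=True)
    link = linkage(condensed, method=method)
    tree = to_tree(link)
    return _newick(tree, list(matrix.index)) + ";"


# -- comparison groups ------------------------------------------------------


@dataclass(frozen=True)
class ComparisonGroup:
    """A labelled set of samples compared against a fixed baseline sample."""

    label: str
    baseline_sample: str
    member_samples: tuple[str, ...]
    category: str = ""

    def __post_init__(self) -> None:
        if self.baseline_sample in self.member_samples:
            raise ValueError("baseline sample may not be a group member")


@dataclass(frozen=True)
class GeneOrder:
    """A permutation of the gene panel: common barcodes first, seeded tail."""

    genes: tuple[str, ...]
    seed: int


def comparison_groups_from_taxonomy(
    db: ReferenceDatabase,
    baseline_sample: str,
    max_members: int = 7,
) -> list[ComparisonGroup]:
    """Build relatedness-stratified comparison groups around a baseline.

    Mirrors the structure of curated group analyses (baseline species vs
    conspecific populations, congeners, confamilials and other families) but
    derives membership from the taxonomy table, so it applies to any
    database. Categories: ``within species`` (other samples of the baseline
    species), ``within genus`` (other species, same genus), ``within
    family`` (other genera, same family), ``between family`` (other
    families). Each category is capped at ``max_members`` samples (taken in
    database order).
    """
    base = db.taxon(baseline_sample)
    buckets: dict[str, list[str]] = {
        "within species": [],
        "within genus": [],
        "within family": [],
        "between family": [],
    }
    for t in db.taxa:
        if t.sample_id == baseline_sample:
            continue
        if t.species == base.species:
            buckets["within species"].append(t.sample_id)
        elif t.genus == base.genus:
            buckets["within genus"].append(t.sample_id)
        elif t.family == base.family:
            buckets["within family"].append(t.sample_id)
        else:
            buckets["between family"].append(t.sample_id)
    return [
        ComparisonGroup(
            label=cat,
            baseline_sample=baseline_sample,
            member_samples=tuple(members[:max_members]),
            category=cat,
        )
        for cat, members in buckets.items()
        if members
    ]


def load_groups_yaml(path) -> list[ComparisonGroup]:
    """Load declarative comparison groups from YAML.

    Expected layout::

        baseline: <sample_id>
        groups:
          - label: within species
            category: within species
            members: [<sample_id>, ...]
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    baseline = spec["baseline"]
    return [
        ComparisonGroup(
            label=g["label"],
            baseline_sample=baseline,
            member_samples=tuple(g["members"]),
            category=g.get("category", g["label"]),
        )
        for g in spec["groups"]
    ]


def default_gene_order(
    panel,
    seed: int,
    common: tuple[str, ...] = COMMON_BARCODES,
) -> GeneOrder:
    """Order a gene panel for iterative concatenation.

    The prefix is the intersection of ``panel`` with the configured common
    barcoding loci (in their priority order); the remainder is shuffled
    deterministically with ``seed``.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty gene panel")
    prefix = [g for g in common if g in panel]
    tail = [g for g in panel if g not in prefix]
    random.Random(seed).shuffle(tail)
    return GeneOrder(tuple(prefix + tail), seed)


def iterative_concat(
    db: ReferenceDatabase,
    order: GeneOrder,
    baseline_sample: str,
    groups: list[ComparisonGroup],
    params: AlignmentParams | None = None,
    cache: GenePairCache | None = None,
) -> pd.DataFrame:
    """Distance from the baseline to each group member as loci are added.

    For each prefix length ``k`` of the gene order, site counts are pooled
    over the first ``k`` genes; a gene missing in either sample contributes
    an all-gap block, which pairwise deletion removes, so the distance is
    always computed over the loci the pair shares. Returns a long-format
    table with columns ``group, category, member, k, gene_added, n_valid,
    distance``.
    """
    if baseline_sample not in db.sample_ids:
        raise KeyError(f"unknown baseline sample {baseline_sample!r}")
    if (baseline_sample, order.genes[0]) not in db.sequences:
        raise ValueError(
            f"baseline {baseline_sample!r} lacks the first gene of the order "
            f"({order.genes[0]!r})"
        )
    cache = cache or GenePairCache(db, params)
    rows = []
    for group in groups:
        for member in group.member_samples:
            if member not in db.sample_ids:
                raise KeyError(f"group member {member!r} absent from database")
            running = SiteCounts()
            for k, gene in enumerate(order.genes, start=1):
                st = cache.get(gene, baseline_sample, member)
                if st is not None:
                    running = running + st.counts
                rows.append(
                    {
                        "group": group.label,
                        "category": group.category,
                        "member": member,
                        "k": k,
                        "gene_added": gene,
                        "n_valid": running.n_valid,
                        "distance": k2p(running),
                    }
                )
    return pd.DataFrame(rows)
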