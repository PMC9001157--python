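"""Leave-one-out discrimination evaluation of a reference database.

Each sample possessing a gene is searched against every other sample
carrying that gene; the top hit is the candidate maximising global
alignment identity over alignment columns. The query/hit pair is then
classified at the lowest taxonomic rank on which the two taxonomies agree
(species < genus < family < order < class), or ``none`` if they share no
rank. Per-gene summaries report the percentage of evaluated samples landing
at each rank; the pooled headline statistic is the percentage of all
(sample, gene) assignments matched at family level or below.

Ties in identity are broken by the larger number of matched columns, then
by lexicographic sample id — a documented deterministic rule, not an
inference about any external search tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import AlignmentParams
from .distances import GenePairCache, pair_stats
from .refdb import GeneRegionSequence, ReferenceDatabase, TaxonRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MATCH_RANKS",
    "AssignmentResult",
    "RankSummary",
    "LooReport",
    "top_hit",
    "classify_rank",
    "loo_summary",
    "loo_all",
]

#: Rank labels in classification order, plus the no-agreement outcome.
MATCH_RANKS = ("species", "genus", "family", "order", "class", "none")

_RANK_FIELDS = (
    ("species", "species"),
    ("genus", "genus"),
    ("family", "family"),
    ("order", "order"),
    ("class", "class_"),
)


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of one leave-one-out query."""

    query_sample: str
    gene: str
    hit_sample: str | None
    score: float
    matched_rank: str


@dataclass(frozen=True)
class RankSummary:
    """Percentage of evaluated samples assigned at each rank for one gene."""

    gene: str
    percentages: dict[str, float]
    n_evaluated: int


@dataclass(frozen=True)
class LooReport:
    """Full leave-one-out evaluation across the gene panel."""

    summaries: dict[str, RankSummary]
    assignments: pd.DataFrame
    #: % of all (sample, gene) assignments matched at family level or below.
    pooled_family_or_below: float
    #: % of samples whose best assignment over any gene is family or below.
    per_sample_family_or_below: float


def classify_rank(query_taxon: TaxonRecord, hit_taxon: TaxonRecord) -> str:
    """Lowest rank at which two taxonomies agree, or ``'none'``."""
    for label, attr in _RANK_FIELDS:
        if getattr(query_taxon, attr) == getattr(hit_taxon, attr):
            return label
    return "none"


def top_hit(
    query: GeneRegionSequence,
    candidates: list[GeneRegionSequence],
    params: AlignmentParams | None = None,
) -> tuple[GeneRegionSequence | None, float]:
    """Best database hit for a query sequence by alignment identity.

    Identity is treated as a symmetric pair property: each pair is aligned
    in canonical (sorted sample id) orientation, matching the cached search
    used by :func:`loo_all`. Returns ``(None, 0.0)`` for an empty candidate
    list.
    """
    best = None
    best_key = None
    for cand in candidates:
        if cand.gene != query.gene:
            raise ValueError(
                f"candidate {cand.sample_id!r} is gene {cand.gene!r}, "
                f"query is {query.gene!r}"
            )
        if cand.sample_id == query.sample_id:
            raise ValueError("candidates must exclude the query's own sample")
        a, b = sorted((query, cand), key=lambda r: r.sample_id)
        st = pair_stats(a.seq, b.seq, params)
        key = (st.identity_columns, st.n_match, _Reversed(cand.sample_id))
        if best_key is None or key > best_key:
            best, best_key = cand, key
    if best is None:
        return None, 0.0
    return best, best_key[0]


class _Reversed:
    """Orders strings descending inside an ascending max-key comparison."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_Reversed") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_Reversed") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Reversed) and self.s == other.s


def _informative(rec: GeneRegionSequence) -> bool:
    return any(c != "N" for c in rec.seq)


def _evaluate_gene(
    db: ReferenceDatabase, gene: str, cache: GenePairCache
) -> list[AssignmentResult]:
    carriers = db.samples_with_gene(gene)
    if not carriers:
        raise ValueError(f"gene {gene!r} absent from database")
    if len(carriers) < 2:
        raise ValueError(f"gene {gene!r} carried by fewer than 2 samples")
    results = []
    for query in carriers:
        if not _informative(db.sequences[(query, gene)]):
            logger.info("excluding fully masked sequence (%s, %s)", query, gene)
            continue
        best_key = None
        best_hit = None
        for cand in carriers:
            if cand == query:
                continue
            st = cache.get(gene, query, cand)
            key = (st.identity_columns, st.n_match, _Reversed(cand))
            if best_key is None or key > best_key:
                best_key, best_hit = key, cand
        rank = classify_rank(db.taxon(query), db.taxon(best_hit))
        results.append(AssignmentResult(query, gene, best_hit, best_key[0], rank))
    return results


def _summarise(gene: str, results: list[AssignmentResult]) -> RankSummary:
    n = len(results)
    pct = {r: 0.0 for r in MATCH_RANKS}
    for res in results:
        pct[res.matched_rank] += 100.0 / n
    return RankSummary(gene=gene, percentages=pct, n_evaluated=n)


def loo_summary(
    db: ReferenceDatabase,
    gene: str,
    params: AlignmentParams | None = None,
    cache: GenePairCache | None = None,
) -> RankSummary:
    """Leave-one-out rank summary for one gene region."""
    cache = cache or GenePairCache(db, params)
    return _summarise(gene, _evaluate_gene(db, gene, cache))


_BELOW_FAMILY = {"species", "genus", "family"}


def loo_all(
    db: ReferenceDatabase,
    params: AlignmentParams | None = None,
    cache: GenePairCache | None = None,
    genes: tuple[str, ...] | None = None,
) -> LooReport:
    """Leave-one-out evaluation across the panel, with pooled statistics.

    Genes carried by fewer than two samples are skipped (logged): no
    informative search exists for them.
    """
    cache = cache or GenePairCache(db, params)
    genes = genes or db.gene_panel
    all_results: list[AssignmentResult] = []
    summaries: dict[str, RankSummary] = {}
    for gene in genes:
        if len(db.samples_with_gene(gene)) < 2:
            logger.info("skipping gene %s: fewer than 2 carriers", gene)
            continue
        results = _evaluate_gene(db, gene, cache)
        summaries[gene] = _summarise(gene, results)
        all_results.extend(results)
    if not all_results:
        raise ValueError("no evaluable (sample, gene) assignments in database")
    frame = pd.DataFrame(
        [
            {
                "query_sample": r.query_sample,
                "gene": r.gene,
                "hit_sample": r.hit_sample,
                "score": r.score,
                "matched_rank": r.matched_rank,
            }
            for r in all_results
        ]
    )
    pooled = 100.0 * frame.matched_rank.isin(_BELOW_FAMILY).mean()
    by_sample = frame.groupby("query_sample").matched_rank.agg(
        lambda s: s.isin(_BELOW_FAMILY).any()
    )
    return LooReport(
        summaries=summaries,
        assignments=frame,
        pooled_family_or_below=float(pooled),
        per_sample_family_or_below=float(100.0 * by_sample.mean()),
    )
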