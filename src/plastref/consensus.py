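"""Depth-masked haploid consensus calling from simplified pileups.

A pileup here is a flat table of quality-labelled base observations
(position, base, base quality, mapping quality). Observations failing
either phred-30 quality filter are discarded; surviving counts are reduced
per position to a single haploid call: the majority base where passing
depth reaches the threshold (default 50), and ``N`` where depth falls
short, where the maximum count is tied, or where no observation exists. A
tie yields ``N`` deliberately — a haploid caller should not invent
certainty at positions the data leave ambiguous.

Gene regions are then located on the consensus by local alignment against
reference gene sequences, with a permissive identity threshold (default
25%) because the consensus may be heavily masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentParams, identity, local_align
from .probes import TargetSequence
from .refdb import GeneRegionSequence

logger = logging.getLogger(__name__)

__all__ = [
    "BaseObservation",
    "PileupColumn",
    "ConsensusSequence",
    "filter_observations",
    "call_consensus",
    "consensus_from_frame",
    "annotate_genes",
    "read_pileup",
    "write_pileup",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

MIN_QUALITY = 30
MIN_DEPTH = 50


@dataclass(frozen=True)
class BaseObservation:
    """One read base at one reference position."""

    position: int
    base: str
    base_quality: int
    map_quality: int

    def __post_init__(self) -> None:
        if self.base not in _BASE_INDEX:
            raise ValueError(f"observation base must be one of ACGT, got {self.base!r}")
        if self.base_quality < 0 or self.map_quality < 0:
            raise ValueError("qualities must be non-negative")
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class PileupColumn:
    """Quality-passing base counts at one 0-based position."""

    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ConsensusSequence:
    """A haploid consensus; ``N`` exactly at the masked positions."""

    sample_id: str
    seq: str
    masked_positions: frozenset[int]

    def __post_init__(self) -> None:
        for i, c in enumerate(self.seq):
            if (c == "N") != (i in self.masked_positions):
                raise ValueError(f"mask/sequence disagreement at position {i}")


def _obs_arrays(obs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(obs, pd.DataFrame):
        pos = obs["position"].to_numpy(dtype=np.int64)
        base = np.array([_BASE_INDEX[b] for b in obs["base"]], dtype=np.int8)
        bq = obs["base_q"].to_numpy(dtype=np.int64)
        mq = obs["map_q"].to_numpy(dtype=np.int64)
    else:
        pos = np.array([o.position for o in obs], dtype=np.int64)
        base = np.array([_BASE_INDEX[o.base] for o in obs], dtype=np.int8)
        bq = np.array([o.base_quality for o in obs], dtype=np.int64)
        mq = np.array([o.map_quality for o in obs], dtype=np.int64)
    if pos.size and (bq.min() < 0 or mq.min() < 0):
        raise ValueError("qualities must be non-negative")
    return pos, base, bq, mq


def _count_matrix(
    pos, base, bq, mq, length: int, min_base_q: int, min_map_q: int
) -> np.ndarray:
    """(length x 4) matrix of quality-passing base counts."""
    if pos.size and pos.max() >= length:
        raise ValueError("observation position beyond declared length")
    keep = (bq >= min_base_q) & (mq >= min_map_q)
    counts = np.zeros((length, 4), dtype=np.int64)
    if keep.any():
        flat = pos[keep] * 4 + base[keep]
        counts += np.bincount(flat, minlength=length * 4).reshape(length, 4)
    return counts


def filter_observations(
    obs,
    min_base_q: int = MIN_QUALITY,
    min_map_q: int = MIN_QUALITY,
    length: int | None = None,
) -> list[PileupColumn]:
    """Quality-filter observations into per-position pileup columns.

    An observation is counted iff both its base quality and its mapping
    quality reach the thresholds. One column is returned per position from
    0 to the highest observed position (or ``length - 1`` if given),
    including zero-depth columns. ``obs`` may be a list of
    :class:`BaseObservation` or a pileup DataFrame.
    """
    pos, base, bq, mq = _obs_arrays(obs)
    n = length if length is not None else (int(pos.max()) + 1 if pos.size else 0)
    counts = _count_matrix(pos, base, bq, mq, n, min_base_q, min_map_q)
    return [
        PileupColumn(
            position=i,
            counts={b: int(c) for b, c in zip(_BASES, counts[i]) if c > 0},
        )
        for i in range(n)
    ]


def call_consensus(
    columns: list[PileupColumn],
    length: int,
    min_depth: int = MIN_DEPTH,
    sample_id: str = "consensus",
) -> ConsensusSequence:
    """Haploid consensus with depth masking.

    Per position: depth below ``min_depth`` -> ``N``; otherwise the single
    majority base; an exact tie for the maximum count -> ``N``; positions
    with no column -> ``N``.
    """
    if columns and max(c.position for c in columns) >= length:
        raise ValueError("column position beyond declared length")
    counts = np.zeros((length, 4), dtype=np.int64)
    for col in columns:
        for b, c in col.counts.items():
            counts[col.position, _BASE_INDEX[b]] += c
    return _call_from_counts(counts, min_depth, sample_id)


def _call_from_counts(counts: np.ndarray, min_depth: int, sample_id: str) -> ConsensusSequence:
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    call = counts.argmax(axis=1)
    masked = (depth < min_depth) | tied
    letters = np.array(list(_BASES))[call]
    letters[masked] = "N"
    return ConsensusSequence(
        sample_id=sample_id,
        seq="".join(letters),
        masked_positions=frozenset(np.flatnonzero(masked).tolist()),
    )


def consensus_from_frame(
    frame: pd.DataFrame,
    length: int,
    min_base_q: int = MIN_QUALITY,
    min_map_q: int = MIN_QUALITY,
    min_depth: int = MIN_DEPTH,
    sample_id: str = "consensus",
) -> ConsensusSequence:
    """Vectorised filter + call pipeline for a pileup DataFrame.

    Equivalent to ``call_consensus(filter_observations(frame, ...), ...)``
    but without materialising per-position column objects; used at study
    scale.
    """
    pos, base, bq, mq = _obs_arrays(frame)
    counts = _count_matrix(pos, base, bq, mq, length, min_base_q, min_map_q)
    return _call_from_counts(counts, min_depth, sample_id)


def annotate_genes(
    consensus: ConsensusSequence,
    reference_genes: list[TargetSequence],
    min_identity: float = 0.25,
    flank: int = 100,
    hints: dict[str, tuple[int, int]] | None = None,
    params: AlignmentParams | None = None,
) -> list[GeneRegionSequence]:
    """Extract gene regions from a consensus by local-alignment annotation.

    Each reference gene is searched against the consensus (or, when a prior
    coordinate hint ``gene -> (start, end)`` is supplied, against that
    window widened by ``flank`` on either side). Genes whose best alignment
    identity (over columns) falls below ``min_identity`` are reported
    absent; extraction is the alignment footprint on the consensus.
    """
    if not reference_genes:
        raise ValueError("no reference genes supplied")
    out = []
    for ref in reference_genes:
        lo, hi = 0, len(consensus.seq)
        if hints and ref.gene in hints:
            h0, h1 = hints[ref.gene]
            lo = max(0, h0 - flank)
            hi = min(len(consensus.seq), h1 + flank)
        window = consensus.seq[lo:hi]
        if not window or set(window) == {"N"}:
            logger.info("gene %s absent: search window empty or fully masked", ref.gene)
            continue
        aln = local_align(ref.seq, window, params)
        if aln.n_columns == 0 or identity(aln, "columns") < min_identity:
            logger.info("gene %s absent: no alignment above identity threshold", ref.gene)
            continue
        footprint = consensus.seq[lo + aln.b_start : lo + aln.b_end]
        out.append(GeneRegionSequence(consensus.sample_id, ref.gene, footprint))
    return out


# -- pileup TSV I/O --------------------------------------------------------

_PILEUP_COLUMNS = ["position", "base", "base_q", "map_q"]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a simplified pileup TSV (one observation per row, 0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    return df[_PILEUP_COLUMNS]


def write_pileup(frame: pd.DataFrame, path: str | Path) -> None:
    frame[_PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)
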