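# Methods

This note documents the models, procedures and numerical choices behind
`plastref`, and what the synthetic studies it ships with do and do not
establish about real data.

## Pairwise alignment

All sequence comparison runs through exact dynamic programming:
Needleman–Wunsch for global alignment, Smith–Waterman for local search,
both with Gotoh affine gap costs (a run of `k` gap columns costs
`gap_open + (k−1)·gap_extend`). Defaults are match +1, mismatch −1,
gap_open −2, gap_extend −1 — standard nucleotide scoring; nothing
downstream is sensitive to the exact values at the divergences the toolkit
operates on, because thresholds act on identities, not raw scores. Setting
`gap_extend = gap_open` gives linear gap costs, the mode the brute-force
test oracle enumerates.

Determinism is part of the contract. Traceback ties prefer the diagonal
move, then the vertical (gap in the second sequence), then the horizontal;
gap states close as early as possible on ties; local alignment anchors on
the earliest maximal cell in row-major order. These rules are design
choices that make every downstream number bit-reproducible — they are not
inferences about how any external aligner breaks ties.

`N` scores as a mismatch against everything, including another `N`: masked
positions are absence of evidence, never support for a match. Alignment
identity comes in two modes: `columns` (matches / alignment columns), used
for hit ranking and annotation thresholds, and `shorter` (matches / length
of the shorter sequence), the convention greedy clustering thresholds on.

The inner DP loops are JIT-compiled with numba; the first call in a
process pays a small compilation cost.

## Probe design

Candidate targets per gene are clustered greedily in length order
(longest first, ties by id): a sequence joins the first cluster whose
representative it matches at ≥95% identity (`shorter` mode), else founds a
new cluster. This reproduces the behaviour of greedy incremental
clusterers: members are guaranteed ≥ threshold identity to their
representative, but representatives of different clusters are *not*
guaranteed mutually below threshold. That asymmetry is documented rather
than "fixed", because panel design only needs a covering set of
representatives.

Representatives are tiled with 120-mer probes stepped by 60 bp (2X
tiling). When `60 ∤ (L − 120)` one extra probe is anchored at `L − 120` so
the 3′ end is covered; the probe count is therefore
`floor((L−120)/60) + 1`, plus one iff the division leaves a remainder.
Sequences under 120 bp are skipped with a warning. Target extraction from
a genome is a local-alignment search accepted at ≥70% column identity and
≥50% reference coverage by default — identity/coverage thresholds stand in
for E-value calibration, which is out of scope.

## Consensus calling

The caller consumes simplified pileups (one quality-labelled base
observation per row) rather than BAMs: read mapping and duplicate marking
sit upstream of this toolkit's scope. Observations need base quality ≥30
*and* mapping quality ≥30 to count. Per position the call is haploid:
depth below 50 → `N`; an exact tie for the majority base → `N` (a haploid
caller should not invent certainty); otherwise the majority base. Raising
the depth threshold can only grow the masked set (tested as a
monotonicity property). Indels are out of scope; coordinates are
reference-ungapped.

Gene annotation locates each reference gene on the consensus by local
alignment, accepted at ≥25% column identity — deliberately permissive
because consensus sequences can be heavily masked. A prior coordinate hint
widens the search window by 100 bp on each side; extraction is always the
alignment footprint itself.

## Reference database and recovery

The database couples a taxonomy table (species, genus, family, order,
class, location per sample) with (sample, gene) sequences over a
configurable panel; the default panel lists 20 chloroplast loci commonly
used as plant barcodes or capture targets (matK, rbcL, trnH-psbA, …) and
is user-overridable everywhere — no logic assumes particular gene names.
On disk: multi-FASTA with `sample|gene` headers plus a TSV; round-trips
are byte-identical.

"Recovered" needs a quantitative definition to be computable: a gene
counts for a sample when a sequence exists *and* ≥50% of its bases are
unambiguous. The threshold is a parameter; lowering it never reduces a
recovery count.

## Leave-one-out evaluation

For each (sample, gene), candidates are all other samples carrying the
gene; the top hit maximises global-alignment column identity, with ties
broken by more matched columns, then lexicographic sample id. Identity is
treated as a symmetric property of the pair (each pair aligned once, in
sorted-id orientation), so results cannot depend on query direction.
Fully masked query sequences are excluded from the evaluated count
(logged): no informative search exists for them.

The query/hit pair is classified at the lowest agreeing rank. Because "%
of samples matched at family level or below across all loci" is ambiguous
between a per-assignment and a per-sample reading, the report emits both:
`pooled_family_or_below` (share of all (sample, gene) assignments — the
headline) and `per_sample_family_or_below` (share of samples whose best
assignment over any locus reaches family or below).

## Distances

Site counting uses pairwise deletion: columns with a gap or `N` in either
sequence are excluded; transitions are A↔G and C↔T. The K2P distance is
`−½ln(1−2P−Q) − ¼ln(1−2Q)` and is reported as undefined (NaN) outside the
formula's domain or with zero comparable sites. Undefined values propagate
explicitly; they are never silently zero. The one exception is the
dendrogram, where undefined entries are imputed as the matrix maximum
(logged) so agglomeration stays defined.

Multi-locus distances exploit an exact identity: since `P` and `Q` are
ratios of pooled counts, the K2P of a concatenated alignment equals the
K2P of the summed per-locus site counts. The toolkit therefore aligns each
shared locus once and pools counts — for the "all genes" baseline profile,
the all-pairs matrix and every prefix of the iterative-concatenation
curves — instead of aligning physical concatenations. The value is
identical under pairwise deletion (missing loci reduce to all-gap blocks,
which deletion removes) and the alignment cost stays linear in the number
of loci. A per-gene pair-statistics cache shares these alignments between
the leave-one-out search and all distance analyses.

The dendrogram uses UPGMA (average linkage) by default, with complete and
single linkage available; branch lengths are ultrametric node heights
(cluster distance / 2). The iterative-concatenation gene order puts the
common barcoding loci first (matK, rbcL, trnH-psbA, in that priority) and
shuffles the remainder deterministically with a user seed; no claim is
made that any particular seed reproduces someone else's unrecorded order.
Comparison groups can be derived from the taxonomy around a baseline
sample (within species / within genus / within family / between family,
capped members per category) or supplied declaratively as YAML for
curated group analyses.

## Synthetic data

The generator emulates the structure the analyses assume:

* **Taxonomy** — a nested five-rank design; counts per rank may be tuples
  cycled across parents, which is how the default "study layout" reaches
  exactly 93 samples (2 classes / 4 orders / 8 families / 16 genera / 31
  species × 3 replicate samples).
* **Sequences** — 20 loci with lengths drawn uniformly from 180–900 bp,
  evolved from uniform-composition roots along a rank-structured
  *ultrametric, star-within-rank* tree under continuous-time K2P
  (transition/transversion rate ratio κ = 2 by default; transition
  probabilities from the matrix exponential of the normalised rate
  matrix). Rank depths are set so the expected pairwise distance of two
  samples equals the configured divergence of their lowest shared rank —
  defaults 0.001 (species), 0.02 (genus), 0.08 (family), 0.15 (order),
  0.25 (class), 0.35 (root) — times a per-gene lognormal rate multiplier
  (σ = 0.3). Star-like rank trees make every comparison category's
  expectation exact, which is what the stratified distance analyses are
  tested against.
* **Dropout** — each (sample, gene) is dropped independently (default
  10%), with a resampling guarantee of ≥1 gene per sample;
  configurations where full dropout is the majority outcome per draw
  (rate^n_genes > 0.5) are rejected outright.
* **Pileups** — depth ~ rounded N(100, 30) truncated at zero, uniform
  0.5% base error, and two-point quality distributions placing ~10% of
  base qualities and ~5% of mapping qualities below the phred-30 filters.
  These defaults mask roughly 5–10% of positions at the depth-50
  threshold: enough to exercise masking and recovery accounting without
  destroying sequences.

Everything derives from `(config, seed)` through per-stage seeded
generators, so studies are reproducible byte for byte.

**What the synthetic studies do not show.** No indels are simulated (so
aligner gap handling is exercised only by dedicated alignment tests, not
by the distance pipeline), base composition is uniform, rates are
homogeneous along branches and across sites, trees are ultrametric, and
dropout is independent of phylogeny and gene. Real capture data violate
all of these; passing pipelines here demonstrate correctness of the
computations under their stated model, not field performance of a real
probe set or database.

## Problem sizes and numerical notes

The shipped end-to-end study runs 93 samples × 20 loci (~4,300 sample
pairs per locus through the alignment cache) — a scale chosen so a full
run, including ~1,700 simulated pileups, completes in a few minutes on one
CPU. Tests use smaller layouts except where the study scale itself is the
property under test. Estimator calibration uses 200 replicate 10 kb pairs
per true distance and checks the mean against three standard errors.
Distances are float64 throughout; exact-equality assertions are reserved
for identities that hold exactly (count pooling, determinism), closed-form
values are checked to 1e−9.

## Known limitations

* Greedy clustering depends on input lengths/ids only through its
  documented sort; it is not an optimal clustering and representatives may
  exceed the threshold pairwise.
* The leave-one-out search ranks by global-alignment identity; results on
  real, structurally variable loci can differ from heuristic local-search
  tools, and the toolkit's claims are about its own defined search.
* The alignment annotation threshold ("similarity") is interpreted as
  alignment-column identity.
* No E-values, no multiple sequence alignment, no ML distances, no
  bootstrap support; the dendrogram is a distance summary, not a
  phylogenetic inference.
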