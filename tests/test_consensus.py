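"""Quality filtering, depth-masked consensus calls, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from plastref.consensus import (
    BaseObservation,
    PileupColumn,
    ConsensusSequence,
    annotate_genes,
    call_consensus,
    consensus_from_frame,
    filter_observations,
    read_pileup,
    write_pileup,
)
from plastref.probes import TargetSequence
from plastref.simulate import (
    PileupConfig,
    SimConfig,
    codes_to_str,
    evolve_sequence,
    random_sequence,
    simulate_pileup,
)


def obs(position, base="A", bq=40, mq=40):
    return BaseObservation(position, base, bq, mq)


class TestFilter:
    def test_quality_29_excluded_30_included(self):
        cols = filter_observations([obs(0, bq=29), obs(0, bq=30), obs(0, mq=29)])
        assert cols[0].depth == 1

    def test_all_high_quality_counted(self):
        cols = filter_observations([obs(0), obs(0), obs(1, "C")])
        assert cols[0].depth == 2 and cols[1].counts == {"C": 1}

    def test_zero_depth_columns_present(self):
        cols = filter_observations([obs(5)], length=8)
        assert len(cols) == 8
        assert cols[3].depth == 0 and cols[5].depth == 1

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            BaseObservation(0, "A", -1, 40)

    def test_depths_match_brute_force_recount(self):
        rng = np.random.default_rng(8)
        observations = [
            BaseObservation(
                int(rng.integers(0, 30)),
                "ACGT"[rng.integers(0, 4)],
                int(rng.integers(0, 60)),
                int(rng.integers(0, 60)),
            )
            for _ in range(500)
        ]
        cols = filter_observations(observations, 30, 30)
        for col in cols:
            manual = sum(
                1
                for o in observations
                if o.position == col.position and o.base_quality >= 30 and o.map_quality >= 30
            )
            assert col.depth == manual


class TestCall:
    def test_depth_threshold_boundary(self):
        col49 = [PileupColumn(0, {"A": 49})]
        col50 = [PileupColumn(0, {"A": 50})]
        assert call_consensus(col49, 1).seq == "N"
        assert call_consensus(col50, 1).seq == "A"

    def test_no_columns_all_n(self):
        assert call_consensus([], 10).seq == "N" * 10

    def test_tie_masked(self):
        cols = [PileupColumn(0, {"A": 30, "G": 30})]
        assert call_consensus(cols, 1).seq == "N"

    def test_majority_base_called(self):
        cols = [PileupColumn(0, {"A": 60, "G": 10})]
        cons = call_consensus(cols, 1)
        assert cons.seq == "A" and not cons.masked_positions

    def test_mask_monotone_in_min_depth(self):
        rng = np.random.default_rng(2)
        cols = [
            PileupColumn(i, {"A": int(rng.integers(0, 120))}) for i in range(200)
        ]
        prev = set()
        for min_depth in (10, 30, 50, 80):
            masked = call_consensus(cols, 200, min_depth=min_depth).masked_positions
            assert prev <= masked
            prev = masked

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(3)
        observations = [
            BaseObservation(int(rng.integers(0, 20)), "ACGT"[rng.integers(0, 4)], 40, 40)
            for _ in range(300)
        ]
        c1 = call_consensus(filter_observations(observations, length=20), 20, min_depth=5)
        shuffled = list(observations)
        rng.shuffle(shuffled)
        c2 = call_consensus(filter_observations(shuffled, length=20), 20, min_depth=5)
        assert c1.seq == c2.seq

    def test_mask_matches_sequence_invariant(self):
        with pytest.raises(ValueError):
            ConsensusSequence("s", "AN", frozenset())


class TestVectorisedEquivalence:
    def test_frame_path_equals_column_path(self):
        cfg = SimConfig(seed=5)
        rng = np.random.default_rng(55)
        true_seq = codes_to_str(random_sequence(150, rng))
        frame = simulate_pileup(true_seq, cfg, rng=rng)
        via_cols = call_consensus(
            filter_observations(frame, length=150), 150, min_depth=50
        )
        via_frame = consensus_from_frame(frame, 150, min_depth=50)
        assert via_cols.seq == via_frame.seq


class TestSimulatedPileups:
    def test_error_free_full_depth_reproduces_truth(self):
        cfg = SimConfig(
            seed=6,
            pileup=PileupConfig(
                mean_depth=100, depth_sd=0, error_rate=0.0,
                base_quality_values=(40,), base_quality_probs=(1.0,),
                map_quality_values=(60,), map_quality_probs=(1.0,),
            ),
        )
        rng = np.random.default_rng(61)
        truth = codes_to_str(random_sequence(500, rng))
        frame = simulate_pileup(truth, cfg, rng=rng)
        assert consensus_from_frame(frame, 500).seq == truth

    def test_one_percent_error_depth_100(self):
        """1% error at depth 100: majority call recovers >=99.9% of 10 kb."""
        cfg = SimConfig(
            seed=7,
            pileup=PileupConfig(
                mean_depth=100, depth_sd=10, error_rate=0.01,
                base_quality_values=(40,), base_quality_probs=(1.0,),
                map_quality_values=(60,), map_quality_probs=(1.0,),
            ),
        )
        rng = np.random.default_rng(71)
        truth = codes_to_str(random_sequence(10_000, rng))
        frame = simulate_pileup(truth, cfg, rng=rng)
        called = consensus_from_frame(frame, 10_000).seq
        correct = sum(1 for a, b in zip(truth, called) if a == b)
        assert correct >= 0.999 * 10_000

    def test_low_depth_mostly_masked(self):
        cfg = SimConfig(
            seed=8,
            pileup=PileupConfig(
                mean_depth=30, depth_sd=10, error_rate=0.0,
                base_quality_values=(40,), base_quality_probs=(1.0,),
                map_quality_values=(60,), map_quality_probs=(1.0,),
            ),
        )
        rng = np.random.default_rng(81)
        truth = codes_to_str(random_sequence(2000, rng))
        frame = simulate_pileup(truth, cfg, rng=rng)
        cons = consensus_from_frame(frame, 2000, min_depth=50)
        assert cons.seq.count("N") >= 1000

    def test_all_low_quality_gives_all_n(self):
        cfg = SimConfig(
            seed=9,
            pileup=PileupConfig(
                mean_depth=100, depth_sd=0, error_rate=0.0,
                base_quality_values=(20,), base_quality_probs=(1.0,),
                map_quality_values=(60,), map_quality_probs=(1.0,),
            ),
        )
        rng = np.random.default_rng(91)
        truth = codes_to_str(random_sequence(100, rng))
        frame = simulate_pileup(truth, cfg, rng=rng)
        assert consensus_from_frame(frame, 100).seq == "N" * 100


class TestAnnotate:
    @staticmethod
    def _consensus_with(seq):
        masked = frozenset(i for i, c in enumerate(seq) if c == "N")
        return ConsensusSequence("samp", seq, masked)

    def test_exact_gene_extracted(self):
        rng = np.random.default_rng(31)
        gene = codes_to_str(random_sequence(200, rng))
        flank_l = codes_to_str(random_sequence(150, rng))
        flank_r = codes_to_str(random_sequence(150, rng))
        cons = self._consensus_with(flank_l + gene + flank_r)
        refs = [TargetSequence("ref", "matK", "tax", gene)]
        out = annotate_genes(cons, refs)
        assert len(out) == 1 and out[0].seq == gene and out[0].gene == "matK"

    def test_fully_masked_gene_absent(self):
        cons = self._consensus_with("N" * 400)
        refs = [TargetSequence("ref", "matK", "tax", "ACGT" * 50)]
        assert annotate_genes(cons, refs) == []

    def test_diverged_gene_footprint(self):
        """5%-diverged copy: recovered footprint spans >=95% of the gene."""
        rng = np.random.default_rng(33)
        gene_codes = random_sequence(300, rng)
        gene = codes_to_str(gene_codes)
        copy = codes_to_str(evolve_sequence(gene_codes, 0.05, 2.0, rng))
        cons = self._consensus_with(
            codes_to_str(random_sequence(120, rng)) + copy + codes_to_str(random_sequence(120, rng))
        )
        out = annotate_genes(cons, [TargetSequence("ref", "rbcL", "tax", gene)])
        assert len(out) == 1
        assert len(out[0].seq) >= 0.95 * 300

    def test_hint_window_restricts_search(self):
        rng = np.random.default_rng(35)
        gene = codes_to_str(random_sequence(150, rng))
        cons_seq = gene + codes_to_str(random_sequence(500, rng))
        cons = self._consensus_with(cons_seq)
        refs = [TargetSequence("ref", "matK", "tax", gene)]
        out = annotate_genes(cons, refs, hints={"matK": (0, 150)}, flank=20)
        assert out[0].seq == gene

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            annotate_genes(self._consensus_with("ACGT"), [])


def test_pileup_tsv_roundtrip(tmp_path):
    cfg = SimConfig(seed=10)
    rng = np.random.default_rng(101)
    frame = simulate_pileup(codes_to_str(random_sequence(40, rng)), cfg, rng=rng)
    path = tmp_path / "pileup.tsv"
    write_pileup(frame, path)
    back = read_pileup(path)
    pd.testing.assert_frame_equal(frame, back)
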