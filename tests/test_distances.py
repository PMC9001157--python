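"""K2P distances, baseline profiles, UPGMA and iterative concatenation."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastref.distances import (
    ComparisonGroup,
    GeneOrder,
    GenePairCache,
    SiteCounts,
    all_genes_matrix,
    baseline_profile,
    comparison_groups_from_taxonomy,
    default_gene_order,
    iterative_concat,
    k2p,
    site_counts,
    upgma_dendrogram,
)
from plastref.refdb import GeneRegionSequence, ReferenceDatabase, TaxonRecord
from plastref.simulate import simulate_diverged_pair
from oracles import hamming_counts


class TestSiteCounts:
    def test_identical(self):
        sc = site_counts("ACGT", "ACGT")
        assert (sc.n_valid, sc.n_transition, sc.n_transversion) == (4, 0, 0)

    def test_gap_and_n_columns_excluded(self):
        sc = site_counts("A-GTN", "ATGTC")
        assert (sc.n_valid, sc.n_transition, sc.n_transversion) == (3, 0, 0)

    def test_transition(self):
        sc = site_counts("AAAA", "GAAA")
        assert (sc.n_valid, sc.n_transition, sc.n_transversion) == (4, 1, 0)

    def test_transversion_pairs(self):
        # A/C, C/A, A/T, C/G all cross the purine/pyrimidine divide
        sc = site_counts("ACAC", "CATG")
        assert sc.n_transversion == 4 and sc.n_transition == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            site_counts("ACG", "AC")

    def test_matches_hand_count_on_random_alignments(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACGTN-"))
        for _ in range(50):
            n = int(rng.integers(1, 120))
            a = "".join(rng.choice(alphabet, n))
            b = "".join(rng.choice(alphabet, n))
            sc = site_counts(a, b)
            assert (sc.n_valid, sc.n_transition, sc.n_transversion) == hamming_counts(a, b)


class TestK2P:
    def test_zero_divergence(self):
        assert k2p(SiteCounts(100, 0, 0)) == 0.0
        assert math.copysign(1.0, k2p(SiteCounts(100, 0, 0))) == 1.0

    def test_closed_form_transitions_only(self):
        # P=0.25, Q=0: d = -1/2 ln(0.5)
        assert k2p(SiteCounts(100, 25, 0)) == pytest.approx(0.34657359, abs=1e-8)

    def test_closed_form_mixed(self):
        # P=0.1, Q=0.1: d = -1/2 ln(0.7) - 1/4 ln(0.8)
        assert k2p(SiteCounts(100, 10, 10)) == pytest.approx(0.23412336, abs=1e-8)

    def test_domain_violation_undefined(self):
        # 1 - 2P - Q = -0.1
        assert math.isnan(k2p(SiteCounts(100, 40, 30)))
        assert math.isnan(k2p(SiteCounts(100, 0, 60)))

    def test_no_comparable_sites_undefined(self):
        assert math.isnan(k2p(SiteCounts(0, 0, 0)))

    @given(
        n=st.integers(10, 10_000),
        ts=st.integers(0, 2000),
        tv=st.integers(0, 2000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_correction_inflates_p_distance(self, n, ts, tv):
        if ts + tv > n:
            return
        d = k2p(SiteCounts(n, ts, tv))
        if not math.isnan(d):
            assert d >= (ts + tv) / n - 1e-12

    def test_symmetric_and_zero_iff_no_differences(self):
        assert k2p(SiteCounts(50, 0, 0)) == 0.0
        assert k2p(SiteCounts(50, 1, 0)) > 0.0
        assert k2p(SiteCounts(50, 0, 1)) > 0.0

    def test_matches_ape_dist_dna(self):
        """Independent oracle: ape's dist.dna(model='K80', pairwise.deletion)."""
        rng = np.random.default_rng(11)
        a, b = simulate_diverged_pair(600, 0.12, 2.0, rng)
        # sprinkle Ns so pairwise deletion is actually exercised
        a = a[:50] + "N" * 5 + a[55:]
        b = b[:300] + "NN" + b[302:]
        script = (
            "suppressMessages(library(ape));"
            f"a <- strsplit('{a.lower()}','')[[1]];"
            f"b <- strsplit('{b.lower()}','')[[1]];"
            "m <- rbind(a,b);"
            "d <- dist.dna(as.DNAbin(m), model='K80', pairwise.deletion=TRUE);"
            "cat(sprintf('%.12f', as.numeric(d)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ours = k2p(site_counts(a, b))
        assert ours == pytest.approx(float(out.stdout), abs=1e-9)


class TestPooling:
    def test_concatenation_equals_pooled_counts(self):
        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACGTN-"))
        for _ in range(30):
            n1, n2 = rng.integers(5, 200, size=2)
            a1, b1 = ("".join(rng.choice(alphabet, n)) for n in (n1, n1))
            a2, b2 = ("".join(rng.choice(alphabet, n)) for n in (n2, n2))
            pooled = site_counts(a1, b1) + site_counts(a2, b2)
            concat = site_counts(a1 + a2, b1 + b2)
            assert pooled == concat
            dp, dc = k2p(pooled), k2p(concat)
            assert dp == dc or (math.isnan(dp) and math.isnan(dc))

    def test_pooled_counts_add(self):
        total = SiteCounts(100, 5, 0) + SiteCounts(100, 0, 10)
        assert (total.n_valid, total.n_transition, total.n_transversion) == (200, 5, 10)
        # pooled closed form: -1/2 ln(1-0.05-0.05) - 1/4 ln(1-0.1)
        #                    = -0.75 ln(0.9) = 0.0790204
        assert k2p(total) == pytest.approx(-0.75 * math.log(0.9), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SiteCounts(10, 8, 8)
        with pytest.raises(ValueError):
            SiteCounts(-1, 0, 0)


def _toy_db():
    """Four samples, two genes, known divergences."""
    taxa = [
        TaxonRecord(f"s{i}", f"sp{i//2}", f"g{i//2}", "f0", "o0", "c0") for i in range(4)
    ]
    db = ReferenceDatabase(taxa=taxa, sequences={}, gene_panel=("g1", "g2"))
    rng = np.random.default_rng(21)
    a1, b1 = simulate_diverged_pair(400, 0.01, 2.0, rng)
    a2, _ = simulate_diverged_pair(300, 0.0, 2.0, rng)
    db.add(GeneRegionSequence("s0", "g1", a1))
    db.add(GeneRegionSequence("s1", "g1", b1))
    db.add(GeneRegionSequence("s0", "g2", a2))
    db.add(GeneRegionSequence("s2", "g1", a1))  # identical to s0 on g1, lacks g2
    db.add(GeneRegionSequence("s3", "g2", a2))  # identical to s0 on g2, lacks g1
    return db


class TestBaselineProfile:
    def test_self_distance_zero(self):
        db = _toy_db()
        prof = baseline_profile(db, "s0", "g1")
        assert prof["s0"] == 0.0

    def test_missing_gene_undefined(self):
        db = _toy_db()
        prof = baseline_profile(db, "s0", "g1")
        assert math.isnan(prof["s3"])

    def test_identical_sample_zero(self):
        db = _toy_db()
        prof = baseline_profile(db, "s0", "g1")
        assert prof["s2"] == 0.0

    def test_all_pools_shared_genes(self):
        db = _toy_db()
        prof = baseline_profile(db, "s0", "all")
        assert prof["s3"] == 0.0  # shares only g2, identical there
        assert prof["s1"] > 0.0

    def test_unknown_baseline_rejected(self):
        with pytest.raises(KeyError):
            baseline_profile(_toy_db(), "nope", "g1")

    def test_baseline_lacking_gene_rejected(self):
        with pytest.raises(ValueError):
            baseline_profile(_toy_db(), "s3", "g1")


class TestUPGMA:
    @staticmethod
    def _parse_heights(newick):
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        return tree

    def test_hand_computed_three_leaf_case(self):
        labels = ["a", "b", "c"]
        mat = pd.DataFrame(
            [[0.0, 0.01, 0.10], [0.01, 0.0, 0.10], [0.10, 0.10, 0.0]],
            index=labels,
            columns=labels,
        )
        nwk = upgma_dendrogram(mat)
        # a,b join first at height 0.005; c attaches at height 0.05
        # (scipy lists the singleton child of the final merge first)
        assert nwk == "(c:0.05,(a:0.005,b:0.005):0.045);"

    def test_identical_samples_star_at_zero(self):
        labels = ["a", "b", "c"]
        mat = pd.DataFrame(np.zeros((3, 3)), index=labels, columns=labels)
        nwk = upgma_dendrogram(mat)
        assert ":0," in nwk.replace(":0.0,", ":0,") or ":0)" in nwk or ":0," in nwk

    def test_all_undefined_rejected(self):
        labels = ["a", "b", "c"]
        vals = np.full((3, 3), np.nan)
        np.fill_diagonal(vals, 0.0)
        with pytest.raises(ValueError):
            upgma_dendrogram(pd.DataFrame(vals, index=labels, columns=labels))

    def test_undefined_imputed_as_max(self):
        labels = ["a", "b", "c"]
        vals = np.array([[0.0, 0.02, np.nan], [0.02, 0.0, 0.3], [np.nan, 0.3, 0.0]])
        nwk = upgma_dendrogram(pd.DataFrame(vals, index=labels, columns=labels))
        assert "a:" in nwk and "c:" in nwk  # agglomeration stayed defined

    def test_unsupported_linkage_rejected(self):
        labels = ["a", "b", "c"]
        mat = pd.DataFrame(np.zeros((3, 3)), index=labels, columns=labels)
        with pytest.raises(ValueError):
            upgma_dendrogram(mat, method="ward")


class TestGeneOrder:
    def test_common_barcodes_lead(self):
        panel = ("ndhC", "rbcL", "atpF", "matK", "psbA")
        order = default_gene_order(panel, seed=4)
        assert order.genes[:2] == ("matK", "rbcL")
        assert sorted(order.genes) == sorted(panel)

    def test_two_gene_panel_fixed(self):
        for seed in (0, 1, 99):
            assert default_gene_order(("matK", "rbcL"), seed).genes == ("matK", "rbcL")

    def test_deterministic_per_seed(self):
        panel = tuple(f"gene{i}" for i in range(20)) + ("matK", "rbcL", "trnH-psbA")
        assert default_gene_order(panel, 7) == default_gene_order(panel, 7)

    def test_different_seeds_share_prefix(self):
        panel = tuple(f"gene{i}" for i in range(20)) + ("matK", "rbcL", "trnH-psbA")
        o1 = default_gene_order(panel, 1)
        o2 = default_gene_order(panel, 2)
        assert o1.genes[:3] == o2.genes[:3] == ("matK", "rbcL", "trnH-psbA")
        assert o1.genes != o2.genes  # 20! tails collide with negligible probability


class TestIterativeConcat:
    ORDER = GeneOrder(("g1", "g2"), seed=0)

    def test_identical_member_zero_for_all_k(self):
        db = _toy_db()
        groups = [ComparisonGroup("ws", "s0", ("s2",), "within species")]
        # s2 lacks g2: the missing block is removed by pairwise deletion, so
        # the distance stays 0 (the shared gene is identical) at every k
        table = iterative_concat(db, self.ORDER, "s0", groups)
        assert (table["distance"] == 0.0).all()

    def test_missing_leading_gene_gives_undefined_then_defined(self):
        db = _toy_db()
        groups = [ComparisonGroup("x", "s0", ("s3",), "between family")]
        # s3 carries only g2: at k=1 (g1 alone) no comparable sites exist
        table = iterative_concat(db, self.ORDER, "s0", groups)
        assert math.isnan(table[table.k == 1].distance.iloc[0])
        assert table[table.k == 2].distance.iloc[0] == 0.0

    def test_pooled_prefix_counts(self):
        db = _toy_db()
        groups = [ComparisonGroup("wg", "s0", ("s1",), "within genus")]
        table = iterative_concat(db, self.ORDER, "s0", groups)
        cache = GenePairCache(db)
        d1 = k2p(cache.get("g1", "s0", "s1").counts)
        assert table[table.k == 1].distance.iloc[0] == pytest.approx(d1)

    def test_absent_member_rejected(self):
        db = _toy_db()
        groups = [ComparisonGroup("x", "s0", ("ghost",), "within genus")]
        with pytest.raises(KeyError):
            iterative_concat(db, self.ORDER, "s0", groups)

    def test_baseline_missing_first_gene_rejected(self):
        db = _toy_db()
        with pytest.raises(ValueError):
            iterative_concat(db, self.ORDER, "s3", [])


class TestComparisonGroups:
    def test_categories_partition_non_baseline_samples(self):
        db = _toy_db()
        groups = comparison_groups_from_taxonomy(db, "s0")
        members = [m for g in groups for m in g.member_samples]
        assert sorted(members) == ["s1", "s2", "s3"]
        by_cat = {g.category: g.member_samples for g in groups}
        assert by_cat["within species"] == ("s1",)

    def test_baseline_not_a_member(self):
        with pytest.raises(ValueError):
            ComparisonGroup("x", "s0", ("s0",), "within species")


def test_all_genes_matrix_symmetric_zero_diagonal():
    db = _toy_db()
    mat = all_genes_matrix(db)
    assert (np.diag(mat) == 0).all()
    arr = mat.to_numpy()
    both = np.isfinite(arr) & np.isfinite(arr.T)
    assert np.allclose(arr[both], arr.T[both])
    # s1/s3 share no gene: undefined
    assert math.isnan(mat.loc["s1", "s3"])
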