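import itertools

import dendropy
import numpy as np
import pytest

from mitoring.divergence import (DistanceMatrix, align_pair,
                                 conserved_positions, count_snps_gaps,
                                 distance_matrix, extract_concatenated_cds,
                                 gap_columns, nj_tree, p_distance)
from mitoring.genome_io import (Annotation, CircularGenome, Interval,
                                reverse_complement_seq, write_newick)
from mitoring.synthetic_data import random_dna


class TestExtractCds:
    def test_alphabetical_order_and_rc(self):
        g2 = "ATGAAATAA"
        g1 = "ATGCATTAA"
        seq = g2 + reverse_complement_seq(g1) + "GGGG"
        g = CircularGenome("g", seq)
        anns = [Annotation("CDS", [Interval(0, 9)], "+", "g2"),
                Annotation("CDS", [Interval(9, 18)], "-", "g1")]
        assert extract_concatenated_cds(g, anns, ["g2", "g1"]) == g1 + g2

    def test_trans_spliced_three_exons(self):
        ex = ["ATGAAA", "CCCGGG", "TTTTAA"]
        spacer = "GGGGGGGGGG"
        seq = ex[0] + spacer + ex[1] + spacer + ex[2]
        g = CircularGenome("g", seq)
        parts = [Interval(0, 6), Interval(16, 22), Interval(32, 38)]
        anns = [Annotation("CDS", parts, "+", "tri")]
        assert extract_concatenated_cds(g, anns, ["tri"]) == "".join(ex)

    def test_missing_gene_errors(self):
        g = CircularGenome("g", "ATGAAATAA")
        anns = [Annotation("CDS", [Interval(0, 9)], "+", "x")]
        with pytest.raises(KeyError, match="nad9"):
            extract_concatenated_cds(g, anns, ["x", "nad9"])


class TestAlign:
    def test_identical(self):
        aln = align_pair("ACGTACGT", "ACGTACGT")
        assert aln.aligned_a == aln.aligned_b
        assert aln.score == 8
        assert count_snps_gaps(aln) == (0, 0)

    def test_hand_verified_gap(self):
        aln = align_pair("ACGTA", "ACTA")
        assert count_snps_gaps(aln) == (0, 1)

    def test_anchored_equals_full_dp(self):
        rng = np.random.default_rng(3)
        a = random_dna(rng, 5_000)
        b = list(a)
        for p in rng.choice(4_900, 50, replace=False):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        # one small deletion too
        del b[2_500:2_503]
        b = "".join(b)
        full = align_pair(a, b, anchored=False)
        anchored = align_pair(a, b, anchored=True)
        assert count_snps_gaps(full) == count_snps_gaps(anchored)

    def test_planted_15_snps(self):
        rng = np.random.default_rng(9)
        a = random_dna(rng, 8_000)
        b = list(a)
        for p in rng.choice(8_000, 15, replace=False):
            b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
        aln = align_pair(a, "".join(b))
        assert count_snps_gaps(aln) == (15, 0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestCounting:
    def test_hand_counted_example(self):
        from mitoring.divergence import PairwiseAlignment
        aln = PairwiseAlignment("a", "b", "ACGTA-CGT", "ACCTAGCGT", 0)
        assert count_snps_gaps(aln) == (1, 1)
        assert gap_columns(aln) == 1

    def test_symmetry(self):
        from mitoring.divergence import PairwiseAlignment
        a, b = "AC-GTAC", "ACCGT-C"
        assert count_snps_gaps(PairwiseAlignment("a", "b", a, b, 0)) == \
            count_snps_gaps(PairwiseAlignment("b", "a", b, a, 0))

    def test_conserved_all_identical(self):
        assert conserved_positions(["ACGTA"] * 3) == (5, 5)

    def test_conserved_two_variable(self):
        assert conserved_positions(["ACGTA", "ACCTA", "ACGTT"]) == (5, 3)

    def test_gap_breaks_conservation(self):
        assert conserved_positions(["ACGTA", "AC-TA"]) == (5, 4)

    def test_ragged_errors(self):
        with pytest.raises(ValueError):
            conserved_positions(["ACGT", "ACG"])


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths; returns
    (taxa, distance matrix, set of non-trivial splits)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [(t,) for t in taxa]
    # build an unrooted binary tree by sequential joining
    tree = dendropy.Tree()
    ns = dendropy.TaxonNamespace(taxa)
    tree.taxon_namespace = ns
    leaves = []
    for t in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        leaves.append(node)
    pool = leaves[:]
    rng_bl = lambda: float(rng.uniform(0.05, 1.0))
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        a, b = pool[j], pool[i]
        parent = dendropy.Node()
        parent.add_child(a); a.edge.length = rng_bl()
        parent.add_child(b); b.edge.length = rng_bl()
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = tree.seed_node
    for p in pool:
        root.add_child(p)
        p.edge.length = rng_bl()
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        t1, t2 = ns.get_taxon(taxa[i]), ns.get_taxon(taxa[j])
        d[i, j] = d[j, i] = pdm.patristic_distance(t1, t2)
    tree.encode_bipartitions()
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition and edge.head_node is not tree.seed_node:
            mask = edge.bipartition.leafset_taxa(ns)
            side = frozenset(t.label for t in mask)
            if 1 < len(side) < n - 1:
                splits.add(min(side, frozenset(taxa) - side,
                               key=lambda s: (len(s), sorted(s))))
    return taxa, d, splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]))
        tree = nj_tree(dm)
        bl = {c.label: l for c, l in tree.root.children}
        assert bl["a"] == pytest.approx(2.0)
        assert bl["b"] == pytest.approx(3.0)
        assert bl["c"] == pytest.approx(7.0)

    def test_five_taxon_additive_exact(self):
        rng = np.random.default_rng(11)
        taxa, d, splits = random_additive_tree(rng, 5)
        tree = nj_tree(DistanceMatrix(taxa, d))
        assert tree.bipartitions() == splits

    def test_additive_recovery_suite(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            taxa, d, splits = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(taxa, d))
            assert tree.bipartitions() == splits

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            taxa, d, _ = random_additive_tree(rng, n)
            # perturb slightly so ties are unlikely but additivity is broken
            noise = rng.normal(0, 0.01, size=d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            dd = np.abs(d + noise)
            dd = (dd + dd.T) / 2
            mine = nj_tree(DistanceMatrix(taxa, dd))
            csv = "," + ",".join(taxa) + "\n"
            for i, t in enumerate(taxa):
                csv += t + "," + ",".join(str(x) for x in dd[i]) + "\n"
            import io
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), delimiter=",")
            ref = pdm.nj_tree()
            ref_splits = set()
            ns = ref.taxon_namespace
            ref.encode_bipartitions()
            nall = frozenset(t.label for t in ns)
            for edge in ref.preorder_edge_iter():
                if edge.bipartition:
                    side = frozenset(t.label for t in
                                     edge.bipartition.leafset_taxa(ns))
                    if 1 < len(side) < len(nall) - 1:
                        ref_splits.add(min(side, nall - side,
                                           key=lambda s: (len(s), sorted(s))))
            assert mine.bipartitions() == ref_splits

    def test_closest_pair_are_neighbors(self):
        # taxon X markedly closest to taxon Y -> they form a cherry
        taxa = ["w", "x", "y", "z"]
        d = np.array([
            [0.00, 0.01, 0.08, 0.09],
            [0.01, 0.00, 0.09, 0.10],
            [0.08, 0.09, 0.00, 0.05],
            [0.09, 0.10, 0.05, 0.00],
        ])
        tree = nj_tree(DistanceMatrix(taxa, d))
        splits = tree.bipartitions()
        pair = frozenset({"w", "x"})
        complement = frozenset(taxa) - pair
        assert pair in splits or complement in splits

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_negative_branch_clamped(self):
        d = np.array([[0, 0.1, 0.4, 0.4],
                      [0.1, 0, 0.4, 0.4],
                      [0.4, 0.4, 0, 0.02],
                      [0.4, 0.4, 0.02, 0.0]])
        tree = nj_tree(DistanceMatrix(list("abcd"), d))
        def all_lengths(node):
            for c, bl in node.children:
                yield bl
                yield from all_lengths(c)
        assert all(bl >= 0 for bl in all_lengths(tree.root))

    def test_newick_roundtrip_through_dendropy(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c", "d"],
                            np.array([[0, 2, 4, 6], [2, 0, 4, 6],
                                      [4, 4, 0, 6], [6, 6, 6, 0.0]]))
        tree = nj_tree(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == \
            ["a", "b", "c", "d"]


class TestDistanceMatrix:
    def test_p_distance_ignores_gap_columns(self):
        assert p_distance("AC-GT", "ACCGA") == pytest.approx(0.25)

    def test_matrix_properties(self):
        seqs = {"a": "ACGTACGT", "b": "ACGTACGA", "c": "ACGAACGA"}
        dm = distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert dm.d[0, 1] == pytest.approx(1 / 8)
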