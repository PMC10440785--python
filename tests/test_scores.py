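import itertools

import numpy as np
import pytest

import lintracer as lt
from lintracer.scores import clustering_info_components

from .oracles import naive_quartet_topology, naive_splits


def panel_trees():
    gt = lt.parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    return {
        "truth": gt,
        "cousins_swapped": lt.parse_newick("(((C,B),(A,D)),((E,F),(G,H)));"),
        "across_clades": lt.parse_newick("(((E,B),(C,D)),((A,F),(G,H)));"),
        "two_sibling_pairs": lt.parse_newick("(((E,F),(C,D)),((A,B),(G,H)));"),
        "cherry_reattached": lt.parse_newick("((G,H),(((A,B),(C,D)),(E,F)));"),
        "star": lt.star_tree(list("ABCDEFGH")),
    }


class TestWorkedEightLeafExample:
    """The panel of deliberately perturbed reconstructions of the balanced
    8-cell colony, with the score values each perturbation should produce."""

    def test_cousin_swap_hits_rf_but_barely_trp(self):
        t = panel_trees()
        assert lt.rf_score(t["truth"], t["cousins_swapped"]) == pytest.approx(0.4)
        assert lt.triplet_score(t["truth"], t["cousins_swapped"]) == pytest.approx(4 / 56)

    def test_across_clade_swap_raises_all_scores(self):
        t = panel_trees()
        vals = lt.score_all(t["truth"], t["across_clades"]).as_dict()
        for v in vals.values():
            assert 0.525 <= v <= 0.6

    def test_two_sibling_pair_swap_relative_changes(self):
        t = panel_trees()
        two = lt.score_all(t["truth"], t["two_sibling_pairs"]).as_dict()
        one = lt.score_all(t["truth"], t["across_clades"]).as_dict()
        assert two["rf"] == pytest.approx(one["rf"] / 3)
        assert two["qrt"] < one["qrt"] / 2 + 0.02
        assert two["trp"] == pytest.approx(one["trp"])

    def test_reattached_cherry_only_visible_to_triplets(self):
        t = panel_trees()
        vals = lt.score_all(t["truth"], t["cherry_reattached"]).as_dict()
        assert vals["trp"] == pytest.approx(16 / 56)
        assert vals["rf"] == 0 and vals["qrt"] == 0 and vals["cli"] == 0

    def test_star_reconstruction_quartet_half(self):
        t = panel_trees()
        assert lt.quartet_score(t["truth"], t["star"]) == pytest.approx(0.5)


class TestScoreProperties:
    @pytest.mark.parametrize("n", [5, 8, 16])
    def test_symmetric_zero_on_identity_and_bounded(self, n):
        rng = np.random.default_rng(n)
        labels = [f"c{i}" for i in range(n)]
        for _ in range(40):
            t1 = lt.random_binary_tree(labels, rng)
            t2 = lt.random_binary_tree(labels, rng)
            for fn in (lt.rf_score, lt.triplet_score, lt.quartet_score,
                       lt.clustering_info_score):
                v12, v21 = fn(t1, t2), fn(t2, t1)
                assert v12 == pytest.approx(v21)
                assert 0.0 <= v12 <= 1.0
                assert fn(t1, t1) == 0.0

    def test_leaf_set_mismatch_rejected(self):
        t1 = lt.parse_newick("((A,B),(C,D));")
        t2 = lt.parse_newick("((A,B),(C,E));")
        for fn in (lt.rf_score, lt.triplet_score, lt.quartet_score,
                   lt.clustering_info_score):
            with pytest.raises(ValueError):
                fn(t1, t2)


class TestRFOracles:
    def test_matches_naive_split_enumeration(self):
        rng = np.random.default_rng(0)
        labels = [f"c{i}" for i in range(8)]
        for _ in range(30):
            t1 = lt.random_binary_tree(labels, rng)
            t2 = lt.random_binary_tree(labels, rng)
            s1, s2 = naive_splits(t1), naive_splits(t2)
            expected = len(s1 ^ s2) / (len(s1) + len(s2))
            assert lt.rf_score(t1, t2) == pytest.approx(expected)

    def test_matches_dendropy_symmetric_difference(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(1)
        labels = [f"c{i}" for i in range(10)]
        for _ in range(20):
            t1 = lt.random_binary_tree(labels, rng)
            t2 = lt.random_binary_tree(labels, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=lt.write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=lt.write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            sym = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert lt.rf_score(t1, t2) == pytest.approx(sym / (2 * (10 - 3)))


class TestQuartetOracle:
    def test_matches_naive_70_subset_enumeration(self):
        rng = np.random.default_rng(2)
        labels = [f"c{i}" for i in range(8)]
        for _ in range(10):
            t1 = lt.random_binary_tree(labels, rng)
            t2 = lt.random_binary_tree(labels, rng)
            d = same = 0
            for quartet in itertools.combinations(labels, 4):
                q1 = naive_quartet_topology(t1, quartet)
                q2 = naive_quartet_topology(t2, quartet)
                if q1 == q2:
                    same += 1
                else:
                    d += 1
            expected = 2 * d / (2 * 70)
            assert lt.quartet_score(t1, t2) == pytest.approx(expected)

    def test_star_counts_all_quartets_resolved_in_one(self):
        t = panel_trees()
        tally = lt.quartet_tally(t["truth"], t["star"])
        assert tally.one_resolved == 70 and tally.total == 70


class TestTripletSubsampling:
    def test_subsample_close_to_exact_on_64_leaves(self):
        rng = np.random.default_rng(3)
        labels = [f"c{i}" for i in range(64)]
        t1 = lt.random_binary_tree(labels, rng)
        t2 = lt.random_binary_tree(labels, rng)
        exact = lt.triplet_score(t1, t2)
        import lintracer.scores as sc

        old = sc.TRIPLET_EXACT_MAX
        sc.TRIPLET_EXACT_MAX = 32  # force the subsampling path
        try:
            approx = lt.triplet_score(t1, t2, rng=np.random.default_rng(4))
        finally:
            sc.TRIPLET_EXACT_MAX = old
        se = np.sqrt(exact * (1 - exact) / sc.SUBSAMPLE_SIZE)
        assert abs(approx - exact) < 3 * se + 1e-9


class TestClusteringInformation:
    def test_matched_information_bounded_by_entropies(self):
        rng = np.random.default_rng(5)
        labels = [f"c{i}" for i in range(12)]
        for _ in range(20):
            t1 = lt.random_binary_tree(labels, rng)
            t2 = lt.random_binary_tree(labels, rng)
            h1, h2, s = clustering_info_components(t1, t2)
            assert s <= min(h1, h2) + 1e-9
            assert s >= 0
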