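import numpy as np
import pytest

import lintracer as lt
from lintracer.model import LevelModel
from lintracer.reconstruct import youden_threshold

from .oracles import isomorphic


class _OracleBooster:
    """Stands in for a trained booster: scores a pair 0.9 when its barcodes
    are identical (all units in a same-state bin) and 0.1 otherwise."""

    def predict(self, X):
        same = X[:, [0, 3, 5]].sum(axis=1)  # F1 + F4 + F6
        total = X.sum(axis=1)
        return np.where(same == total, 0.9, 0.1)


def oracle_model(level=1):
    return LevelModel(
        level=level,
        booster=_OracleBooster(),
        feature_names=["F1", "F2", "F3", "F4", "F5", "F6"],
        n_trees_used=0,
        seed=0,
    )


def matrix(rows):
    return lt.BarcodeMatrix.from_strings(
        sorted(rows), [rows[k] for k in sorted(rows)], lt.Alphabet.mouse_style()
    )


class TestReconstructTree:
    def test_two_cells_give_cherry(self):
        m = matrix({"A": "111", "B": "102"})
        tree = lt.reconstruct_tree(m, {1: oracle_model()}, 0.5)
        assert lt.write_newick(tree) == "(A,B);"

    def test_four_cells_follow_oracle_probabilities(self):
        """p(AB)=p(CD)=0.9 (identical barcodes), cross pairs 0.1: the ranked
        greedy merge with threshold 0.5 must produce ((A,B),(C,D))."""
        m = matrix({"A": "111", "B": "111", "C": "002", "D": "002"})
        tree = lt.reconstruct_tree(m, {1: oracle_model()}, 0.5)
        assert isomorphic(tree, lt.parse_newick("((A,B),(C,D));"))

    def test_structural_contract(self, small_models):
        colony = lt.simulate_colony(
            10, 4, lt.EditModel.uniform(0.15, lt.Alphabet.mouse_style()),
            np.random.default_rng(0),
        )
        tree = lt.reconstruct_tree(colony.barcodes, small_models, 0.5)
        assert tree.is_binary()
        assert sorted(tree.leaf_labels()) == sorted(colony.barcodes.cell_ids)
        assert tree.n_nodes() == 2 * colony.barcodes.n_cells - 1

    def test_deterministic_given_models_and_order(self, small_models):
        colony = lt.simulate_colony(
            10, 4, lt.EditModel.uniform(0.15, lt.Alphabet.mouse_style()),
            np.random.default_rng(1),
        )
        t1 = lt.reconstruct_tree(colony.barcodes, small_models, 0.5)
        t2 = lt.reconstruct_tree(colony.barcodes, small_models, 0.5)
        assert lt.write_newick(t1) == lt.write_newick(t2)

    def test_tie_break_is_lexicographic(self):
        """All pairs identical barcodes -> all probabilities tie; merges must
        follow (min id, max id) order."""
        m = matrix({"A": "11", "B": "11", "C": "11", "D": "11"})
        tree = lt.reconstruct_tree(m, {1: oracle_model()}, 0.5)
        assert lt.write_newick(tree) == "((A,B),(C,D));"

    def test_deadlock_force_merges_best_pair(self):
        """Probabilities all below threshold: assembly must still terminate
        with a binary tree."""
        m = matrix({"A": "111", "B": "102", "C": "020", "D": "200"})
        tree = lt.reconstruct_tree(m, {1: oracle_model()}, 0.99)
        assert tree.is_binary() and tree.n_leaves() == 4

    def test_missing_level1_model_rejected(self):
        m = matrix({"A": "111", "B": "111"})
        with pytest.raises(ValueError, match="level-1"):
            lt.reconstruct_tree(m, {2: oracle_model(2)}, 0.5)

    def test_single_cell_rejected(self):
        m = lt.BarcodeMatrix.from_strings(["A"], ["111"], lt.Alphabet.mouse_style())
        with pytest.raises(ValueError, match="two cells"):
            lt.reconstruct_tree(m, {1: oracle_model()}, 0.5)

    def test_beats_random_trees_end_to_end(self):
        """High-information colonies should be reconstructed much better than
        a random binary tree on the same leaves (margin 0.2 on mean RF)."""
        cfg = lt.SimConfig(
            n_units=40, depth_choices=(4,), mu_choices=(0.2,),
            alphabet=lt.Alphabet.mouse_style(), n_colonies=260,
        )
        rng = np.random.default_rng(21)
        colonies = lt.sample_experiment(cfg, rng)
        models, thresholds, failures = lt.train_pipeline(
            colonies[:200], seed=0, validation=colonies[200:210]
        )
        assert not failures
        rf_ml, rf_rand = [], []
        for colony in colonies[210:260]:
            pred = lt.reconstruct_tree(colony.barcodes, models, thresholds)
            rand = lt.random_binary_tree(colony.barcodes.cell_ids, rng)
            rf_ml.append(lt.rf_score(colony.tree, pred))
            rf_rand.append(lt.rf_score(colony.tree, rand))
        assert np.mean(rf_ml) < np.mean(rf_rand) - 0.2


class TestMergeThresholdTuning:
    def test_empty_validation_defaults_to_half(self):
        assert lt.tune_merge_threshold({1: oracle_model()}, []) == {1: 0.5}

    def test_chosen_cutoff_no_worse_than_half_on_validation(
        self, small_models, shallow_colonies
    ):
        validation = shallow_colonies[150:170]
        thresholds = lt.tune_merge_threshold(small_models, validation)
        usable = [c for c in validation if c.barcodes.n_cells >= 4]

        def mean_rf(th):
            return np.mean(
                [lt.rf_score(c.tree, lt.reconstruct_tree(c.barcodes, small_models, th))
                 for c in usable]
            )

        assert mean_rf(thresholds) <= mean_rf(0.5) + 1e-12


class TestThresholds:
    def test_separable_scores_give_interior_threshold(self):
        scores = np.array([0.9] * 10 + [0.1] * 10)
        labels = np.array([True] * 10 + [False] * 10)
        thr = youden_threshold(scores, labels)
        assert 0.1 < thr < 0.9

    def test_no_validation_defaults_to_half(self):
        models = {1: oracle_model(1), 2: oracle_model(2)}
        assert lt.estimate_level_thresholds(models, None) == {1: 0.5, 2: 0.5}

    def test_youden_at_least_as_good_as_fixed_half(self, small_models, shallow_colonies):
        validation = shallow_colonies[150:]
        thresholds = lt.estimate_level_thresholds(small_models, validation)
        from lintracer.features import all_pair_features, level_pair_labels
        from lintracer.reconstruct import _frame

        for t, model in small_models.items():
            scores, labels = [], []
            for colony in validation:
                pairs, counts = all_pair_features(colony.barcodes)
                probs = lt.predict_pair_probability(
                    model, _frame(counts, model.feature_names)
                )
                positives, _ = level_pair_labels(colony.tree, t)
                scores.append(probs)
                labels.extend(frozenset(p) in positives for p in pairs)
            scores = np.concatenate(scores)
            labels = np.array(labels)

            def j(cut):
                called = scores > cut
                n_pos = labels.sum()
                n_neg = len(labels) - n_pos
                return (called & labels).sum() / n_pos - (called & ~labels).sum() / n_neg

            assert j(thresholds[t]) >= j(0.5) - 1e-12
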