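import numpy as np
import pandas as pd
import pytest

import lintracer as lt
from lintracer.features import feature_names


def toy_table(n=60):
    """Linearly separable: positives have F1=10, negatives F1=0."""
    half = n // 2
    rows = []
    for i in range(n):
        label = i < half
        rows.append(
            {"F1": 10 if label else 0, "F2": 0, "F3": 10 - (10 if label else 0),
             "F4": 0, "F5": 0, "F6": 0, "level": 1, "label": label}
        )
    return pd.DataFrame(rows)


class TestTraining:
    def test_separable_toy_reaches_perfect_training_auc(self):
        table = toy_table()
        model = lt.train_level_model(table, level=1, seed=0)
        probs = lt.predict_pair_probability(model, table)
        pos = probs[table.label.to_numpy()]
        neg = probs[~table.label.to_numpy()]
        assert pos.min() > neg.max()  # AUC = 1.0

    def test_same_seed_identical_predictions(self, shallow_colonies):
        table = lt.build_training_table(shallow_colonies[:40], [1])
        m1 = lt.train_level_model(table, level=1, seed=3)
        m2 = lt.train_level_model(table, level=1, seed=3)
        p1 = lt.predict_pair_probability(m1, table)
        p2 = lt.predict_pair_probability(m2, table)
        assert np.array_equal(p1, p2)

    def test_heldout_auc_above_threshold(self, shallow_colonies, level1_model):
        """On colonies never seen in training, sibling classification must be
        clearly better than chance (AUC > 0.75)."""
        test_table = lt.build_training_table(shallow_colonies[150:], [1])
        probs = lt.predict_pair_probability(level1_model, test_table)
        y = test_table.label.to_numpy()
        order = np.argsort(probs)
        ranks = np.empty(len(probs))
        ranks[order] = np.arange(1, len(probs) + 1)
        n_pos = y.sum()
        auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * (len(y) - n_pos))
        assert auc > 0.75

    def test_single_class_rejected(self):
        table = toy_table()
        table["label"] = True
        with pytest.raises(ValueError, match="single-class"):
            lt.train_level_model(table, level=1, seed=0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            lt.train_level_model(toy_table(6), level=1, seed=0)


class TestPrediction:
    def test_probabilities_in_unit_interval(self, level1_model):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.integers(0, 10, size=(50, 6)), columns=feature_names(lt.Alphabet.mouse_style())
        )
        p = lt.predict_pair_probability(level1_model, X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_identical_barcodes_outrank_disjoint_ones(self, level1_model):
        """Pairs sharing all their (edited) units must score at least as high
        as pairs with no agreement at all."""
        same = {"F1": 2, "F2": 0, "F3": 0, "F4": 4, "F5": 0, "F6": 4}
        diff = {"F1": 0, "F2": 3, "F3": 3, "F4": 0, "F5": 4, "F6": 0}
        p_same = lt.predict_pair_probability(level1_model, same)[0]
        p_diff = lt.predict_pair_probability(level1_model, diff)[0]
        assert p_same >= p_diff

    def test_column_order_irrelevant_when_named(self, level1_model):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.integers(0, 10, size=(20, 6)), columns=level1_model.feature_names
        )
        shuffled = X[list(reversed(X.columns))]
        assert np.array_equal(
            lt.predict_pair_probability(level1_model, X),
            lt.predict_pair_probability(level1_model, shuffled),
        )

    def test_missing_feature_errors(self, level1_model):
        with pytest.raises(ValueError, match="missing feature"):
            lt.predict_pair_probability(level1_model, pd.DataFrame({"F1": [1]}))


class TestInterpretation:
    def test_importance_sums_to_100(self, level1_model, shallow_colonies):
        table = lt.build_training_table(shallow_colonies[:20], [1])
        out = lt.interpret_model(level1_model, table)
        assert sum(out["relative_importance"].values()) == pytest.approx(100.0)
        assert sum(out["gain_importance"].values()) == pytest.approx(100.0)

    def test_all_features_informative_on_three_state_recorder(
        self, level1_model
    ):
        imp = level1_model.booster.feature_importance(importance_type="split")
        assert (imp > 0).all()

    def test_single_feature_model_gets_full_importance(self):
        table = toy_table()
        for c in ("F2", "F3", "F4", "F5", "F6"):
            table[c] = 0
        model = lt.train_level_model(table, level=1, seed=0)
        out = lt.interpret_model(model, table)
        assert out["relative_importance"]["F1"] == pytest.approx(100.0)

    def test_pdp_is_pointwise_mean_of_ice(self, level1_model, shallow_colonies):
        table = lt.build_training_table(shallow_colonies[:10], [1])
        out = lt.interpret_model(level1_model, table)
        for name in level1_model.feature_names:
            assert np.allclose(
                out["pdp"][name]["mean"],
                out["ice"][name]["curves"].mean(axis=0),
                atol=1e-10,
            )

    def test_single_edit_feature_depresses_sibling_probability(
        self, level1_model, shallow_colonies
    ):
        """PDP for F3 (one cell ground, the other inverted) should trend
        downward: mismatched editing argues against siblinghood."""
        from scipy.stats import spearmanr

        table = lt.build_training_table(shallow_colonies[:40], [1])
        out = lt.interpret_model(level1_model, table)
        grid = out["pdp"]["F3"]["grid"]
        mean = out["pdp"]["F3"]["mean"]
        rho = spearmanr(grid, mean).statistic
        assert rho < 0


class TestSerialization:
    def test_save_load_round_trip(self, level1_model, tmp_path):
        level1_model.save(tmp_path)
        again = lt.LevelModel.load(tmp_path, 1)
        X = pd.DataFrame(
            np.random.default_rng(0).integers(0, 10, size=(10, 6)),
            columns=level1_model.feature_names,
        )
        assert np.allclose(
            lt.predict_pair_probability(level1_model, X),
            lt.predict_pair_probability(again, X),
        )
        assert again.n_trees_used == level1_model.n_trees_used
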