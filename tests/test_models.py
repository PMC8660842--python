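"""Random forests, trees, plug-in classifiers, feature selection and
Y-scrambling."""

import numpy as np
import pytest

from photoreact.models import (
    Prediction,
    RFConfig,
    TrainedModel,
    extract_rules,
    oob_permutation_importance,
    predict,
    select_top_k,
    train_cart,
    train_mlp,
    train_rf,
    train_svm,
    y_scramble,
)


class TestRandomForest:
    def test_separable_oob_high(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=200, seed=1))
        assert model.oob_accuracy >= 0.95

    def test_scrambled_labels_chance_level(self, separable_xy):
        X, y = separable_xy
        rng = np.random.default_rng(3)
        model = train_rf(X, y[rng.permutation(len(y))], RFConfig(n_trees=200, seed=1))
        assert 0.40 <= model.oob_accuracy <= 0.60

    def test_single_tree_degenerate_forest(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=1, seed=0))
        preds = predict(model, X[:5])
        assert len(preds) == 5

    def test_single_class_errors(self, separable_xy):
        X, _ = separable_xy
        with pytest.raises(ValueError):
            train_rf(X, np.repeat("POS", len(X)), RFConfig(n_trees=10))

    def test_oob_not_above_self_consistency(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=100, seed=2))
        self_acc = np.mean([p.predicted for p in predict(model, X)] == y)
        assert model.oob_accuracy <= self_acc + 1e-12

    def test_seeded_determinism(self, separable_xy):
        X, y = separable_xy
        p1 = predict(train_rf(X, y, RFConfig(n_trees=50, seed=9)), X)
        p2 = predict(train_rf(X, y, RFConfig(n_trees=50, seed=9)), X)
        assert p1 == p2

    def test_mtry_third(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=20, mtry="third", seed=0))
        assert model.config["mtry"] == "third"


class _FixedProba:
    """Stub estimator with controllable POS vote fractions."""

    classes_ = np.array(["NEG", "POS"])

    def __init__(self, p_pos):
        self.p_pos = np.asarray(p_pos)

    def predict_proba(self, X):
        return np.column_stack([1 - self.p_pos, self.p_pos])


class TestPredict:
    def _model(self, p_pos, n_features=3):
        return TrainedModel("rf", _FixedProba(p_pos), {}, [f"f{i}" for i in range(n_features)])

    def test_probability_is_vote_fraction_of_predicted(self):
        preds = predict(self._model([1.0, 0.2]), np.zeros((2, 3)))
        assert preds[0].predicted == "POS" and preds[0].probability == 1.0
        assert preds[1].predicted == "NEG" and preds[1].probability == 0.8

    def test_exact_tie_goes_pos(self):
        (p,) = predict(self._model([0.5]), np.zeros((1, 3)))
        assert p.predicted == "POS" and p.probability == 0.5

    def test_column_mismatch_errors(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=10, seed=0))
        with pytest.raises(ValueError, match="features"):
            predict(model, X[:, :5])

    def test_training_self_consistency(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=200, seed=4))
        agreement = np.mean([p.predicted for p in predict(model, X)] == y)
        assert agreement >= 0.95


class TestFeatureSelection:
    def test_informative_columns_selected_across_seeds(self, separable_xy):
        X, y = separable_xy
        for seed in range(5):
            model = train_rf(X, y, RFConfig(n_trees=60, seed=seed), compute_mda=True)
            top = set(select_top_k(model, 2))
            assert top == {3, 7}

    def test_mda_positive_for_informative(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=60, seed=0))
        mda = oob_permutation_importance(model, X, y, seed=0)
        assert mda[3] > max(mda[i] for i in range(12) if i not in (3, 7))

    def test_k_bounds(self, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=10, seed=0))
        with pytest.raises(ValueError):
            select_top_k(model, 0)
        with pytest.raises(ValueError):
            select_top_k(model, 13)
        assert select_top_k(model, 12) == list(range(12))

    def test_tie_break_by_lower_index(self):
        model = TrainedModel("rf", None, {}, ["a", "b", "c"], importances_mda=np.array([0.5, 0.5, 0.5]))
        assert select_top_k(model, 2) == [0, 1]


class TestCart:
    def test_perfect_bit_yields_depth_one_tree(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(200, 6)).astype(float)
        y = np.where(X[:, 2] > 0.5, "POS", "NEG")
        model = train_cart(X, y, cp=0.01, seed=0)
        assert model.estimator.get_depth() == 1
        assert model.estimator.tree_.feature[0] == 2

    def test_rules_reference_split_feature(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(120, 4)).astype(float)
        y = np.where(X[:, 1] > 0.5, "POS", "NEG")
        model = train_cart(X, y, seed=0)
        rules = extract_rules(model)
        assert any(cond[0] == "f1" for rule in rules for cond in rule.conditions)
        assert {r.predicted for r in rules} == {"POS", "NEG"}

    def test_huge_cp_gives_single_leaf(self, separable_xy):
        X, y = separable_xy
        model = train_cart(X, y, cp=10.0, seed=0)
        assert model.estimator.get_n_leaves() == 1

    def test_single_class_warns_not_errors(self):
        X = np.zeros((5, 2))
        with pytest.warns(UserWarning):
            model = train_cart(X, np.repeat("NEG", 5))
        assert model.estimator.get_n_leaves() == 1


class TestYScramble:
    def test_chance_level_and_determinism(self, separable_xy):
        X, y = separable_xy
        accs = y_scramble(X, y, RFConfig(n_trees=50), n_rounds=5, seed=11)
        assert len(accs) == 5
        assert all(0.35 <= a <= 0.65 for a in accs)
        assert accs == y_scramble(X, y, RFConfig(n_trees=50), n_rounds=5, seed=11)

    def test_single_round(self, separable_xy):
        X, y = separable_xy
        assert len(y_scramble(X, y, RFConfig(n_trees=20), n_rounds=1, seed=0)) == 1

    def test_invalid_rounds(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(ValueError):
            y_scramble(X, y, n_rounds=0, seed=0)


class TestPlugins:
    def test_svm_separable_and_provenance(self, separable_xy):
        X, y = separable_xy
        model = train_svm(X, y)
        acc = np.mean(model.estimator.predict(X) == y)
        assert acc >= 0.95
        assert model.config["C"] == 500.0 and model.config["gamma"] == 0.004
        with pytest.raises(ValueError):
            train_svm(X, np.repeat("POS", len(X)))

    def test_mlp_architecture_and_learning(self, separable_xy):
        X, y = separable_xy
        model = train_mlp(X, y, seed=0)
        assert model.config["hidden_layers"] == (250, 250, 8, 4)
        assert model.config["epochs"] == 100
        assert model.config["output_activation"] == "sigmoid"
        proba = model.estimator.predict_proba(X)
        assert np.all((proba >= 0) & (proba <= 1))
        assert np.mean(model.estimator.predict(X) == y) >= 0.9


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, separable_xy):
        X, y = separable_xy
        model = train_rf(X, y, RFConfig(n_trees=20, seed=0))
        model.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        assert predict(back, X[:10]) == predict(model, X[:10])
        assert back.config == model.config
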