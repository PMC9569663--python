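import numpy as np
import pandas as pd
import pytest

from kinogen.likelihood import (
    ClassifierSpec,
    ConfusionMatrix,
    auc_pairwise,
    binary_metrics,
    build_training_table,
    evaluate,
    predict_likelihood,
    split_table,
    train,
)
from kinogen.molecules import Family
from kinogen.synthetic_data import make_labeled_table


class TestBuildTrainingTable:
    def test_binary_targets_and_counts(self, scaffold_library):
        fams = list(scaffold_library)
        sets = {
            Family.SRC: scaffold_library[fams[0]][:10],
            Family.ABL1: scaffold_library[fams[1]][:10],
            Family.BACKGROUND: scaffold_library[fams[2]][:10],
        }
        spec = ClassifierSpec(mode="binary", space="feature")
        table = build_training_table(sets, spec)
        assert len(table) == 30
        assert table["target"].sum() == 10
        assert table.shape[1] == 21  # 20 descriptors + target

    def test_multiclass_distinct_codes(self, scaffold_library):
        spec = ClassifierSpec(mode="multiclass", space="feature")
        table = build_training_table(scaffold_library, spec)
        assert table["target"].nunique() == len(scaffold_library)

    def test_latent_space_has_d_plus_one_columns(self, scaffold_library, surrogate):
        spec = ClassifierSpec(mode="binary", space="latent", positive_class=Family.SRC)
        latents = {fam: surrogate.encode(recs) for fam, recs in scaffold_library.items()}
        table = build_training_table(scaffold_library, spec, latents=latents)
        assert table.shape[1] == 197  # 196 latent coordinates + target

    def test_empty_family_fatal(self):
        spec = ClassifierSpec()
        with pytest.raises(ValueError, match="zero members"):
            build_training_table({Family.SRC: []}, spec)


class TestTrain:
    def test_perfectly_separable_predictor(self):
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 5))
        X[:, 2] = y  # one predictor equals the target
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        table["target"] = y
        tr, te = split_table(table, seed=0)
        model = train(tr, ClassifierSpec(n_trees=100))
        report = evaluate(model, te)
        assert report.accuracy == 1.0

    def test_pure_noise_near_chance(self):
        table = make_labeled_table(n_per_class=1000, n_features=10, effect_size=0.0, seed=1)
        tr, te = split_table(table, seed=1)
        model = train(tr, ClassifierSpec(n_trees=100, seed=1))
        report = evaluate(model, te)
        assert abs(report.accuracy - 0.5) < 0.06

    def test_seeded_determinism(self):
        table = make_labeled_table(n_per_class=100, effect_size=1.0, seed=2)
        tr, te = split_table(table, seed=2)
        X_te = te.drop(columns="target").to_numpy()
        p1 = predict_likelihood(train(tr, ClassifierSpec(n_trees=50, seed=9)), X_te)
        p2 = predict_likelihood(train(tr, ClassifierSpec(n_trees=50, seed=9)), X_te)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_fatal(self):
        table = pd.DataFrame({"f0": [1.0, 2.0], "target": [1, 1]})
        with pytest.raises(ValueError):
            train(table, ClassifierSpec())


@pytest.fixture(scope="module")
def separable_model():
    table = make_labeled_table(n_per_class=300, n_features=6, effect_size=6.0, seed=3)
    tr, te = split_table(table, seed=3)
    return train(tr, ClassifierSpec(n_trees=200, seed=3)), te


class TestPredictLikelihood:
    def test_probabilities_in_unit_interval(self, separable_model):
        model, te = separable_model
        p = predict_likelihood(model, te.drop(columns="target").to_numpy())
        assert np.all((p >= 0) & (p <= 1))

    def test_deep_positive_and_negative_regions(self, separable_model):
        model, _ = separable_model
        deep_pos = np.array([[6.0, 0, 0, 0, 0, 0]])  # at the positive-class mean
        deep_neg = np.zeros((1, 6))
        assert predict_likelihood(model, deep_pos)[0] > 0.9
        assert predict_likelihood(model, deep_neg)[0] < 0.1

    def test_dimension_mismatch_fatal(self, separable_model):
        model, _ = separable_model
        with pytest.raises(ValueError, match="dimensionality"):
            predict_likelihood(model, np.zeros((1, 9)))


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        m = binary_metrics(ConfusionMatrix(tp=50, fp=10, fn=5, tn=35))
        assert m["accuracy"] == pytest.approx(0.85, abs=1e-12)
        assert m["precision"] == pytest.approx(50 / 60, abs=1e-12)
        assert m["recall"] == pytest.approx(50 / 55, abs=1e-12)
        assert m["f1"] == pytest.approx(2 * (50 / 60) * (50 / 55) / (50 / 60 + 50 / 55), abs=1e-12)

    def test_undefined_precision_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = binary_metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(m["precision"])

    def test_perfect_predictions(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        table = pd.DataFrame({"f0": y.astype(float), "target": y})
        model = train(table, ClassifierSpec(n_trees=20, seed=0))
        report = evaluate(model, table)
        assert report.accuracy == report.precision == report.recall == report.f1 == 1.0
        assert report.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(6)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert auc_pairwise(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_trapezoidal_auc_equals_pairwise_oracle(self):
        """AUC must equal the probability a random positive outscores a
        random negative, including with heavily tied forest scores."""
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 150
            labels = rng.integers(0, 2, n)
            while labels.sum() in (0, n):
                labels = rng.integers(0, 2, n)
            scores = np.round(rng.random(n) * 0.4 + labels * 0.3, 2)  # many ties
            fpr, tpr, _ = roc_curve(labels, scores)
            assert abs(sk_auc(fpr, tpr) - auc_pairwise(scores, labels)) < 1e-12


class TestFeatureImportance:
    def test_single_signal_feature_ranks_first(self):
        table = make_labeled_table(
            n_per_class=200, n_features=8, signal_columns=(3,), effect_size=10.0, seed=8
        )
        tr, te = split_table(table, seed=8)
        model = train(tr, ClassifierSpec(n_trees=200, seed=8))
        report = evaluate(model, te)
        assert report.feature_importances[0][0] == "f3"
        weights = np.array([w for _, w in report.feature_importances])
        assert np.all(weights >= 0)
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_feature_space_beats_noise_latents(self, scaffold_library, surrogate):
        """When descriptors separate the classes but latent coordinates are
        pure noise, the feature-space binary model must reach the higher F1."""
        fams = list(scaffold_library)
        sets = {fams[0]: scaffold_library[fams[0]], fams[1]: scaffold_library[fams[1]]}
        fspec = ClassifierSpec(mode="binary", space="feature", positive_class=fams[0], n_trees=200)
        ftable = build_training_table(sets, fspec)
        rng = np.random.default_rng(0)
        noise_latents = {fam: rng.standard_normal((len(recs), 196)) for fam, recs in sets.items()}
        lspec = ClassifierSpec(mode="binary", space="latent", positive_class=fams[0], n_trees=200)
        ltable = build_training_table(sets, lspec, latents=noise_latents)
        f_tr, f_te = split_table(ftable, seed=0)
        l_tr, l_te = split_table(ltable, seed=0)
        f_report = evaluate(train(f_tr, fspec), f_te)
        l_report = evaluate(train(l_tr, lspec), l_te)
        f1_latent = 0.0 if np.isnan(l_report.f1) else l_report.f1
        assert f_report.f1 > f1_latent
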