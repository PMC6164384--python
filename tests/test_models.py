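import numpy as np
import pytest

from nmrqsar.metrics import ConfusionCounts, accuracy_q, sensitivity
from nmrqsar.models import (
    DEFAULT_C_GRID,
    ModelError,
    ModelSpec,
    cross_validate,
    fit,
    oob_permutation_importance,
    predict,
    predict_proba,
    rebalance_weights,
    tune_c,
)


@pytest.fixture(scope="module")
def labeled_blobs(blob_data):
    X, labels = blob_data
    y = np.where(labels == 0, "active", "inactive")
    return X, y


class TestFit:
    def test_rf_oob_accuracy_on_separable_blobs(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("rf", "classification", n_trees=200, seed=1), X, y)
        cm = ConfusionCounts.from_labels(y, model.oob_predictions, "active")
        assert accuracy_q(cm) > 0.95

    def test_rf_determinism(self, labeled_blobs):
        X, y = labeled_blobs
        m1 = fit(ModelSpec("rf", "classification", n_trees=50, seed=3), X, y)
        m2 = fit(ModelSpec("rf", "classification", n_trees=50, seed=3), X, y)
        assert np.array_equal(m1.oob_probabilities, m2.oob_probabilities)

    def test_knn_zero_distance_short_circuit(self, blob_data):
        X, _ = blob_data
        y = np.arange(float(X.shape[0]))
        model = fit(ModelSpec("knn", "regression", k=10), X, y)
        assert predict(model, X[7:8])[0] == pytest.approx(7.0)

    def test_svm_training_accuracy(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("svm", "classification", C=10.0, seed=1), X, y)
        assert (predict(model, X) == y).mean() > 0.95

    def test_single_class_rejected(self, blob_data):
        X, _ = blob_data
        with pytest.raises(ModelError):
            fit(ModelSpec("rf", "classification", seed=0), X, np.zeros(X.shape[0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ModelError):
            fit(ModelSpec("knn", "regression"), np.zeros((1, 2)), np.zeros(1))

    def test_non_finite_rejected(self, blob_data):
        X, _ = blob_data
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ModelError):
            fit(ModelSpec("knn", "regression"), X, np.arange(float(X.shape[0])))


class TestPredict:
    def test_probabilities_sum_to_one(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("rf", "classification", n_trees=50, seed=2), X, y)
        proba = predict_proba(model, X[:10])
        assert proba.shape == (10, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert ((0.0 <= proba) & (proba <= 1.0)).all()

    def test_unanimous_vote_probability_one(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("rf", "classification", n_trees=50, seed=2), X, y)
        p_active = predict_proba(model, X[:1], positive="active")
        assert p_active[0] == pytest.approx(1.0)

    def test_knn_equidistant_unweighted_mean(self):
        # 10 training points on a unit circle, query at the center
        theta = np.linspace(0.0, 2 * np.pi, 10, endpoint=False)
        X = np.column_stack([np.cos(theta), np.sin(theta)])
        y = np.arange(10.0)
        model = fit(ModelSpec("knn", "regression", k=10), X, y)
        assert predict(model, np.zeros((1, 2)))[0] == pytest.approx(y.mean())

    def test_knn_duplicated_training_set(self, blob_data):
        """Doubling every training point (and k with it) leaves the
        inverse-distance-weighted prediction unchanged."""
        X, _ = blob_data
        rng = np.random.default_rng(0)
        y = rng.normal(size=X.shape[0])
        m1 = fit(ModelSpec("knn", "regression", k=5), X, y)
        m2 = fit(ModelSpec("knn", "regression", k=10),
                 np.vstack([X, X]), np.concatenate([y, y]))
        queries = rng.normal(5.0, 3.0, size=(20, X.shape[1]))
        assert np.allclose(predict(m1, queries), predict(m2, queries))

    def test_dimension_mismatch(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("knn", "classification"), X, y)
        with pytest.raises(ModelError):
            predict(model, np.zeros((2, 3)))


class TestRebalanceWeights:
    def test_published_training_counts(self):
        # 25 actives vs 49 inactives -> weight ratio 49:25
        w = rebalance_weights({"active": 25, "inactive": 49})
        assert w["active"] / w["inactive"] == pytest.approx(49 / 25)

    def test_balanced_counts_equal_weights(self):
        w = rebalance_weights({"a": 10, "b": 10})
        assert w["a"] == pytest.approx(w["b"])

    def test_equal_total_mass_per_class(self):
        counts = {"a": 7, "b": 31, "c": 12}
        w = rebalance_weights(counts)
        masses = {k: w[k] * counts[k] for k in counts}
        assert len({round(m, 9) for m in masses.values()}) == 1

    def test_empty_class_rejected(self):
        with pytest.raises(ModelError):
            rebalance_weights({"a": 0, "b": 5})

    def test_rebalancing_raises_sensitivity_on_imbalanced_data(self):
        """2:1 imbalance with a weak signal: 50:50 class weights must not
        hurt, and typically raise, the minority-class sensitivity."""
        from nmrqsar.binning import build_matrix
        from nmrqsar.simulate import SpectraSimConfig, gen_spectra, default_schemes

        cfg = SpectraSimConfig(
            n_active=40, n_inactive=80,
            p_informative_active=0.55, p_informative_inactive=0.2, seed=12,
        )
        peaklists, labels = gen_spectra(cfg)
        scheme_h, scheme_c = default_schemes()
        X = build_matrix(peaklists, scheme_h, scheme_c).values
        y = np.array(labels)
        pos = "moderate-active-to-active"

        plain = fit(ModelSpec("rf", "classification", n_trees=300, seed=12), X, y)
        weights = rebalance_weights({pos: 40, "inactive": 80})
        weighted = fit(
            ModelSpec("rf", "classification", n_trees=300,
                      class_weights=weights, seed=12),
            X, y,
        )
        se_plain = sensitivity(ConfusionCounts.from_labels(y, plain.oob_predictions, pos))
        se_weighted = sensitivity(
            ConfusionCounts.from_labels(y, weighted.oob_predictions, pos)
        )
        assert se_weighted > se_plain


class TestImportances:
    def test_planted_descriptors_beat_noise_quantile(self, labeled_blobs):
        rng = np.random.default_rng(8)
        n = 150
        informative = rng.standard_normal((n, 4))
        y = np.where(informative.sum(axis=1) > 0, "a", "b")
        X = np.column_stack([informative, rng.standard_normal((n, 40))])
        model = fit(ModelSpec("rf", "classification", n_trees=300, seed=8), X, y)
        imp = model.importances(kind="permutation")
        noise_q95 = np.quantile(imp[4:], 0.95)
        assert (imp[:4] > noise_q95).all()

    def test_impurity_importances_normalized(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("rf", "classification", n_trees=50, seed=2), X, y)
        imp = model.importances(kind="impurity")
        assert imp.shape == (X.shape[1],)
        assert imp.sum() == pytest.approx(1.0)

    def test_importances_only_for_rf(self, labeled_blobs):
        X, y = labeled_blobs
        model = fit(ModelSpec("knn", "classification"), X, y)
        with pytest.raises(ModelError):
            model.importances()

    def test_oob_permutation_regression(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 10))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.3, 120)
        model = fit(ModelSpec("rf", "regression", n_trees=150, seed=5), X, y)
        imp = oob_permutation_importance(model)
        assert imp[0] > imp[1:].max()


class TestCrossValidate:
    def test_perfect_signal_pooled_accuracy(self, labeled_blobs):
        X, y = labeled_blobs
        report = cross_validate(
            ModelSpec("knn", "classification", k=3), X, y, folds=10, seed=0,
            positive="active",
        )
        assert report.pooled["raw"]["q"] == pytest.approx(1.0)

    def test_fold_sizes_within_one(self, labeled_blobs):
        from sklearn.model_selection import StratifiedKFold

        X, y = labeled_blobs
        sizes = [len(t) for _, t in
                 StratifiedKFold(10, shuffle=True, random_state=0).split(X, y)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, labeled_blobs):
        X, y = labeled_blobs
        r1 = cross_validate(ModelSpec("knn", "classification"), X, y, folds=5,
                            seed=4, positive="active")
        r2 = cross_validate(ModelSpec("knn", "classification"), X, y, folds=5,
                            seed=4, positive="active")
        assert r1.pooled["raw"] == r2.pooled["raw"]

    def test_cv_rmse_close_to_oob_rmse(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 12))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.4, 150)
        spec = ModelSpec("rf", "regression", n_trees=150, seed=6)
        model = fit(spec, X, y)
        from nmrqsar.metrics import regression_report

        oob_rmse = regression_report(y, model.oob_predictions).rmse
        cv = cross_validate(spec, X, y, folds=10, seed=6)
        cv_rmse = cv.pooled["report"].rmse
        assert abs(cv_rmse - oob_rmse) < 0.25 * oob_rmse

    def test_too_few_folds_rejected(self, labeled_blobs):
        X, y = labeled_blobs
        with pytest.raises(ModelError):
            cross_validate(ModelSpec("knn", "classification"), X, y, folds=1, seed=0)


class TestTuneC:
    def test_single_point_grid(self, labeled_blobs):
        X, y = labeled_blobs
        spec = ModelSpec("svm", "classification", seed=0)
        best, scores = tune_c(spec, X, y, grid=[50.0], folds=5, seed=0,
                              positive="active")
        assert best == 50.0
        assert set(scores) == {50.0}

    def test_ties_go_to_smallest_c(self, labeled_blobs):
        # blobs are trivially separable, so every C scores 1.0
        X, y = labeled_blobs
        spec = ModelSpec("svm", "classification", seed=0)
        best, scores = tune_c(spec, X, y, grid=[10.0, 100.0, 1000.0], folds=5,
                              seed=0, positive="active")
        assert len(set(scores.values())) == 1
        assert best == 10.0

    def test_deterministic(self, labeled_blobs):
        X, y = labeled_blobs
        spec = ModelSpec("svm", "classification", seed=0)
        a = tune_c(spec, X, y, grid=[10.0, 100.0], folds=5, seed=1, positive="active")
        b = tune_c(spec, X, y, grid=[10.0, 100.0], folds=5, seed=1, positive="active")
        assert a == b

    def test_empty_grid_rejected(self, labeled_blobs):
        X, y = labeled_blobs
        with pytest.raises(ModelError):
            tune_c(ModelSpec("svm", "classification"), X, y, grid=[], folds=5, seed=0)

    def test_default_grid_spans_range(self):
        assert min(DEFAULT_C_GRID) == 10.0
        assert max(DEFAULT_C_GRID) == 1000.0

    def test_non_svm_rejected(self, labeled_blobs):
        X, y = labeled_blobs
        with pytest.raises(ModelError):
            tune_c(ModelSpec("rf", "classification"), X, y, folds=5, seed=0)
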