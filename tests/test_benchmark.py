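"""ML benchmark harness: splitting, suites, embeddings, chaining and
feature attribution."""

import numpy as np
import pandas as pd
import pytest

from otterlab.benchmark import (
    CLASSIFIER_NAMES,
    REGRESSOR_NAMES,
    SplitSpec,
    embed,
    feature_importance,
    make_classifier,
    make_regressor,
    make_split,
    pca_then_classify,
    run_classification_suite,
    run_regression_suite,
)
from otterlab.datasets import (
    AcquisitionConfig,
    ClassificationSpec,
    Dataset,
    RegressionSpec,
    generate_classification_dataset,
    generate_regression_dataset,
)


def _toy_dataset(X, y_frame):
    grid = np.arange(X.shape[1], dtype=float)
    truth = pd.DataFrame(index=range(X.shape[0])).assign(dummy=0.0)
    return Dataset(signals=X, grid=grid, labels=y_frame, truth=truth)


class TestMakeSplit:
    def test_97_rows_split_73_24(self):
        tr, te = make_split(97, SplitSpec(train_fraction=0.75, seed=0))
        assert len(tr) == 73 and len(te) == 24
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 97

    def test_stratified_small_classes_hit_both_partitions(self):
        labels = np.repeat([0, 1, 2, 3], 5)
        tr, te = make_split(20, SplitSpec(seed=1, stratify=True), labels=labels)
        for c in range(4):
            assert c in labels[tr] and c in labels[te]
        assert len(tr) == 15 and len(te) == 5

    def test_same_seed_reproduces(self):
        a = make_split(50, SplitSpec(seed=7))
        b = make_split(50, SplitSpec(seed=7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_singleton_class_cannot_stratify(self):
        labels = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="stratification"):
            make_split(10, SplitSpec(stratify=True), labels=labels)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestRegressionSuite:
    def test_realizable_linear_target_is_fit_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        y = 2.0 * X[:, 0] - 0.5 * X[:, 3]
        ds = _toy_dataset(X, pd.DataFrame({"y": y}))
        rep = run_regression_suite(ds, SplitSpec(seed=0), models=["linear"])
        e = rep["linear"]
        assert e.train_r2 == pytest.approx(1.0, abs=1e-10)
        assert e.test_r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_target_convention(self):
        # R^2 is defined as 0 for a constant target; the fitted constant
        # predictor has zero RMSE
        X = np.random.default_rng(1).normal(size=(24, 4))
        ds = _toy_dataset(X, pd.DataFrame({"y": np.full(24, 3.0)}))
        rep = run_regression_suite(ds, SplitSpec(seed=0), models=["linear"])
        e = rep["linear"]
        assert e.train_r2 == 0.0 and e.test_r2 == 0.0
        assert e.test_rmse == pytest.approx(0.0, abs=1e-8)

    def test_unknown_model_name_is_registry_error(self):
        ds = _toy_dataset(np.zeros((8, 3)), pd.DataFrame({"y": np.arange(8.0)}))
        with pytest.raises(KeyError, match="unknown regressor"):
            run_regression_suite(ds, models=["linear", "perceptronx"])

    def test_model_failure_is_recorded_not_raised(self):
        ds = _toy_dataset(
            np.random.default_rng(0).normal(size=(20, 3)),
            pd.DataFrame({"y": np.arange(20.0)}),
        )
        rep = run_regression_suite(
            ds, SplitSpec(seed=0), models=["knn"], overrides={"knn": {"n_neighbors": 999}}
        )
        assert rep["knn"].error is not None
        assert np.isnan(rep["knn"].test_r2)

    def test_every_registry_model_appears_once(self):
        ds = generate_regression_dataset(RegressionSpec(n_signals=24), AcquisitionConfig(n_points=64), seed=0)
        rep = run_regression_suite(ds, SplitSpec(seed=0))
        assert [e.name for e in rep.entries] == list(REGRESSOR_NAMES)

    def test_training_metrics_ignore_test_rows(self):
        # corrupting the test rows must not change any training prediction
        ds = generate_regression_dataset(RegressionSpec(n_signals=24), AcquisitionConfig(n_points=32), seed=2)
        split = SplitSpec(seed=5)
        rep1 = run_regression_suite(ds, split, models=["linear", "random_forest"])
        corrupted = Dataset(
            signals=ds.signals.copy(), grid=ds.grid, labels=ds.labels.copy(), truth=ds.truth.copy()
        )
        corrupted.signals[rep1.test_idx] += 100.0
        rep2 = run_regression_suite(corrupted, split, models=["linear", "random_forest"])
        for name in ("linear", "random_forest"):
            assert rep1[name].train_r2 == rep2[name].train_r2
            assert rep1[name].train_rmse == rep2[name].train_rmse

    def test_multi_target_labels_supported(self):
        spec = RegressionSpec(n_signals=24, mode="gradient")
        ds = generate_regression_dataset(spec, AcquisitionConfig(n_points=64), seed=0)
        rep = run_regression_suite(ds, SplitSpec(seed=0), models=["linear", "svm"])
        assert rep["linear"].error is None and rep["svm"].error is None

    def test_report_determinism(self):
        ds = generate_regression_dataset(RegressionSpec(n_signals=24), AcquisitionConfig(n_points=64), seed=1)
        a = run_regression_suite(ds, SplitSpec(seed=3), models=["random_forest", "deep_learning"])
        b = run_regression_suite(ds, SplitSpec(seed=3), models=["random_forest", "deep_learning"])
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


class TestClassificationSuite:
    def test_constant_distinct_classes_are_trivially_separable(self):
        X = np.vstack([np.zeros((5, 4)), np.ones((5, 4))])
        ds = _toy_dataset(X, pd.DataFrame({"subject": [1] * 5 + [2] * 5}))
        rep = run_classification_suite(ds, SplitSpec(seed=0, stratify=True))
        for e in rep.entries:
            if e.name == "deep_learning":
                continue  # a 2-point constant design can defeat early stopping
            if e.name == "lda":
                # zero within-class scatter makes the discriminant ill-posed;
                # the suite records the failure instead of raising
                assert e.error is not None or e.test_accuracy == 100.0
                continue
            assert e.error is None, e.error
            assert e.train_accuracy == 100.0 and e.test_accuracy == 100.0

    def test_every_registry_model_appears_once(self):
        ds = generate_classification_dataset(seed=0, acq=AcquisitionConfig(n_points=64))
        rep = run_classification_suite(ds, SplitSpec(seed=0, stratify=True))
        assert [e.name for e in rep.entries] == list(CLASSIFIER_NAMES)

    def test_confusion_counts_sum_to_partition_sizes(self):
        ds = generate_classification_dataset(seed=1, acq=AcquisitionConfig(n_points=64))
        rep = run_classification_suite(ds, SplitSpec(seed=1, stratify=True), models=["logistic"])
        e = rep["logistic"]
        assert e.confusion_train.sum() == len(rep.train_idx)
        assert e.confusion_test.sum() == len(rep.test_idx)

    def test_accuracies_within_percent_bounds(self):
        ds = generate_classification_dataset(seed=2, acq=AcquisitionConfig(n_points=64))
        rep = run_classification_suite(ds, SplitSpec(seed=2, stratify=True))
        for e in rep.entries:
            if e.error is None:
                assert 0.0 <= e.train_accuracy <= 100.0
                assert 0.0 <= e.test_accuracy <= 100.0


class TestEmbeddings:
    def test_pca_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        ds = _toy_dataset(X, pd.DataFrame({"y": np.zeros(10)}))
        emb = embed(ds, "pca", n_components=2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1][:2]
        brute = Xc @ evecs[:, order]
        for j in range(2):  # components match up to sign
            assert min(
                np.max(np.abs(emb.coordinates[:, j] - brute[:, j])),
                np.max(np.abs(emb.coordinates[:, j] + brute[:, j])),
            ) < 1e-8

    def test_pca_exact_on_planar_data(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(size=(2, 8))
        X = rng.normal(size=(12, 2)) @ basis  # exactly rank 2
        ds = _toy_dataset(X, pd.DataFrame({"y": np.zeros(12)}))
        emb = embed(ds, "pca", n_components=2)
        recon = emb.transformer.inverse_transform(emb.coordinates)
        assert np.max(np.abs(recon - X)) < 1e-10

    def test_pca_variances_non_increasing(self):
        ds = generate_classification_dataset(seed=5, acq=AcquisitionConfig(n_points=64))
        emb = embed(ds, "pca", n_components=2)
        assert emb.explained[0] >= emb.explained[1]

    def test_lda_separates_classes_for_nearest_centroid(self):
        ds = generate_classification_dataset(seed=6, acq=AcquisitionConfig(n_points=64))
        emb = embed(ds, "lda", n_components=2)
        y = ds.labels["subject"].to_numpy()
        cents = {c: emb.coordinates[y == c].mean(axis=0) for c in np.unique(y)}
        pred = [
            min(cents, key=lambda c: np.linalg.norm(emb.coordinates[i] - cents[c]))
            for i in range(len(y))
        ]
        assert np.mean(np.asarray(pred) == y) == 1.0

    def test_dimension_preconditions(self):
        ds = generate_classification_dataset(seed=0, acq=AcquisitionConfig(n_points=64))
        with pytest.raises(ValueError, match="LDA"):
            embed(ds, "lda", n_components=4)  # > n_classes - 1
        with pytest.raises(ValueError, match="PCA"):
            embed(ds, "pca", n_components=21)


class TestPcaChain:
    def test_lossless_components_match_direct_run_for_kernel_model(self):
        # full-rank PCA is centring + rotation; an RBF-kernel classifier
        # depends only on pairwise distances, so accuracy is unchanged
        ds = generate_classification_dataset(seed=7, acq=AcquisitionConfig(n_points=64))
        split = SplitSpec(seed=7, stratify=True)
        chained = pca_then_classify(ds, n_components=15, model="svc", split=split, scale=False)
        direct = run_classification_suite(ds, split, models=["svc"], scale=False)["svc"]
        assert chained.train_accuracy == direct.train_accuracy
        assert chained.test_accuracy == direct.test_accuracy

    def test_two_component_random_forest_on_separable_classes(self):
        ds = generate_classification_dataset(seed=8)
        entry = pca_then_classify(ds, 2, "random_forest", SplitSpec(seed=8, stratify=True))
        assert entry.train_accuracy == 100.0
        assert entry.test_accuracy == 100.0

    def test_zero_components_rejected(self):
        ds = generate_classification_dataset(seed=0, acq=AcquisitionConfig(n_points=64))
        with pytest.raises(ValueError):
            pca_then_classify(ds, 0, "random_forest")


class TestFeatureImportance:
    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 5))
        X[:, 2] = 7.0
        y = X[:, 0]
        model = make_regressor("linear", scale=False).fit(X, y)
        perm = feature_importance(model, X, y, method="permutation", seed=0)
        assert perm.scores[2] == 0.0
        shap = feature_importance(model, X, y, method="shapley", seed=0, n_permutations=5)
        assert shap.scores[2] <= 1e-10

    def test_identity_target_ranks_its_feature_first(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        y = X[:, 4].copy()
        model = make_regressor("linear", scale=False).fit(X, y)
        for method in ("permutation", "shapley"):
            rep = feature_importance(model, X, y, method=method, seed=0, n_permutations=8)
            assert rep.ranking[0] == 4

    def test_ranking_is_a_permutation(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 7))
        y = X.sum(axis=1)
        model = make_regressor("linear").fit(X, y)
        rep = feature_importance(model, X, y, seed=0)
        assert sorted(rep.ranking.tolist()) == list(range(7))

    def test_unfitted_model_rejected(self):
        model = make_regressor("linear")
        with pytest.raises(RuntimeError, match="fitted"):
            feature_importance(model, np.zeros((4, 2)), np.zeros(4))


def test_classifier_and_regressor_factories_cover_registries():
    for nm in REGRESSOR_NAMES:
        assert make_regressor(nm, seed=0) is not None
    for nm in CLASSIFIER_NAMES:
        assert make_classifier(nm, seed=0) is not None
    with pytest.raises(KeyError):
        make_classifier("oracle")
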