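import json

import numpy as np
import pytest

from msirna.classifier import (
    MSIModel,
    load_model,
    predict,
    save_model,
    score_matrix,
    smote_balance,
    train,
    youden_threshold,
)
from msirna.errors import ModelFormatError, ValidationError
from msirna.io_matrix import ExpressionMatrix, LabeledCohort
from msirna.preprocess import bulk_transform
from msirna.simulate import SimulationConfig, simulate_bulk


def brute_force_youden(scores, y):
    """Oracle: scan every candidate cutpoint, ties toward larger t."""
    s = np.asarray(scores, float)
    distinct = np.unique(s)
    cands = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]])
    best = (-np.inf, -np.inf)
    for t in cands:
        called = s >= t
        sens = (called & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~called & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if (j, t) > best:
            best = (j, t)
    return best[1]


class TestSmoteBalance:
    def test_counts_balanced_and_originals_recoverable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(2, 1, (20, 3))])
        y = np.array([1] * 5 + [0] * 20)
        Xb, yb = smote_balance(X, y, k=3, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 20
        assert Xb.shape == (40, 3)
        np.testing.assert_array_equal(Xb[:25], X)  # originals untouched, in order

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(1)
        Xmin = rng.normal(0, 1, (6, 4))
        X = np.vstack([Xmin, rng.normal(5, 1, (30, 4))])
        y = np.array([1] * 6 + [0] * 30)
        Xb, yb = smote_balance(X, y, k=5, seed=2)
        synthetic = Xb[36:]
        for s in synthetic:
            # each synthetic point is a convex combination of two minority
            # points, so coordinate-wise it lies between some pair
            ok = False
            for i in range(6):
                for j in range(6):
                    lo = np.minimum(Xmin[i], Xmin[j]) - 1e-12
                    hi = np.maximum(Xmin[i], Xmin[j]) + 1e-12
                    if np.all(s >= lo) and np.all(s <= hi):
                        ok = True
            assert ok

    def test_balanced_input_returned_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 2))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = smote_balance(X, y, k=5, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_k_clamped_with_warning_and_singleton_rejected(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(4, 1, (10, 2))])
        y = np.array([1] * 3 + [0] * 10)
        with pytest.warns(UserWarning, match="clamped"):
            smote_balance(X, y, k=5, seed=0)
        y_single = np.array([1] + [0] * 12)
        with pytest.raises(ValidationError, match="minority"):
            smote_balance(X, y_single, k=5, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(2, 1, (12, 3))])
        y = np.array([1] * 4 + [0] * 12)
        a = smote_balance(X, y, seed=11)
        b = smote_balance(X, y, seed=11)
        np.testing.assert_array_equal(a[0], b[0])


class TestYoudenThreshold:
    def test_worked_example_midpoint(self):
        t = youden_threshold([0.1, 0.2, 0.8, 0.9], ["MSS", "MSS", "MSI", "MSI"])
        assert t == pytest.approx(0.5)

    def test_all_scores_equal_boundary_rule(self):
        t = youden_threshold([0.7, 0.7, 0.7], ["MSI", "MSS", "MSI"])
        assert t == pytest.approx(1.0)  # J = 0 everywhere; tie -> larger t

    def test_inverted_scores_warn(self):
        with pytest.warns(UserWarning, match="Youden"):
            youden_threshold([0.9, 0.8, 0.1, 0.2], ["MSS", "MSS", "MSI", "MSI"])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.uniform(0, 1, n), 2)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert youden_threshold(scores, y) == pytest.approx(
            brute_force_youden(scores, y)
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            youden_threshold([0.1, 0.9], ["MSI", "MSI"])


@pytest.fixture()
def trained(reference_cohort, reference_selection, reference_model):
    cohort, truth, _ = reference_cohort
    gene_set, _ = reference_selection
    return cohort, truth, gene_set.gene_ids, reference_model


class TestTrainPredict:
    def test_training_set_auc_high_on_separable_cohort(self, trained):
        cohort, truth, genes, model = trained
        from msirna.metrics import roc_auc

        scores = score_matrix(model, cohort.matrix)
        assert roc_auc(scores, cohort.label_array()) >= 0.99

    def test_threshold_in_open_unit_interval(self, trained):
        *_, model = trained
        assert 0.0 < model.threshold < 1.0

    def test_heldout_cohort_auc(self, trained):
        cohort, truth, genes, model = trained
        from msirna.metrics import roc_auc

        test, _ = simulate_bulk(
            SimulationConfig(seed=1, n_msi=40, n_mss=60), sample_seed=7
        )
        scores = score_matrix(model, test.matrix)
        assert roc_auc(scores, test.label_array()) >= 0.95

    def test_scoring_deterministic(self, trained):
        cohort, *_, model = trained
        a = score_matrix(model, cohort.matrix)
        b = score_matrix(model, cohort.matrix)
        np.testing.assert_array_equal(a, b)

    def test_status_follows_threshold_rule(self, trained):
        cohort, *_, model = trained
        results = predict(model, cohort.matrix)
        scores = score_matrix(model, cohort.matrix)
        for r, s in zip(results, scores):
            assert r.status == ("MSI" if s >= model.threshold else "MSS")

    def test_scores_invariant_to_gene_row_order(self, trained):
        cohort, *_, model = trained
        matrix = cohort.matrix
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(matrix.gene_ids))
        shuffled = matrix.subset_genes(perm)
        np.testing.assert_allclose(
            score_matrix(model, matrix), score_matrix(model, shuffled), atol=1e-12
        )

    def test_retrain_same_seed_bit_identical_model_file(self, trained, tmp_path):
        cohort, truth, genes, model = trained
        z = bulk_transform(cohort.matrix).subset_genes(genes)
        again = train(LabeledCohort(z, cohort.labels), seed=1)
        save_model(model, tmp_path / "a.json")
        save_model(again, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_single_class_cohort_rejected(self, trained):
        cohort, truth, genes, _ = trained
        z = bulk_transform(cohort.matrix).subset_genes(genes)
        labels = {o: "MSI" for o in z.obs_ids}
        with pytest.raises(ValidationError):
            train(LabeledCohort(z, labels), seed=1)


class TestMissingGenes:
    def test_few_missing_genes_zero_imputed_with_warning(self, trained):
        cohort, *_, model = trained
        if len(model.genes) < 2:
            pytest.skip("model has a single gene; cannot drop 10%")
        drop = model.genes[0]
        kept = [g for g in cohort.matrix.gene_ids if g != drop]
        sub = cohort.matrix.subset_genes(kept)
        n_missing = 1
        if n_missing <= 0.1 * len(model.genes):
            with pytest.warns(UserWarning, match="imputed"):
                score_matrix(model, sub)
        else:
            with pytest.raises(ValidationError):
                score_matrix(model, sub)

    def test_many_missing_genes_error_names_them(self, trained):
        cohort, *_, model = trained
        drop = set(model.genes[: max(1, len(model.genes) // 2 + 1)])
        kept = [g for g in cohort.matrix.gene_ids if g not in drop]
        sub = cohort.matrix.subset_genes(kept)
        with pytest.raises(ValidationError, match=sorted(drop)[0]):
            score_matrix(model, sub)


class TestModelPersistence:
    def test_round_trip_preserves_scores(self, trained, tmp_path):
        cohort, *_, model = trained
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        np.testing.assert_allclose(
            score_matrix(loaded, cohort.matrix),
            score_matrix(model, cohort.matrix),
            atol=1e-9,
        )

    def test_truncated_file_rejected(self, trained, tmp_path):
        *_, model = trained
        save_model(model, tmp_path / "m.json")
        text = (tmp_path / "m.json").read_text()
        (tmp_path / "bad.json").write_text(text[: len(text) // 2])
        with pytest.raises(ModelFormatError):
            load_model(tmp_path / "bad.json")

    def test_unknown_kernel_rejected(self, trained, tmp_path):
        *_, model = trained
        save_model(model, tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        doc["kernel"] = "hyperbolic"
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises((ModelFormatError, ValidationError)):
            load_model(tmp_path / "bad.json")

    def test_version_mismatch_rejected(self, trained, tmp_path):
        *_, model = trained
        save_model(model, tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        doc["format_version"] = 999
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(tmp_path / "bad.json")


class TestPlattScalingMatchesSklearn:
    def test_manual_probability_equals_sklearn_pipeline(self):
        # cross-check: our serialized scoring path against sklearn's own
        # calibrated-SVC predict_proba on the same fitted model
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(1.5, 1, (30, 3))])
        y = np.array([0] * 40 + [1] * 30)
        clf = CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale", random_state=7),
            method="sigmoid",
            ensemble=False,
        ).fit(X, y)
        cal = clf.calibrated_classifiers_[0]
        svc = cal.estimator
        model = MSIModel(
            genes=[f"g{i}" for i in range(3)],
            kernel="rbf",
            gamma=float(svc._gamma),
            C=1.0,
            support_vectors=svc.support_vectors_,
            dual_coef=svc.dual_coef_.ravel(),
            intercept=float(svc.intercept_[0]),
            platt_a=float(cal.calibrators[0].a_),
            platt_b=float(cal.calibrators[0].b_),
            threshold=0.5,
        )
        np.testing.assert_allclose(
            model.score_features(X), clf.predict_proba(X)[:, 1], atol=1e-9
        )
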