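import numpy as np
import pytest

from lifetracer.classify import (
    ModelSpec,
    default_grid,
    encode_labels,
    fit_final,
    make_estimator,
    ninefold_loo_cv,
    stratified_nested_cv,
)
from lifetracer.errors import ValidationError

from .conftest import make_matrix

LABELS_18 = ["abiotic"] * 8 + ["biotic"] * 10


def separable_matrix(n_signal=3, n_noise=10, seed=0):
    """Features equal to the class label (redundant fragments of one
    discriminative compound) plus random noise rows."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * 8 + [0] * 10)
    rows = [y.copy() for _ in range(n_signal)] + [rng.integers(0, 2, 18) for _ in range(n_noise)]
    return make_matrix(np.array(rows), LABELS_18)


class TestGrids:
    def test_logreg_grid_powers_of_ten(self):
        cs = [hp["C"] for hp in default_grid("logreg_l2")]
        assert cs == [10.0**k for k in range(-4, 5)]

    def test_svm_grid_cross_product(self):
        g = default_grid("svm")
        assert len(g) == 7 * 4
        assert {hp["kernel"] for hp in g} == {
            "linear",
            "polynomial",
            "radial basis function",
            "sigmoid",
        }

    def test_nb_and_rf_grids(self):
        assert sorted(hp["alpha"] for hp in default_grid("bernoulli_nb")) == [
            0.01,
            0.1,
            0.5,
            1.0,
            5.0,
            10.0,
        ]
        assert [hp["n_estimators"] for hp in default_grid("random_forest")] == [
            20,
            50,
            100,
            200,
            500,
        ]

    def test_every_family_estimator_constructs(self):
        for family in ("logreg_l1", "logreg_l2", "svm", "bernoulli_nb", "random_forest"):
            est = make_estimator(family, default_grid(family)[0])
            assert hasattr(est, "fit")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            default_grid("deep_net")


class TestNinefoldLOO:
    def test_separable_matrix_perfect(self):
        matrix = separable_matrix()
        spec = ModelSpec("logreg_l2", [{"C": 0.1}, {"C": 1.0}])
        report = ninefold_loo_cv(matrix, spec, n_seeds=3)
        assert report.mean_accuracy == 1.0
        assert report.mean_auc == 1.0

    def test_sample_count_must_split_into_nine_folds(self):
        matrix = make_matrix(np.ones((3, 10)), ["abiotic"] * 5 + ["biotic"] * 5)
        with pytest.raises(ValidationError):
            ninefold_loo_cv(matrix, ModelSpec("logreg_l2", [{"C": 1.0}]))

    def test_single_point_grid_equals_plain_ninefold(self):
        """Degenerate grid: inner LOO is a no-op, so results equal a plain
        9-fold CV run manually with the same folds and estimator."""
        matrix = separable_matrix()
        spec = ModelSpec("logreg_l2", [{"C": 0.1}])
        a = ninefold_loo_cv(matrix, spec, n_seeds=2)
        assert all(hp == {"C": 0.1} for seed in a.selected for hp in seed)
        X, y = encode_labels(matrix)
        for seed in range(2):
            rng = np.random.RandomState(seed)
            folds = rng.permutation(18).reshape(9, 2)
            accs = []
            for fold in folds:
                test = np.zeros(18, dtype=bool)
                test[fold] = True
                est = make_estimator("logreg_l2", {"C": 0.1}, seed)
                est.fit(X[~test], y[~test])
                accs.append((est.predict(X[test]) == y[test]).mean())
            assert a.per_seed_accuracy[seed] == pytest.approx(float(np.mean(accs)))

    def test_label_permutation_near_chance(self):
        """Null check: permuted labels give ~0.5 accuracy over seeds."""
        rng = np.random.default_rng(123)
        y = np.array([1] * 8 + [0] * 10)
        perm_y = rng.permutation(y)
        rows = [rng.integers(0, 2, 18) for _ in range(30)]
        labels = ["abiotic" if v else "biotic" for v in perm_y]
        matrix = make_matrix(np.array(rows), labels)
        report = ninefold_loo_cv(matrix, ModelSpec("logreg_l2", [{"C": 0.1}, {"C": 1.0}]), n_seeds=10)
        assert abs(report.mean_accuracy - 0.5) <= 0.15

    def test_ten_seeds_reported(self):
        matrix = separable_matrix()
        report = ninefold_loo_cv(matrix, ModelSpec("logreg_l2", [{"C": 0.1}]), n_seeds=10)
        assert len(report.per_seed_accuracy) == 10
        assert len(report.per_seed_auc) == 10


class TestStratified:
    def test_separable_matrix_perfect_auc(self):
        matrix = separable_matrix()
        spec = ModelSpec("logreg_l2", [{"C": 0.1}, {"C": 1.0}])
        report = stratified_nested_cv(matrix, spec, n_seeds=2)
        assert report.mean_auc == 1.0

    def test_every_outer_fold_contains_both_classes(self):
        from sklearn.model_selection import StratifiedKFold

        matrix = separable_matrix()
        _, y = encode_labels(matrix)
        for seed in range(3):
            skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=seed)
            for _, te in skf.split(np.zeros((18, 1)), y):
                assert len(np.unique(y[te])) == 2

    def test_class_too_small_rejected(self):
        matrix = make_matrix(
            np.ones((2, 8)), ["abiotic"] * 3 + ["biotic"] * 5
        )
        with pytest.raises(ValidationError):
            stratified_nested_cv(matrix, ModelSpec("logreg_l2", [{"C": 1.0}]))

    def test_single_point_grid_reduces_to_plain_cv(self):
        matrix = separable_matrix()
        report = stratified_nested_cv(matrix, ModelSpec("logreg_l2", [{"C": 0.1}]), n_seeds=2)
        assert all(hp == {"C": 0.1} for seed in report.selected for hp in seed)


class TestNoLeakage:
    def test_fold_membership_disjoint(self):
        """Outer test indices never appear in the data used for selection."""
        n = 18
        for seed in range(3):
            rng = np.random.RandomState(seed)
            folds = rng.permutation(n).reshape(9, 2)
            all_test = np.concatenate(folds)
            assert sorted(all_test) == list(range(n))
            for fold in folds:
                train = np.setdiff1d(np.arange(n), fold)
                assert len(np.intersect1d(train, fold)) == 0
                assert len(train) == 16


class TestFitFinal:
    def test_planted_feature_gets_largest_abiotic_coefficient(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 8 + [0] * 10)
        rows = [y] + [rng.integers(0, 2, 18) for _ in range(50)]
        matrix = make_matrix(np.array(rows), LABELS_18)
        fitted = fit_final(matrix)
        coefs = fitted.coefficients
        top = max(coefs, key=lambda f: abs(coefs[f]))
        assert top == 0
        assert coefs[0] > 0  # abiotic-enriched -> positive sign

    def test_all_zero_feature_coefficient_zero(self):
        rng = np.random.default_rng(6)
        y = np.array([1] * 8 + [0] * 10)
        rows = [y, np.zeros(18, dtype=int)] + [rng.integers(0, 2, 18) for _ in range(5)]
        matrix = make_matrix(np.array(rows), LABELS_18)
        fitted = fit_final(matrix)
        assert fitted.coefficients[1] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_across_reruns(self):
        matrix = separable_matrix()
        a = fit_final(matrix)
        b = fit_final(matrix)
        assert a.coefficients == b.coefficients
        assert a.intercept == b.intercept

    def test_single_class_rejected(self):
        matrix = make_matrix(np.ones((2, 4)), ["abiotic"] * 4)
        with pytest.raises(ValidationError):
            fit_final(matrix)

    def test_nonlinear_family_rejected(self):
        matrix = separable_matrix()
        with pytest.raises(ValidationError):
            fit_final(matrix, ModelSpec("random_forest", [{"n_estimators": 20}]))

    def test_top_k_precision_on_planted_features(self):
        """5 planted discriminative features among 200 noise, n=18."""
        rng = np.random.default_rng(7)
        y = np.array([1] * 8 + [0] * 10)
        planted = [y.copy() for _ in range(5)]
        noise = [rng.integers(0, 2, 18) for _ in range(200)]
        matrix = make_matrix(np.array(planted + noise), LABELS_18)
        fitted = fit_final(matrix)
        coefs = fitted.coefficients
        top5 = sorted(coefs, key=lambda f: -abs(coefs[f]))[:5]
        precision = len(set(top5) & {0, 1, 2, 3, 4}) / 5
        assert precision >= 0.8

    def test_predictions_match_decision_scores(self):
        matrix = separable_matrix()
        fitted = fit_final(matrix)
        scores = fitted.decision_scores(matrix)
        np.testing.assert_array_equal(fitted.predict(matrix), (scores > 0).astype(int))


class TestModelComparison:
    def test_all_families_run_and_rank(self):
        """Comparison harness: every family trains and reports a metric."""
        matrix = separable_matrix(n_noise=5)
        results = {}
        for family in ("logreg_l1", "logreg_l2", "svm", "bernoulli_nb", "random_forest"):
            spec = ModelSpec(family, [default_grid(family)[len(default_grid(family)) // 2]])
            report = stratified_nested_cv(matrix, spec, n_seeds=1)
            results[family] = report.mean_auc
        ranked = sorted(results, key=results.get, reverse=True)
        assert len(ranked) == 5
        assert all(0.0 <= v <= 1.0 for v in results.values())
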