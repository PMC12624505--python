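"""Abiotic-vs-biotic classification on the binary feature matrix.

Two nested cross-validation schemes are provided:

* ``ninefold_loo_cv`` — shuffle the 18 samples, split into nine folds of
  two; inside each fold a leave-one-out loop over the 16 training samples
  picks the hyperparameters with the best mean validation accuracy, the
  model is refit on all 16 and scored on the held-out pair; repeated over
  ten seeds.
* ``stratified_nested_cv`` — 6-fold stratified outer split (every fold holds
  both classes), inner 5-fold selection by mean validation AUC; repeated
  over ten seeds.

Class encoding: abiotic = 1, biotic = 0, so positive coefficients mark
abiotic-enriched features.  Validation ties break toward stronger
regularization (grids are ordered strongest-first and selection uses a
strict improvement test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC

from lifetracer.errors import ValidationError
from lifetracer.features import FeatureMatrix

POSITIVE_CLASS = "abiotic"  # encoded as 1

_KERNEL_MAP = {
    "linear": "linear",
    "polynomial": "poly",
    "radial basis function": "rbf",
    "sigmoid": "sigmoid",
}

LINEAR_FAMILIES = ("logreg_l1", "logreg_l2")


def default_grid(family: str) -> list[dict]:
    """Hyperparameter grid per model family, ordered strongest-regularization
    first so tie-breaking stays conservative."""
    if family in ("logreg_l1", "logreg_l2"):
        return [{"C": float(c)} for c in 10.0 ** np.arange(-4, 5)]
    if family == "svm":
        return [
            {"C": float(c), "kernel": k}
            for c in 10.0 ** np.arange(-3, 4)
            for k in ("linear", "polynomial", "radial basis function", "sigmoid")
        ]
    if family == "bernoulli_nb":
        return [{"alpha": a} for a in (10.0, 5.0, 1.0, 0.5, 0.1, 0.01)]
    if family == "random_forest":
        return [{"n_estimators": n} for n in (20, 50, 100, 200, 500)]
    raise ValidationError(f"unknown model family {family!r}")


@dataclass
class ModelSpec:
    family: str
    grid: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not self.grid:
            self.grid = default_grid(self.family)


@dataclass
class CVReport:
    scheme: str
    per_seed_accuracy: list[float]
    per_seed_auc: list[float]
    selected: list[list[dict]]  # per seed, per outer fold

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_seed_accuracy))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_seed_auc))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "per_seed_accuracy": self.per_seed_accuracy,
            "per_seed_auc": self.per_seed_auc,
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "selected": self.selected,
        }


@dataclass
class FittedClassifier:
    family: str
    hyperparameters: dict
    coefficients: dict  # feature_id -> signed weight
    intercept: float
    feature_ids: list

    def decision_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        w = np.array([self.coefficients[f] for f in self.feature_ids])
        X = matrix.df.loc[self.feature_ids].T.values.astype(float)
        return X @ w + self.intercept

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        """1 = abiotic, 0 = biotic."""
        return (self.decision_scores(matrix) > 0).astype(int)


def make_estimator(family: str, hp: dict, random_state: int = 0):
    if family == "logreg_l1":
        return LogisticRegression(C=hp["C"], l1_ratio=1, solver="liblinear", max_iter=5000)
    if family == "logreg_l2":
        return LogisticRegression(C=hp["C"], max_iter=5000)
    if family == "svm":
        return SVC(C=hp["C"], kernel=_KERNEL_MAP[hp["kernel"]])
    if family == "bernoulli_nb":
        return BernoulliNB(alpha=hp["alpha"])
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=hp["n_estimators"], random_state=random_state)
    raise ValidationError(f"unknown model family {family!r}")


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


def encode_labels(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(samples x features design matrix, 0/1 label vector)."""
    X = matrix.df.T.values.astype(float)
    y = (matrix.labels.values == POSITIVE_CLASS).astype(int)
    return X, y


def _select_by_loo_accuracy(X, y, spec: ModelSpec, random_state: int) -> dict:
    """Leave-one-out hyperparameter selection by mean validation accuracy."""
    if len(spec.grid) == 1:
        return spec.grid[0]
    n = len(y)
    best_hp, best_acc = None, -1.0
    for hp in spec.grid:
        correct = 0
        for i in range(n):
            tr = np.arange(n) != i
            if len(np.unique(y[tr])) < 2:
                continue
            est = make_estimator(spec.family, hp, random_state)
            est.fit(X[tr], y[tr])
            correct += int(est.predict(X[~tr])[0] == y[i])
        acc = correct / n
        if acc > best_acc:  # strict: earlier (stronger-regularized) wins ties
            best_hp, best_acc = hp, acc
    return best_hp


def ninefold_loo_cv(
    matrix: FeatureMatrix, spec: ModelSpec, n_seeds: int = 10
) -> CVReport:
    """Nine-fold outer CV with nested leave-one-out model selection."""
    X, y = encode_labels(matrix)
    n = len(y)
    if n % 9 != 0:
        raise ValidationError(f"{n} samples cannot be split into 9 equal folds")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    fold_size = n // 9
    per_seed_acc, per_seed_auc, selected = [], [], []
    for seed in range(n_seeds):
        rng = np.random.RandomState(seed)
        perm = rng.permutation(n)
        folds = perm.reshape(9, fold_size)
        fold_accs, seed_hps = [], []
        scores = np.empty(n)
        for fold in folds:
            test = np.zeros(n, dtype=bool)
            test[fold] = True
            hp = _select_by_loo_accuracy(X[~test], y[~test], spec, seed)
            est = make_estimator(spec.family, hp, seed)
            est.fit(X[~test], y[~test])
            fold_accs.append(accuracy_score(y[test], est.predict(X[test])))
            scores[test] = _scores(est, X[test])
            seed_hps.append(hp)
        per_seed_acc.append(float(np.mean(fold_accs)))
        per_seed_auc.append(float(roc_auc_score(y, scores)))  # pooled over folds
        selected.append(seed_hps)
    return CVReport("ninefold_loo", per_seed_acc, per_seed_auc, selected)


def _select_by_kfold_auc(X, y, spec: ModelSpec, inner: int, seed: int) -> dict:
    if len(spec.grid) == 1:
        return spec.grid[0]
    skf = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_hp, best_auc = None, -1.0
    for hp in spec.grid:
        aucs = []
        for tr, va in splits:
            est = make_estimator(spec.family, hp, seed)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[va], _scores(est, X[va])))
        auc = float(np.mean(aucs))
        if auc > best_auc:
            best_hp, best_auc = hp, auc
    return best_hp


def stratified_nested_cv(
    matrix: FeatureMatrix,
    spec: ModelSpec,
    outer: int = 6,
    inner: int = 5,
    n_seeds: int = 10,
) -> CVReport:
    """Stratified outer folds with inner k-fold AUC-based model selection."""
    X, y = encode_labels(matrix)
    counts = np.bincount(y, minlength=2)
    if counts.min() < outer:
        raise ValidationError(
            f"each class needs >= {outer} samples for {outer}-fold stratification"
        )
    per_seed_acc, per_seed_auc, selected = [], [], []
    for seed in range(n_seeds):
        skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
        fold_aucs, fold_accs, seed_hps = [], [], []
        for tr, te in skf.split(X, y):
            hp = _select_by_kfold_auc(X[tr], y[tr], spec, inner, seed)
            est = make_estimator(spec.family, hp, seed)
            est.fit(X[tr], y[tr])
            fold_aucs.append(roc_auc_score(y[te], _scores(est, X[te])))
            fold_accs.append(accuracy_score(y[te], est.predict(X[te])))
            seed_hps.append(hp)
        per_seed_acc.append(float(np.mean(fold_accs)))
        per_seed_auc.append(float(np.mean(fold_aucs)))
        selected.append(seed_hps)
    return CVReport("stratified_6x5", per_seed_acc, per_seed_auc, selected)


def fit_final(matrix: FeatureMatrix, spec: ModelSpec | None = None) -> FittedClassifier:
    """Fit the deployed model on all samples and expose signed coefficients.

    Hyperparameters come from leave-one-out selection over the full data;
    the shipped default is L2 logistic regression with C = 0.1 (a singleton
    grid, so selection is trivial).  Only linear families expose
    coefficients.
    """
    spec = spec or ModelSpec("logreg_l2", [{"C": 0.1}])
    if spec.family not in LINEAR_FAMILIES:
        raise ValidationError(f"final model must be linear, got {spec.family!r}")
    X, y = encode_labels(matrix)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to fit the final model")
    hp = _select_by_loo_accuracy(X, y, spec, random_state=0)
    est = make_estimator(spec.family, hp, random_state=0)
    est.fit(X, y)
    feature_ids = list(matrix.df.index)
    coefs = dict(zip(feature_ids, est.coef_[0].astype(float)))
    return FittedClassifier(
        family=spec.family,
        hyperparameters=hp,
        coefficients=coefs,
        intercept=float(est.intercept_[0]),
        feature_ids=feature_ids,
    )
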