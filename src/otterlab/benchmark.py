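"""Benchmarking many regressors/classifiers on labelled decay collections.

The study design: raw signal samples are the features (one column per time
point), targets are hydration levels (regression), a (surface hydration,
gradient) pair (multi-target regression) or subject identity
(classification).  Data are split 75/25 once, every registered model is
fitted on the training rows only, and train/test metrics are collected
into a report.  Also provided: 2-component LDA/PCA embeddings, a
PCA-then-classifier chain, and per-feature importance attribution
(permutation importance, or a Monte-Carlo Shapley-value estimate).

Model hyper-parameters are library defaults with fixed seeds; a config
mapping allows overrides but no tuning loop is shipped.  Features are
standardised inside each model pipeline by default (``scale=False`` to
disable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone, is_classifier
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
    VotingRegressor,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, LogisticRegression, RidgeCV
from sklearn.metrics import accuracy_score, confusion_matrix, mean_squared_error, r2_score
from sklearn.multioutput import MultiOutputRegressor
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor

from .datasets import Dataset

__all__ = [
    "REGRESSOR_NAMES",
    "CLASSIFIER_NAMES",
    "SplitSpec",
    "make_split",
    "make_regressor",
    "make_classifier",
    "RegressionReport",
    "ClassificationReport",
    "run_regression_suite",
    "run_classification_suite",
    "EmbeddingResult",
    "embed",
    "pca_then_classify",
    "ImportanceReport",
    "feature_importance",
]


# ---------------------------------------------------------------- splitting

@dataclass(frozen=True)
class SplitSpec:
    """One random train/test partition (default 75/25), optionally
    stratified by class label."""

    train_fraction: float = 0.75
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


def make_split(n: int, spec: SplitSpec = SplitSpec(), labels=None):
    """Disjoint, exhaustive (train, test) index arrays.

    ``|train| = round(train_fraction * n)`` (half-up), so 97 rows at 0.75
    give 73 train / 24 test.  With ``stratify=True`` the training quota is
    apportioned per class by largest remainder, guaranteeing every class
    appears in both partitions (classes need >= 2 members).
    """
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    if not spec.stratify:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if labels is None:
        raise ValueError("stratified split requires labels")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("stratification impossible: a class has fewer than 2 members")
    quota = spec.train_fraction * counts
    base = np.floor(quota).astype(int)
    base = np.clip(base, 1, counts - 1)
    short = n_train - base.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    i = 0
    while short > 0 and i < 10 * classes.size:
        c = order[i % classes.size]
        if base[c] < counts[c] - 1:
            base[c] += 1
            short -= 1
        i += 1
    train, test = [], []
    for c, k in zip(classes, base):
        idx = np.nonzero(labels == c)[0]
        perm = rng.permutation(idx)
        train.append(perm[:k])
        test.append(perm[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


# ---------------------------------------------------------------- registries

REGRESSOR_NAMES = (
    "lasso",
    "elastic_net",
    "decision_tree",
    "svm",
    "gradient_boosting",
    "linear",
    "random_forest",
    "knn",
    "extreme_gradient_boosting",
    "pls",
    "voting",
    "ridge_cv",
    "deep_learning",
)

CLASSIFIER_NAMES = (
    "logistic",
    "naive_bayes",
    "svc",
    "random_forest",
    "bagging",
    "ada_boost",
    "gradient_boost",
    "deep_learning",
    "lda",
)

# regressors whose sklearn estimator handles a 2-D target natively
_NATIVE_MULTIOUTPUT = {"linear", "ridge_cv", "knn", "decision_tree", "random_forest", "pls", "deep_learning", "lasso", "elastic_net"}


def _base_regressor(name: str, seed: int, overrides: dict):
    kw = dict(overrides or {})
    if name == "lasso":
        return Lasso(random_state=seed, **kw)
    if name == "elastic_net":
        return ElasticNet(random_state=seed, **kw)
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **kw)
    if name == "svm":
        return SVR(**kw)
    if name == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **kw)
    if name == "linear":
        return LinearRegression(**kw)
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **kw)
    if name == "knn":
        return KNeighborsRegressor(**kw)
    if name == "extreme_gradient_boosting":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **kw)
    if name == "pls":
        return PLSRegression(**{"n_components": 2, **kw})
    if name == "voting":
        return VotingRegressor(
            estimators=[
                ("linear", LinearRegression()),
                ("knn", KNeighborsRegressor()),
                ("rf", RandomForestRegressor(random_state=seed, n_jobs=1)),
            ],
            **kw,
        )
    if name == "ridge_cv":
        return RidgeCV(**kw)
    if name == "deep_learning":
        return MLPRegressor(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            early_stopping=True,
            max_iter=500,
            random_state=seed,
            **kw,
        )
    raise KeyError(f"unknown regressor {name!r}; known: {REGRESSOR_NAMES}")


def _base_classifier(name: str, seed: int, overrides: dict):
    kw = dict(overrides or {})
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **kw)
    if name == "naive_bayes":
        return GaussianNB(**kw)
    if name == "svc":
        return SVC(random_state=seed, **kw)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **kw)
    if name == "bagging":
        return BaggingClassifier(random_state=seed, n_jobs=1, **kw)
    if name == "ada_boost":
        # depth-2 base trees: a depth-1 stump has 2 leaves, fewer than the
        # number of classes in a multi-class problem, so the boosted
        # ensemble cannot represent a K>2 partition
        from sklearn.tree import DecisionTreeClassifier

        kw.setdefault("estimator", DecisionTreeClassifier(max_depth=2, random_state=seed))
        return AdaBoostClassifier(random_state=seed, **kw)
    if name == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed, **kw)
    if name == "deep_learning":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            early_stopping=True,
            max_iter=500,
            random_state=seed,
            **kw,
        )
    if name == "lda":
        return LinearDiscriminantAnalysis(**kw)
    raise KeyError(f"unknown classifier {name!r}; known: {CLASSIFIER_NAMES}")


def make_regressor(name: str, seed: int = 0, scale: bool = True, multioutput: bool = False, overrides: dict | None = None):
    """Build the named regressor pipeline (standardised features unless
    ``scale=False``; wrapped per-target when the target is 2-D and the
    estimator lacks native multi-output support)."""
    est = _base_regressor(name, seed, overrides or {})
    if multioutput and name not in _NATIVE_MULTIOUTPUT:
        est = MultiOutputRegressor(est)
    steps = ([("scale", StandardScaler())] if scale else []) + [("model", est)]
    return Pipeline(steps)


def make_classifier(name: str, seed: int = 0, scale: bool = True, overrides: dict | None = None):
    """Build the named classifier pipeline."""
    est = _base_classifier(name, seed, overrides or {})
    steps = ([("scale", StandardScaler())] if scale else []) + [("model", est)]
    return Pipeline(steps)


# ---------------------------------------------------------------- reports

def _r2(y_true, y_pred) -> float:
    """R^2 with the convention that a constant target scores 0 (an exact
    constant predictor would otherwise be 0/0)."""
    y_true = np.asarray(y_true, dtype=float)
    if np.allclose(np.var(y_true, axis=0), 0):
        return 0.0
    return float(r2_score(y_true, y_pred))


def _rmse(y_true, y_pred) -> float:
    return float(np.sqrt(mean_squared_error(y_true, y_pred)))


@dataclass
class RegressionEntry:
    name: str
    train_r2: float = np.nan
    test_r2: float = np.nan
    train_rmse: float = np.nan
    test_rmse: float = np.nan
    y_test: np.ndarray | None = None
    y_pred: np.ndarray | None = None
    error: str | None = None


@dataclass
class RegressionReport:
    entries: list
    split: SplitSpec
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __getitem__(self, name: str) -> RegressionEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": e.name,
                    "train_r2": e.train_r2,
                    "test_r2": e.test_r2,
                    "train_rmse": e.train_rmse,
                    "test_rmse": e.test_rmse,
                    "error": e.error or "",
                }
                for e in self.entries
            ]
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Regression benchmark ({len(self.train_idx)} train / {len(self.test_idx)} test, seed {self.split.seed})",
            "=" * 64,
            f"{'model':<26}{'train R2':>9}{'test R2':>9}{'test RMSE':>11}",
        ]
        for _, r in df.iterrows():
            if r["error"]:
                lines.append(f"{r['model']:<26}  failed: {r['error']}")
            else:
                lines.append(
                    f"{r['model']:<26}{r['train_r2']:>9.3f}{r['test_r2']:>9.3f}{r['test_rmse']:>11.4g}"
                )
        return "\n".join(lines)


@dataclass
class ClassificationEntry:
    name: str
    train_accuracy: float = np.nan  # percent
    test_accuracy: float = np.nan  # percent
    confusion_train: np.ndarray | None = None
    confusion_test: np.ndarray | None = None
    error: str | None = None


@dataclass
class ClassificationReport:
    entries: list
    split: SplitSpec
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __getitem__(self, name: str) -> ClassificationEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": e.name,
                    "train_accuracy_pct": e.train_accuracy,
                    "test_accuracy_pct": e.test_accuracy,
                    "error": e.error or "",
                }
                for e in self.entries
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Classification benchmark ({len(self.train_idx)} train / {len(self.test_idx)} test, seed {self.split.seed})",
            "=" * 56,
            f"{'model':<20}{'train acc [%]':>14}{'test acc [%]':>14}",
        ]
        for e in self.entries:
            if e.error:
                lines.append(f"{e.name:<20}  failed: {e.error}")
            else:
                lines.append(f"{e.name:<20}{e.train_accuracy:>14.1f}{e.test_accuracy:>14.1f}")
        return "\n".join(lines)


# ---------------------------------------------------------------- suites

def run_regression_suite(
    data: Dataset,
    split: SplitSpec = SplitSpec(),
    models=None,
    scale: bool = True,
    overrides: dict | None = None,
) -> RegressionReport:
    """Fit every requested regressor on one train/test split of a
    continuous-label dataset and report R^2 / RMSE on both partitions.
    A model that raises is recorded with its failure reason, not raised.
    """
    names = tuple(models) if models is not None else REGRESSOR_NAMES
    for nm in names:
        _base_regressor(nm, 0, {})  # validate registry names up front
    X = data.signals
    y = data.y
    multi = y.ndim > 1
    tr, te = make_split(data.n_signals, split)
    entries = []
    for nm in names:
        entry = RegressionEntry(name=nm)
        try:
            ov = (overrides or {}).get(nm)
            model = make_regressor(nm, seed=split.seed, scale=scale, multioutput=multi, overrides=ov)
            model.fit(X[tr], y[tr])
            p_tr = np.asarray(model.predict(X[tr]))
            p_te = np.asarray(model.predict(X[te]))
            if multi:
                p_tr = p_tr.reshape(len(tr), -1)
                p_te = p_te.reshape(len(te), -1)
            entry.train_r2 = _r2(y[tr], p_tr)
            entry.test_r2 = _r2(y[te], p_te)
            entry.train_rmse = _rmse(y[tr], p_tr)
            entry.test_rmse = _rmse(y[te], p_te)
            entry.y_test = y[te]
            entry.y_pred = p_te
        except Exception as exc:  # noqa: BLE001 — failures are data, not control flow
            entry.error = f"{type(exc).__name__}: {exc}"
        entries.append(entry)
    return RegressionReport(entries=entries, split=split, train_idx=tr, test_idx=te)


def run_classification_suite(
    data: Dataset,
    split: SplitSpec = SplitSpec(stratify=True),
    models=None,
    scale: bool = True,
    overrides: dict | None = None,
) -> ClassificationReport:
    """Fit every requested classifier on one (by default stratified)
    split of a class-labelled dataset; accuracies are reported in percent.
    """
    names = tuple(models) if models is not None else CLASSIFIER_NAMES
    for nm in names:
        _base_classifier(nm, 0, {})
    X = data.signals
    y = np.asarray(data.y)
    tr, te = make_split(data.n_signals, split, labels=y if split.stratify else None)
    if set(np.unique(y[te])) - set(np.unique(y[tr])):
        raise ValueError("a class present in the test partition is absent from training")
    entries = []
    for nm in names:
        entry = ClassificationEntry(name=nm)
        try:
            ov = (overrides or {}).get(nm)
            model = make_classifier(nm, seed=split.seed, scale=scale, overrides=ov)
            model.fit(X[tr], y[tr])
            p_tr = model.predict(X[tr])
            p_te = model.predict(X[te])
            entry.train_accuracy = 100.0 * accuracy_score(y[tr], p_tr)
            entry.test_accuracy = 100.0 * accuracy_score(y[te], p_te)
            labels_all = np.unique(y)
            entry.confusion_train = confusion_matrix(y[tr], p_tr, labels=labels_all)
            entry.confusion_test = confusion_matrix(y[te], p_te, labels=labels_all)
        except Exception as exc:  # noqa: BLE001
            entry.error = f"{type(exc).__name__}: {exc}"
        entries.append(entry)
    return ClassificationReport(entries=entries, split=split, train_idx=tr, test_idx=te)


# ---------------------------------------------------------------- embeddings

@dataclass
class EmbeddingResult:
    """2-D coordinates from LDA or PCA, with the explained structure
    (variance ratios / eigenvalues) and the fitted transformer."""

    method: str
    coordinates: np.ndarray
    explained: np.ndarray
    transformer: object

    def plot(self, labels=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = None if labels is None else np.asarray(pd.factorize(np.asarray(labels))[0])
        sc = ax.scatter(self.coordinates[:, 0], self.coordinates[:, 1], c=c, cmap="tab10")
        ax.set_xlabel(f"{self.method} 1")
        ax.set_ylabel(f"{self.method} 2")
        return ax


def embed(data: Dataset, method: str = "pca", n_components: int = 2) -> EmbeddingResult:
    """Project the signal matrix onto its first components.

    PCA maximises variance; LDA (labels required) maximises between- to
    within-class scatter and allows at most ``n_classes - 1`` components.
    """
    X = data.signals
    method = method.lower()
    if method == "pca":
        if n_components > min(X.shape):
            raise ValueError("PCA: n_components exceeds min(n_rows, n_features)")
        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(X)
        return EmbeddingResult("PCA", coords, pca.explained_variance_ratio_, pca)
    if method == "lda":
        y = np.asarray(data.y)
        n_classes = np.unique(y).size
        if n_components > n_classes - 1:
            raise ValueError("LDA: n_components must be <= n_classes - 1")
        lda = LinearDiscriminantAnalysis(n_components=n_components)
        coords = lda.fit_transform(X, y)
        return EmbeddingResult("LDA", coords, lda.explained_variance_ratio_, lda)
    raise ValueError(f"unknown embedding method {method!r}")


def pca_then_classify(
    data: Dataset,
    n_components: int,
    model: str = "random_forest",
    split: SplitSpec = SplitSpec(stratify=True),
    scale: bool = False,
) -> ClassificationEntry:
    """Chain PCA (fitted on training rows only) into a classifier; test
    rows are projected with the training transform before prediction."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = data.signals
    y = np.asarray(data.y)
    tr, te = make_split(data.n_signals, split, labels=y if split.stratify else None)
    pca = PCA(n_components=min(n_components, min(len(tr), X.shape[1])), svd_solver="full")
    Z_tr = pca.fit_transform(X[tr])
    Z_te = pca.transform(X[te])
    clf = make_classifier(model, seed=split.seed, scale=scale)
    clf.fit(Z_tr, y[tr])
    entry = ClassificationEntry(name=f"pca{n_components}+{model}")
    p_tr, p_te = clf.predict(Z_tr), clf.predict(Z_te)
    entry.train_accuracy = 100.0 * accuracy_score(y[tr], p_tr)
    entry.test_accuracy = 100.0 * accuracy_score(y[te], p_te)
    labels_all = np.unique(y)
    entry.confusion_train = confusion_matrix(y[tr], p_tr, labels=labels_all)
    entry.confusion_test = confusion_matrix(y[te], p_te, labels=labels_all)
    return entry


# ---------------------------------------------------------------- importance

@dataclass
class ImportanceReport:
    """Per-feature attribution: mean-absolute scores, the descending
    ranking (a permutation of feature indices) and the method tag."""

    scores: np.ndarray
    ranking: np.ndarray
    method: str
    feature_times: np.ndarray | None = None

    def top(self, k: int = 5) -> np.ndarray:
        return self.ranking[:k]


def feature_importance(
    model,
    X,
    y,
    method: str = "permutation",
    seed: int = 0,
    n_repeats: int = 5,
    n_permutations: int = 10,
    feature_times=None,
) -> ImportanceReport:
    """Attribute the fitted model's output to individual features.

    ``method="permutation"`` shuffles one feature at a time and scores
    the drop in model performance (model-agnostic, fast).
    ``method="shapley"`` runs a Monte-Carlo permutation-sampling estimate
    of Shapley values: for each evaluation row and each sampled feature
    ordering, features are switched one at a time from a random background
    row's values to the row's own values, and the successive prediction
    differences are the marginal contributions.  Scores are mean absolute
    attributions over rows.  The model must already be fitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    try:
        check_is_fitted(model if not isinstance(model, Pipeline) else model[-1])
    except NotFittedError as exc:
        raise RuntimeError("feature_importance requires a fitted model") from exc

    if method == "permutation":
        res = permutation_importance(model, X, y, n_repeats=n_repeats, random_state=seed)
        scores = np.abs(res.importances_mean)
    elif method == "shapley":
        scores = _mc_shapley(model, X, seed=seed, n_permutations=n_permutations)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    ranking = np.argsort(-scores, kind="stable")
    return ImportanceReport(
        scores=scores,
        ranking=ranking,
        method=method,
        feature_times=None if feature_times is None else np.asarray(feature_times),
    )


def _predict_value(model, X):
    """Scalar model output per row: prediction for regressors, probability
    of each row's predicted class for classifiers."""
    est = model if not isinstance(model, Pipeline) else model[-1]
    if is_classifier(est):
        if hasattr(model, "predict_proba"):
            try:
                proba = model.predict_proba(X)
                return proba.max(axis=1) if proba.ndim == 2 else proba
            except AttributeError:
                pass
        if hasattr(model, "decision_function"):
            df = np.asarray(model.decision_function(X), dtype=float)
            return df.reshape(len(X), -1).max(axis=1)
        return np.asarray(model.predict(X), dtype=float)
    out = np.asarray(model.predict(X), dtype=float)
    return out.reshape(len(X), -1).mean(axis=1)


def _mc_shapley(model, X, seed: int, n_permutations: int) -> np.ndarray:
    """Monte-Carlo permutation-sampling Shapley estimate (feature
    independence assumed; background = rows of X)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    contrib = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        bg = X[rng.integers(0, n, n)]
        for i in range(n):
            # build the p+1 intermediate rows in one batch: row k has the
            # first k features (in `order`) set to x_i, the rest background
            steps = np.tile(bg[i], (p + 1, 1))
            for k, j in enumerate(order):
                steps[k + 1 :, j] = X[i, j]
            vals = _predict_value(model, steps)
            contrib[i, order] += np.diff(vals)
    contrib /= n_permutations
    return np.abs(contrib).mean(axis=0)
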