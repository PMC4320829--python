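"""PCA visualisation and CTX/HPC classification of feature vectors.

Two classifiers are provided: a random forest (bagged decision trees
with Gini splitting, 500 trees by default) and an RBF-kernel SVM with
``gamma = 1/11`` and ``C = 1``.  Performance is the mean percentage of
correct classifications on a held-out third, averaged over repeated
random stratified two-thirds/one-third splits.  For the forest,
feature importance is the mean decrease in Gini impurity, aggregated
over repeats and normalised so the top feature scores exactly 1.

Undefined (NaN) feature values are imputed with the training-split
median inside every fit, so no statistic leaks from test to train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from meadev.features import FEATURE_NAMES

__all__ = [
    "PcaResult",
    "ClassificationResult",
    "impute_median",
    "pca_project",
    "train_eval",
    "evaluate",
    "incremental_performance",
]

METHODS = ("tree_ensemble", "svm_rbf", "single_tree")
DEFAULT_GAMMA = 1.0 / 11.0
DEFAULT_TREES = 500
DEFAULT_REPEATS = 500
TEST_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class PcaResult:
    projections: np.ndarray  # n_samples x n_components
    variance_fractions: np.ndarray
    components: np.ndarray  # n_components x n_features (loadings)
    feature_names: tuple[str, ...]

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)


@dataclass(frozen=True)
class ClassificationResult:
    method: str
    age_div: int | None
    n_features_used: int
    mean_accuracy: float  # percent
    accuracy_sd: float  # percent
    n_repeats: int
    importance_scores: dict[str, float] | None  # max-normalised; forests only

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "age_div": self.age_div,
            "n_features_used": self.n_features_used,
            "mean_accuracy": self.mean_accuracy,
            "accuracy_sd": self.accuracy_sd,
            "n_repeats": self.n_repeats,
            "importance_scores": self.importance_scores,
        }


def impute_median(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Replace NaN entries column-wise with medians of ``reference``.

    ``reference`` defaults to ``X`` itself; pass the training block to
    impute a test block without leakage.  Columns that are entirely
    NaN in the reference fall back to 0.
    """
    X = np.array(X, dtype=float)
    ref = X if reference is None else np.asarray(reference, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(ref, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(med, idx[1])
    return X


def pca_project(X: np.ndarray, feature_names=FEATURE_NAMES) -> PcaResult:
    """PCA of feature vectors with per-feature variance normalisation.

    Each column is centred and scaled to unit variance before the
    eigendecomposition.  Zero-variance columns are dropped with a
    warning (their scale is undefined).  NaN input is rejected: impute
    upstream with :func:`impute_median`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 recordings")
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute before PCA")
    names = tuple(feature_names)[: X.shape[1]]
    var = X.var(axis=0)
    keep = var > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        X = X[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)
    if X.shape[1] == 0:
        raise ValueError("no feature has positive variance")
    Z = StandardScaler().fit_transform(X)
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(Z)
    return PcaResult(
        projections=proj,
        variance_fractions=pca.explained_variance_ratio_,
        components=pca.components_,
        feature_names=names,
    )


def _make_model(method: str, model_seed, n_trees: int):
    if method == "tree_ensemble":
        return RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", random_state=model_seed
        )
    if method == "single_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=model_seed)
    if method == "svm_rbf":
        return SVC(kernel="rbf", gamma=DEFAULT_GAMMA, C=1.0)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def train_eval(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "tree_ensemble",
    split_seed=0,
    model_seed=0,
    n_trees: int = DEFAULT_TREES,
    stratify: bool = True,
    return_importance: bool = False,
):
    """Fit on a random two-thirds and score on the held-out third.

    Returns percent correct; with ``return_importance=True`` (tree
    methods) also the raw Gini-importance vector of this fit.  Splits
    are stratified by class by default; if a class still ends up absent
    from the training block the split is redrawn (logged via warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(split_seed)
    for attempt in range(100):
        seed = int(rng.integers(2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            test_size=TEST_FRACTION,
            random_state=seed,
            stratify=y if stratify else None,
        )
        if np.unique(y_tr).size == 2 and len(y_te):
            break
        warnings.warn("degenerate split resampled")
    X_te = impute_median(X_te, reference=X_tr)
    X_tr = impute_median(X_tr)

    model = _make_model(method, model_seed, n_trees)
    if method == "svm_rbf":
        scaler = StandardScaler().fit(X_tr)
        model.fit(scaler.transform(X_tr), y_tr)
        acc = float(np.mean(model.predict(scaler.transform(X_te)) == y_te)) * 100.0
        importance = None
    else:
        model.fit(X_tr, y_tr)
        acc = float(np.mean(model.predict(X_te) == y_te)) * 100.0
        importance = model.feature_importances_.copy()
    if return_importance:
        return acc, importance
    return acc


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "tree_ensemble",
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    n_trees: int = DEFAULT_TREES,
    feature_names=FEATURE_NAMES,
    age_div: int | None = None,
) -> ClassificationResult:
    """Accuracy distribution over repeated splits (and forest importances).

    Repeat ``r`` derives its split and model seeds deterministically
    from ``seed``, so results are reproducible for a fixed repeat count.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    root = np.random.SeedSequence(seed)
    accs = np.empty(n_repeats)
    imp_sum = np.zeros(X.shape[1])
    tree_method = method in ("tree_ensemble", "single_tree")
    for r in range(n_repeats):
        split_ss, model_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(r,)).spawn(2)
        model_seed = int(model_ss.generate_state(1)[0] % (2**31 - 1))
        out = train_eval(
            X,
            y,
            method=method,
            split_seed=split_ss,
            model_seed=model_seed,
            n_trees=n_trees,
            return_importance=tree_method,
        )
        if tree_method:
            accs[r], imp = out
            imp_sum += imp
        else:
            accs[r] = out
    importance = None
    if tree_method:
        mean_imp = imp_sum / n_repeats
        top = mean_imp.max()
        norm = mean_imp / top if top > 0 else mean_imp
        importance = {n: float(v) for n, v in zip(feature_names, norm)}
    return ClassificationResult(
        method=method,
        age_div=age_div,
        n_features_used=X.shape[1],
        mean_accuracy=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
        importance_scores=importance,
    )


def incremental_performance(
    X: np.ndarray,
    y: np.ndarray,
    ranking,
    method: str = "tree_ensemble",
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    n_trees: int = DEFAULT_TREES,
    feature_names=FEATURE_NAMES,
    age_div: int | None = None,
) -> pd.DataFrame:
    """Mean accuracy using only the top-k ranked features, k = 1..len(ranking).

    ``ranking`` lists feature names in decreasing importance; it must
    cover a subset of ``feature_names`` (all 11 for the standard
    table).  Returns a frame with columns (k, feature_added, accuracy).
    """
    names = list(feature_names)
    idx = [names.index(f) for f in ranking]  # KeyError -> ValueError naturally
    rows = []
    for k in range(1, len(idx) + 1):
        res = evaluate(
            X[:, idx[:k]],
            y,
            method=method,
            n_repeats=n_repeats,
            seed=seed,
            n_trees=n_trees,
            feature_names=[names[i] for i in idx[:k]],
            age_div=age_div,
        )
        rows.append({"k": k, "feature_added": ranking[k - 1], "accuracy": res.mean_accuracy})
    return pd.DataFrame(rows)
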