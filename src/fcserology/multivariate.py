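"""Multivariate classification of bNAb status from Fc features.

PCA summarizes the selected features; a 500-tree random forest with
out-of-bag (OOB) cross-validation classifies subjects into bNAb /
no-bNAb groups; Gini importance ranks the features; and a
label-permutation test measures how often a forest fit to randomly
shuffled labels matches or beats the observed OOB accuracy.

Features are Z-score standardized before PCA and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from . import _fast_forest
from .composite import ConfusionMatrix, classification_metrics, zscore_standardize
from .errors import InputError

DEFAULT_N_TREES = 500


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by mean decrease in Gini impurity."""

    ranking: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        vals = [v for _, v in self.ranking]
        if any(v < 0 for v in vals):
            raise InputError("Gini importances must be non-negative")
        if any(vals[i] < vals[i + 1] for i in range(len(vals) - 1)):
            raise InputError("importance ranking must be sorted descending")

    def top(self, k: int) -> list[str]:
        return [f for f, _ in self.ranking[:k]]


@dataclass(frozen=True)
class RFResult:
    oob_predictions: pd.Series
    confusion: ConfusionMatrix
    importance: ImportanceRanking
    oob_accuracy: float
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float  # percent
    n_shuffles: int
    n_exceeding: int
    seed: int
    strict: bool = True
    n_tied: int = 0  # shuffles whose accuracy equals the observed exactly

    @property
    def exceedance_proportion(self) -> float:
        return self.n_exceeding / self.n_shuffles

    @property
    def p_value_add_one(self) -> float:
        """(k+1)/(N+1) estimator — never exactly zero, unlike the plain
        exceedance proportion under complete separation."""
        return (self.n_exceeding + 1) / (self.n_shuffles + 1)


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, SD 1 across subjects)."""
    return features.apply(lambda c: zscore_standardize(c.to_numpy()), axis=0,
                          result_type="broadcast")


def pca_summary(features: pd.DataFrame | np.ndarray, k: int = 2) -> dict:
    """Principal components of a standardized feature matrix.

    Missing values are an error — no imputation.  Returns component
    loadings, the per-component fraction of variance explained, and the
    cumulative fraction over the first ``k`` components.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InputError("need >= 2 subjects and >= 2 features")
    if np.isnan(X).any():
        raise InputError("missing values present; no imputation is performed")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if k < 1 or k > n_comp:
        raise InputError(f"k must be in [1, {n_comp}]")
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    return {
        "component_loadings": pca.components_,
        "scores": scores,
        "variance_explained": ratios,
        "cumulative": float(ratios[:k].sum()),
    }


def _encode_labels(labels, positive) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise InputError("labels must contain exactly 2 classes")
    if positive is None:
        positive = "bNAb" if "bNAb" in classes else classes.max()
    if positive not in classes:
        raise InputError(f"positive class {positive!r} not in labels")
    y01 = (y == positive).astype(np.int64)
    if y01.sum() < 2 or (1 - y01).sum() < 2:
        raise InputError("need >= 2 subjects in each class")
    return y01


def rf_classify(features: pd.DataFrame, labels, n_trees: int = DEFAULT_N_TREES,
                seed: int = 0, positive=None,
                standardize: bool = True) -> RFResult:
    """Random-forest classification with OOB cross-validation.

    Fits ``n_trees`` trees (Gini criterion, sqrt(n_features) candidate
    features per split, unlimited depth) and evaluates each subject with
    the majority vote of the trees that did not see it during training.
    Returns OOB predictions, the OOB confusion matrix (bNAb positive),
    the Gini importance ranking, and sensitivity/specificity/accuracy.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    if features.isna().any().any():
        raise InputError("missing values present; no imputation is performed")
    y = _encode_labels(labels, positive)
    X = standardize_features(features) if standardize else features
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        oob_score=True, bootstrap=True, random_state=int(seed) % (2**31),
    )
    rf.fit(X.to_numpy(), y)
    votes = rf.oob_decision_function_
    # subjects in every bootstrap sample (vanishingly rare at >=100 trees)
    # fall back to the majority class
    no_vote = np.isnan(votes).any(axis=1)
    pred = np.where(votes[:, 1] > votes[:, 0], 1, 0) if votes.shape[1] == 2 else votes
    majority = int(y.mean() > 0.5)
    pred = np.where(no_vote, majority, pred)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
    )
    order = np.argsort(rf.feature_importances_)[::-1]
    ranking = ImportanceRanking(tuple(
        (str(features.columns[i]), float(rf.feature_importances_[i]))
        for i in order
    ))
    return RFResult(
        oob_predictions=pd.Series(pred, index=features.index, name="oob_prediction"),
        confusion=cm,
        importance=ranking,
        oob_accuracy=float((pred == y).mean()),
        metrics=classification_metrics(cm),
    )


def permutation_test(features: pd.DataFrame, labels,
                     n_shuffles: int = 100_000,
                     n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                     positive=None, strict: bool = True,
                     standardize: bool = True) -> PermutationResult:
    """Label-permutation test of random-forest OOB accuracy.

    The observed OOB accuracy is computed once; for each shuffle the
    labels are permuted uniformly at random and a fresh forest's OOB
    accuracy recorded.  ``strict=True`` counts shuffles whose accuracy
    is strictly greater than observed; ``strict=False`` counts >=.
    Both forests use the compiled evaluator so the comparison is
    like-for-like.
    """
    if n_shuffles < 1:
        raise InputError("n_shuffles must be >= 1")
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    y = _encode_labels(labels, positive)
    X = standardize_features(features) if standardize else features
    Xv = np.ascontiguousarray(X.to_numpy(), dtype=np.float64)
    rng = np.random.default_rng(seed)
    observed = _fast_forest.oob_accuracy(
        Xv, y, n_trees, int(rng.integers(2**31)))
    n_greater = 0
    n_tied = 0
    tol = 0.5 / len(y)  # accuracies live on a 1/n lattice
    for _ in range(n_shuffles):
        perm = rng.permutation(y)
        acc = _fast_forest.oob_accuracy(
            Xv, perm, n_trees, int(rng.integers(2**31)))
        if acc > observed + tol:
            n_greater += 1
        elif acc > observed - tol:
            n_tied += 1
    return PermutationResult(
        observed_accuracy=100.0 * observed,
        n_shuffles=int(n_shuffles),
        n_exceeding=int(n_greater) if strict else int(n_greater + n_tied),
        seed=int(seed),
        strict=strict,
        n_tied=int(n_tied),
    )
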