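"""Subtype classification benchmarking and feature-importance ranking.

Base learners come from scikit-learn; what is implemented here is the
benchmark protocol (repeated stratified splits at a fixed train:test
proportion), the MSVM-RFE backward-elimination ranking loop over
subsampled linear SVMs, and the adaboost selection-frequency score, where
a depth-1 stump weak learner makes "which feature did this round pick"
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

SUPPORTED_CLASSIFIERS = ("msvm_rfe", "l1_logistic", "naive_bayes",
                         "random_forest", "adaboost")


@dataclass
class BenchmarkReport:
    """Mean recall/precision/accuracy (percent) per classifier over the
    repeated splits."""
    metrics: pd.DataFrame          # index=classifier, cols recall/precision/accuracy
    n_repeats: int
    split_sizes: tuple[int, int]


@dataclass
class ImportanceRanking:
    names: list[str]
    scores: np.ndarray             # frequency score or elimination rank
    kind: str                      # "adaboost" | "msvm_rfe"

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.names)


def _make_classifier(name: str, seed: int):
    if name == "l1_logistic":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                  random_state=seed, max_iter=2000)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100, random_state=seed)
    raise ValueError(
        f"unknown classifier {name!r}; supported: {SUPPORTED_CLASSIFIERS}")


class _MsvmRfeClassifier:
    """MSVM-RFE feature ranking followed by a linear SVM on the top
    features (ranking loop implemented here, base SVMs from sklearn)."""

    def __init__(self, seed: int, n_keep: int = 30, n_subsamples: int = 5):
        self.seed = seed
        self.n_keep = n_keep
        self.n_subsamples = n_subsamples

    def fit(self, X, y):
        table = pd.DataFrame(X)
        ranking = msvm_rfe_rank(table, y, n_subsamples=self.n_subsamples,
                                rng_seed=self.seed, step_fraction=0.2)
        order = np.argsort(ranking.scores)   # rank 1 = best
        self.keep_ = order[: min(self.n_keep, X.shape[1])]
        self.svm_ = LinearSVC(random_state=self.seed, max_iter=20000)
        self.svm_.fit(X[:, self.keep_], y)
        return self

    def predict(self, X):
        return self.svm_.predict(X[:, self.keep_])


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       positive) -> tuple[float, float, float]:
    tp = np.sum((y_true == positive) & (y_pred == positive))
    fn = np.sum((y_true == positive) & (y_pred != positive))
    fp = np.sum((y_true != positive) & (y_pred == positive))
    tn = np.sum((y_true != positive) & (y_pred != positive))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / len(y_true)
    return recall, precision, accuracy


def run_benchmark(table: pd.DataFrame, labels: np.ndarray,
                  classifiers: list[str] | None = None,
                  n_repeats: int = 5,
                  split: tuple[int, int] = (62, 60),
                  rng_seed: int = 0,
                  positive_class=None) -> BenchmarkReport:
    """Repeated stratified random splits at the given train:test
    proportion; reports mean recall, precision and accuracy (percent) of
    the positive class (first class alphabetically unless given)."""
    classifiers = list(classifiers or SUPPORTED_CLASSIFIERS)
    for name in classifiers:
        if name not in SUPPORTED_CLASSIFIERS:
            raise ValueError(f"unknown classifier {name!r}; "
                             f"supported: {SUPPORTED_CLASSIFIERS}")
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("benchmark requires exactly two classes")
    positive = positive_class if positive_class is not None else classes[0]
    X = table.to_numpy(dtype=float)
    n = len(y)
    train_frac = split[0] / (split[0] + split[1])
    rng = np.random.default_rng(rng_seed)
    rows = {name: [] for name in classifiers}
    for rep in range(n_repeats):
        train_idx, test_idx = [], []
        for cls in classes:
            idx = np.nonzero(y == cls)[0]
            idx = rng.permutation(idx)
            k = int(round(train_frac * len(idx)))
            k = min(max(k, 1), len(idx) - 1)
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        tr = np.array(train_idx)
        te = np.array(test_idx)
        seed = int(rng.integers(2 ** 31 - 1))
        for name in classifiers:
            clf = (_MsvmRfeClassifier(seed) if name == "msvm_rfe"
                   else _make_classifier(name, seed))
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            rows[name].append(_confusion_metrics(y[te], pred, positive))
    metrics = pd.DataFrame(
        {name: 100.0 * np.mean(rows[name], axis=0) for name in classifiers},
        index=["recall", "precision", "accuracy"]).T
    n_train = int(round(train_frac * n))
    return BenchmarkReport(metrics, n_repeats, (n_train, n - n_train))


def msvm_rfe_rank(table: pd.DataFrame, labels: np.ndarray,
                  n_subsamples: int = 10, rng_seed: int = 0,
                  step_fraction: float = 0.0) -> ImportanceRanking:
    """Multiple-SVM recursive feature elimination.

    Each iteration trains linear SVMs on bootstrap subsamples, scores the
    surviving features by the sum of squared weights across the SVMs, and
    removes the worst feature (or the worst ``step_fraction`` of features
    when set, for speed).  Reversing the elimination order gives the
    ranks: 1 is the most important feature."""
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("MSVM-RFE requires binary labels")
    X = table.to_numpy(dtype=float)
    names = list(table.columns)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(rng_seed)
    surviving = list(range(p))
    ranks = np.zeros(p, dtype=int)
    next_rank = p
    while surviving:
        Xs = X[:, surviving]
        scores = np.zeros(len(surviving))
        for _ in range(n_subsamples):
            while True:   # bootstrap must contain both classes
                idx = rng.integers(len(y), size=len(y))
                if len(np.unique(y[idx])) == 2:
                    break
            svm = LinearSVC(max_iter=20000,
                            random_state=int(rng.integers(2 ** 31 - 1)))
            svm.fit(Xs[idx], y[idx])
            scores += svm.coef_.ravel() ** 2
        n_drop = max(1, int(step_fraction * len(surviving)))
        n_drop = min(n_drop, len(surviving))
        drop_order = np.argsort(scores)[:n_drop]
        # worst feature gets the worst remaining rank
        for pos in sorted(drop_order, key=lambda q: scores[q]):
            ranks[surviving[pos]] = next_rank
            next_rank -= 1
        surviving = [f for q, f in enumerate(surviving)
                     if q not in set(drop_order)]
    return ImportanceRanking(names, ranks.astype(float), "msvm_rfe")


def adaboost_importance(table: pd.DataFrame, labels: np.ndarray,
                        n_rounds: int = 100,
                        rng_seed: int = 0) -> ImportanceRanking:
    """Selection-frequency importance from stump adaboost: the score of a
    feature is the number of boosting rounds whose stump split on it.

    The discrete-adaboost reweighting loop is explicit so every round
    contributes one selection; a stump that classifies the weighted sample
    perfectly absorbs the remaining rounds (the weights would no longer
    change)."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("adaboost importance requires binary labels")
    ysign = np.where(y == classes[0], -1.0, 1.0)
    n = len(y)
    w = np.full(n, 1.0 / n)
    freq = np.zeros(X.shape[1])
    rng = np.random.default_rng(rng_seed)
    for round_no in range(n_rounds):
        stump = DecisionTreeClassifier(
            max_depth=1, random_state=int(rng.integers(2 ** 31 - 1)))
        stump.fit(X, ysign, sample_weight=w)
        feat = stump.tree_.feature[0]
        pred = stump.predict(X)
        err = float(np.sum(w * (pred != ysign)))
        if feat < 0:
            feat = 0      # degenerate single-leaf stump
        if err <= 1e-12:
            freq[feat] += n_rounds - round_no
            break
        freq[feat] += 1
        err = min(err, 1.0 - 1e-12)
        alpha = 0.5 * np.log((1.0 - err) / err)
        w *= np.exp(-alpha * ysign * pred)
        w /= w.sum()
    return ImportanceRanking(list(table.columns), freq, "adaboost")
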