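"""Classifier training and repeated stratified cross-validated evaluation.

Preterm is the positive class throughout. Confusion counts are pooled over
the k folds of each repetition (fold-level sensitivity on 3–4 positives
would be quantized to 25% steps), then sensitivity / specificity / accuracy
are averaged across repetitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, normalize_features
from .records import PRETERM

__all__ = [
    "ClassifierConfig",
    "EvalResult",
    "StratificationError",
    "stratified_folds",
    "train_classifier",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
]


class StratificationError(ValueError):
    """A class has fewer members than folds: cannot guarantee both classes
    in every fold."""


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier variant in the evaluation sweep."""

    kind: str  # knn | svm | dt
    knn_k: int = 4
    knn_metric: str = "euclidean"
    svm_kernel: str = "poly"  # linear | rbf | poly
    svm_poly_degree: int = 3
    dt_max_splits: int = 6
    dt_min_leaf_size: int = 20
    tuning: str = "default"  # default | inner_search

    def __post_init__(self):
        if self.kind not in ("knn", "svm", "dt"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.dt_max_splits < 1 or self.dt_min_leaf_size < 1:
            raise ValueError("classifier hyperparameters must be >= 1")

    def describe(self) -> str:
        if self.kind == "knn":
            return f"kNN K={self.knn_k}"
        if self.kind == "svm":
            return f"SVM {self.svm_kernel}"
        return f"DT MLS={self.dt_min_leaf_size}"


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into k folds preserving class proportions.

    Per-class counts across folds differ by at most one; which folds carry
    the remainder is randomized. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise StratificationError(
                f"class {cls!r} has {idx.size} members but k={k}; cannot "
                f"guarantee both classes in every fold"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(idx.size, k)
        sizes = np.full(k, base)
        sizes[rng.permutation(k)[:rem]] += 1
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(k):
            folds[f].extend(idx[start[f]:stop[f]])
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


class _Model:
    """Trained model exposing predict() -> bool preterm and score() -> real
    (higher = more preterm-like)."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def score(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _KnnModel(_Model):
    """Majority vote over the K nearest neighbors; a tied vote is broken by
    the label of the single nearest neighbor."""

    def __init__(self, nn: NearestNeighbors, y: np.ndarray, k: int):
        self._nn, self._y, self._k = nn, y, k

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, idx = self._nn.kneighbors(X, n_neighbors=self._k)
        votes = self._y[idx]
        frac = votes.mean(axis=1)
        out = frac > 0.5
        tie = frac == 0.5
        out[tie] = votes[tie, 0].astype(bool)  # columns are distance-ordered
        return out

    def score(self, X: np.ndarray) -> np.ndarray:
        _, idx = self._nn.kneighbors(X, n_neighbors=self._k)
        return self._y[idx].mean(axis=1)


class _SklearnModel(_Model):
    def __init__(self, estimator, use_decision_function: bool):
        self._est = estimator
        self._use_df = use_decision_function

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict(X).astype(bool)

    def score(self, X: np.ndarray) -> np.ndarray:
        if self._use_df:
            return self._est.decision_function(X)
        classes = list(self._est.classes_)
        return self._est.predict_proba(X)[:, classes.index(True)]


def train_classifier(config: ClassifierConfig, X: np.ndarray, y: np.ndarray) -> _Model:
    """Fit one classifier. ``y`` is boolean (True = preterm) or a label array
    convertible to it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype != bool:
        y = y == PRETERM
    if y.all() or not y.any():
        raise ValueError("training set contains a single class")
    if config.kind == "knn":
        nn = NearestNeighbors(metric=config.knn_metric).fit(X)
        return _KnnModel(nn, y.astype(int), config.knn_k)
    if config.kind == "svm":
        est = SVC(kernel=config.svm_kernel, degree=config.svm_poly_degree,
                  gamma="scale", C=1.0)
        if config.tuning == "inner_search":
            grid = {"C": [0.1, 1.0, 10.0, 100.0]}
            if config.svm_kernel != "linear":
                grid["gamma"] = ["scale", 0.01, 0.1, 1.0]
            est = GridSearchCV(est, grid, cv=5, scoring="balanced_accuracy")
        est.fit(X, y)
        return _SklearnModel(est, use_decision_function=True)
    est = DecisionTreeClassifier(
        criterion="gini",
        max_leaf_nodes=config.dt_max_splits + 1,  # internal nodes = leaves - 1
        min_samples_leaf=config.dt_min_leaf_size,
        random_state=0,
    )
    est.fit(X, y)
    return _SklearnModel(est, use_decision_function=False)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy as percentages."""
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both classes must be present in the confusion table")
    se = tp / (tp + fn) * 100.0
    sp = tn / (tn + fp) * 100.0
    acc = (tp + tn) / (tp + tn + fp + fn) * 100.0
    return se, sp, acc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points (1−Sp, Se) and AUC by threshold sweep over unique scores.

    Tied scores collapse to one threshold step; AUC is the trapezoidal area,
    which equals the Mann–Whitney concordance with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == PRETERM
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last index of each run of equal scores
    last = np.flatnonzero(np.diff(s) != 0)
    keep = np.concatenate([last, [s.size - 1]])
    tpr = np.concatenate([[0.0], tps[keep] / n_pos])
    fpr = np.concatenate([[0.0], fps[keep] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvalResult:
    config: ClassifierConfig
    channel: str
    per_repetition: list[dict] = field(default_factory=list)  # TP/FN/TN/FP
    se_mean: float = 0.0
    sp_mean: float = 0.0
    acc_mean: float = 0.0
    se_sd: float = 0.0
    sp_sd: float = 0.0
    acc_sd: float = 0.0
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = 0.0
    seeds: list[int] = field(default_factory=list)
    normalization: str = "global"

    def to_json(self) -> str:
        payload = asdict(self)
        payload["config"] = asdict(self.config)
        return json.dumps(payload, indent=2)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def cross_validate(
    config: ClassifierConfig,
    matrix: FeatureMatrix,
    k: int = 10,
    repetitions: int = 30,
    base_seed: int = 0,
    normalization: str = "global",
) -> EvalResult:
    """Repeated stratified k-fold evaluation.

    Repetition ``i`` uses seed ``base_seed + i`` for its folds. Within a
    repetition the confusion counts of all k held-out folds are pooled; the
    summary statistics are the mean and SD of the per-repetition pooled
    metrics. ROC scores come from the out-of-fold scores of the first
    repetition.

    ``normalization="global"`` expects an already-normalized matrix;
    ``"train_only"`` z-scores inside each fold using training rows only.
    """
    if normalization == "global":
        if not matrix.normalized:
            matrix = normalize_features(matrix, mode="global")
    elif normalization != "train_only":
        raise ValueError(f"unknown normalization {normalization!r}")
    y = matrix.labels == PRETERM
    result = EvalResult(config=config, channel=matrix.channel,
                        normalization=normalization)
    per_se, per_sp, per_acc = [], [], []
    roc_scores = np.zeros(len(y))
    for rep in range(repetitions):
        seed = base_seed + rep
        result.seeds.append(seed)
        folds = stratified_folds(matrix.labels, k=k, seed=seed)
        tp = fn = tn = fp = 0
        for f, test_idx in enumerate(folds):
            train_idx = np.concatenate([folds[g] for g in range(k) if g != f])
            if normalization == "train_only":
                norm = normalize_features(matrix, mode="train_only",
                                          train_indices=train_idx)
                X = norm.X
            else:
                X = matrix.X
            model = train_classifier(config, X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            truth = y[test_idx]
            tp += int(np.sum(pred & truth))
            fn += int(np.sum(~pred & truth))
            tn += int(np.sum(~pred & ~truth))
            fp += int(np.sum(pred & ~truth))
            if rep == 0:
                roc_scores[test_idx] = model.score(X[test_idx])
        result.per_repetition.append({"TP": tp, "FN": fn, "TN": tn, "FP": fp})
        se, sp, acc = confusion_metrics(tp, fn, tn, fp)
        per_se.append(se)
        per_sp.append(sp)
        per_acc.append(acc)
    result.se_mean = float(np.mean(per_se))
    result.sp_mean = float(np.mean(per_sp))
    result.acc_mean = float(np.mean(per_acc))
    result.se_sd = float(np.std(per_se, ddof=1)) if repetitions > 1 else 0.0
    result.sp_sd = float(np.std(per_sp, ddof=1)) if repetitions > 1 else 0.0
    result.acc_sd = float(np.std(per_acc, ddof=1)) if repetitions > 1 else 0.0
    result.roc_points, result.auc = roc_auc(roc_scores, y)
    return result
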