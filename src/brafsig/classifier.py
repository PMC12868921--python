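"""BAG label-transfer classifier.

To reproduce activity-group labels in external cohorts, a radial-basis
SVM is trained on the labelled reference cohort: an 80/20 stratified
split, a pairwise-correlation redundancy filter, random-forest importance
ranking, and stepwise feature selection under k-fold cross-validation.
External cohorts must be z-scored per gene before prediction so features
are comparable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import ExpressionMatrix, GroupAssignment

DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-7, 4, 2))  # 2^-7 .. 2^3
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-3, 8, 2))  # 2^-3 .. 2^7


def stratified_partition(
    labels: pd.Series, train_frac: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic per-class proportional train/test split.

    Every class contributes round(train_frac * n_class) training samples
    (clamped so both sides keep at least one sample); classes with a
    single sample are rejected.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(set(labels)):
        ids = sorted(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has only {len(ids)} sample(s); cannot split")
        order = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in order[:n_train])
        test.extend(ids[i] for i in order[n_train:])
    return sorted(train), sorted(test)


def redundancy_filter(matrix: ExpressionMatrix, cutoff: float = 0.8) -> list[str]:
    """Greedy elimination of highly correlated genes.

    While any retained pair has absolute Pearson correlation above the
    cutoff, the member of the worst (most correlated) pair with the larger
    mean absolute correlation to all other retained genes is removed;
    ties break lexicographically.  The survivors contain no pair with
    |r| > cutoff.
    """
    genes = list(matrix.values.index)
    if len(genes) < 2:
        return genes
    corr = np.corrcoef(matrix.values.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    retained = list(range(len(genes)))
    while True:
        sub = np.abs(corr[np.ix_(retained, retained)])
        if sub.size == 0 or sub.max() <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        gi, gj = retained[i], retained[j]
        mean_i = sub[i].sum() / (len(retained) - 1)
        mean_j = sub[j].sum() / (len(retained) - 1)
        if mean_i > mean_j:
            drop = gi
        elif mean_j > mean_i:
            drop = gj
        else:
            drop = gi if genes[gi] > genes[gj] else gj
        retained.remove(drop)
    return [genes[i] for i in retained]


def rank_features_rf(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
) -> list[str]:
    """Random-forest mean impurity-decrease importance ranking, descending
    (lexicographic tie-break); deterministic given the seed."""
    X = matrix.values[labels.index].to_numpy().T
    y = labels.to_numpy()
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least two classes to rank features")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    imp = pd.Series(rf.feature_importances_, index=matrix.values.index)
    order = sorted(imp.index, key=lambda g: (-imp[g], g))
    return list(order)


@dataclass
class ClassifierModel:
    """Trained RBF-SVM with its selection trace and training metadata."""

    features: tuple[str, ...]
    svc: SVC
    classes: tuple[str, ...]
    cv_trace: pd.DataFrame  # columns: size, cv_accuracy, C, gamma
    seed: int
    folds: int
    gamma_grid: tuple[float, ...]
    c_grid: tuple[float, ...]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int,
    class_weight,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, val_idx in skf.split(X, y):
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[val_idx]) == y[val_idx]).sum())
    return correct / len(y)


def stepwise_svm(
    matrix: ExpressionMatrix,
    ranked_features: Sequence[str],
    labels: pd.Series,
    folds: int = 5,
    seed: int = 0,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    class_weight: str | None = "balanced",
    max_features: int | None = None,
) -> ClassifierModel:
    """Stepwise feature selection with an RBF-SVM tuned by k-fold CV.

    For each prefix of the importance-ranked feature list, the (C, gamma)
    grid is scanned and the best cross-validated accuracy recorded; the
    selected model is the smallest prefix attaining the maximal CV
    accuracy (first-maximum rule), refit on the full training set with its
    best hyper-parameters.  Inverse-frequency class weights protect
    minority groups by default.
    """
    y = labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count {counts.min()}"
        )
    ranked = list(ranked_features)
    if max_features is not None:
        ranked = ranked[:max_features]

    rows = []
    per_size_best: list[tuple[float, float, float]] = []  # (acc, C, gamma)
    Xfull = matrix.values.loc[ranked, labels.index].to_numpy().T
    for size in range(1, len(ranked) + 1):
        X = Xfull[:, :size]
        best = (-1.0, None, None)
        for C in c_grid:
            for gamma in gamma_grid:
                acc = _cv_accuracy(X, y, C, gamma, folds, seed, class_weight)
                if acc > best[0]:
                    best = (acc, C, gamma)
        per_size_best.append(best)
        rows.append((size, best[0], best[1], best[2]))
    trace = pd.DataFrame(rows, columns=["size", "cv_accuracy", "C", "gamma"])
    best_size = int(trace.loc[trace["cv_accuracy"].idxmax(), "size"])  # first max
    acc, C, gamma = per_size_best[best_size - 1]
    features = tuple(ranked[:best_size])
    svc = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
    svc.fit(Xfull[:, :best_size], y)
    return ClassifierModel(
        features=features,
        svc=svc,
        classes=tuple(sorted(set(y.tolist()))),
        cv_trace=trace,
        seed=seed,
        folds=folds,
        gamma_grid=tuple(gamma_grid),
        c_grid=tuple(c_grid),
    )


def evaluate_model(
    model: ClassifierModel, matrix: ExpressionMatrix, labels: pd.Series
) -> dict:
    """Confusion matrix, per-class one-vs-rest sensitivity/specificity,
    and overall accuracy on a held-out set."""
    unseen = set(labels) - set(model.classes)
    if unseen:
        raise ValueError(f"test labels contain unseen classes: {sorted(unseen)}")
    pred = predict_labels(model, matrix).labels.loc[labels.index]
    classes = list(model.classes)
    cm = confusion_matrix(labels.to_numpy(), pred.to_numpy(), labels=classes)
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    per_class = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[cls] = {
            "sensitivity": float(tp / (tp + fn)) if tp + fn else None,
            "specificity": float(tn / (tn + fp)) if tn + fp else None,
        }
    return {
        "accuracy": accuracy,
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
        "per_class": per_class,
    }


def predict_labels(model: ClassifierModel, matrix: ExpressionMatrix) -> GroupAssignment:
    """Predict labels without the scale check (internal / held-out use)."""
    missing = [g for g in model.features if g not in matrix.values.index]
    if missing:
        raise ValueError(f"matrix lacks model features: {missing}")
    X = matrix.values.loc[list(model.features)].to_numpy().T
    pred = model.svc.predict(X)
    return GroupAssignment(
        pd.Series(pred, index=matrix.sample_ids), tuple(model.classes)
    )


def apply_model(model: ClassifierModel, external: ExpressionMatrix) -> GroupAssignment:
    """Assign BAG labels to an external cohort.

    The external matrix must be declared z-scored per gene (the training
    convention); a wrong scale flag or missing model features abort
    before prediction.
    """
    if external.scale != "zscore_gene":
        raise ValueError(
            f"external matrix must be z-scored per gene before classification, "
            f"got scale={external.scale!r}"
        )
    return predict_labels(model, external)
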