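"""Incremental feature selection (IFS) over a random-forest classifier.

Given an mRMR-ranked feature list, nested subsets S_1 c S_2 c ... are formed
by adding features one at a time from the top of the ranking. Each subset is
scored by stratified 10-fold cross-validation of a random forest, pooling the
test-fold confusion counts, and the subset with the best Matthews correlation
coefficient (MCC) is selected (ties toward fewer features). The chosen subset
is then refit on the full training set and evaluated once on held-out data.

The reference forest configuration mirrors the Weka 3.6 RandomForest
defaults under which the method was characterized: 10 unpruned trees,
floor(log2(M)) + 1 candidate features per split. Modern library defaults
(100 trees, sqrt(M)) are available via :meth:`ClassifierConfig.modern`.

Metrics from pooled confusion counts (TP, FP, TN, FN):

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Ac  = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a factor of the denominator vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .dataset import feature_category, FEATURE_CATEGORIES
from .errors import StratificationError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


class Metrics(NamedTuple):
    sn: float
    sp: float
    ac: float
    mcc: float


def compute_metrics(cc: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if cc.total == 0:
        raise ValidationError("cannot compute metrics on an empty evaluation")
    tp, fp, tn, fn = (float(v) for v in (cc.tp, cc.fp, cc.tn, cc.fn))
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    ac = (tp + tn) / cc.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return Metrics(sn=sn, sp=sp, ac=ac, mcc=mcc)


@dataclass(frozen=True)
class IFSRecord:
    """Cross-validated performance of the top-k feature subset."""

    k: int
    sn: float
    sp: float
    ac: float
    mcc: float


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest and cross-validation configuration.

    ``n_trees=10`` and the ``floor(log2 M) + 1`` features-per-split rule are
    the Weka 3.6 reference defaults; trees are fully grown and unpruned.
    """

    n_trees: int = 10
    features_per_split: str = "log2plus1"  # or "sqrt"
    seed: int = 0
    folds: int = 10

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")

    @classmethod
    def modern(cls, seed: int = 0, folds: int = 10) -> "ClassifierConfig":
        return cls(n_trees=100, features_per_split="sqrt", seed=seed, folds=folds)

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)

    def make_classifier(self, n_features: int) -> RandomForestClassifier:
        if self.features_per_split == "log2plus1":
            m = min(n_features, int(math.log2(n_features)) + 1)
        elif self.features_per_split == "sqrt":
            m = "sqrt"
        else:
            raise ValidationError(
                f"unknown features_per_split rule {self.features_per_split!r}"
            )
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=m,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )


def _subset(X: np.ndarray, feature_subset: Sequence[int]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    idx = np.asarray(feature_subset, dtype=int)
    if idx.size == 0:
        raise ValidationError("feature subset must be non-empty")
    if idx.min() < 0 or idx.max() >= X.shape[1]:
        raise IndexError("feature subset outside the matrix columns")
    return X[:, idx]


def crossvalidate(
    X: np.ndarray,
    y: Sequence[int],
    feature_subset: Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
) -> ConfusionCounts:
    """Stratified k-fold cross-validation pooling test-fold confusion counts.

    Fold assignment is seeded; every sample is tested exactly once.
    """
    y = np.asarray(y).astype(int)
    Xs = _subset(X, feature_subset)
    class_counts = np.bincount(y)
    if (class_counts[class_counts > 0] < config.folds).any():
        raise StratificationError(
            f"every class needs >= {config.folds} samples for "
            f"{config.folds}-fold stratification"
        )
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(Xs, y):
        clf = config.make_classifier(Xs.shape[1])
        clf.fit(Xs[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(Xs[test_idx])
    return ConfusionCounts.from_predictions(y, pred)


def run_ifs(
    X: np.ndarray,
    y: Sequence[int],
    ranking: Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
    k_values: Sequence[int] | None = None,
) -> list[IFSRecord]:
    """Score nested top-k subsets along a ranked feature list.

    By default every k from 1 to len(ranking) is evaluated; ``k_values``
    restricts the sweep (e.g. every 10th k) for cheaper runs.
    """
    ranking = list(ranking)
    if len(set(ranking)) != len(ranking):
        raise ValidationError("ranking contains duplicate feature indices")
    ks = list(k_values) if k_values is not None else list(range(1, len(ranking) + 1))
    records = []
    for k in ks:
        if not 1 <= k <= len(ranking):
            raise ValidationError(f"k={k} outside 1..{len(ranking)}")
        cc = crossvalidate(X, y, ranking[:k], config)
        m = compute_metrics(cc)
        records.append(IFSRecord(k=k, sn=m.sn, sp=m.sp, ac=m.ac, mcc=m.mcc))
    return records


def select_optimal(table: Sequence[IFSRecord]) -> IFSRecord:
    """The record with maximal MCC; ties resolve to the smallest k."""
    if not table:
        raise ValidationError("empty IFS table")
    return min(table, key=lambda r: (-r.mcc, r.k))


def evaluate_holdout(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_test: np.ndarray,
    y_test: Sequence[int],
    feature_subset: Sequence[int],
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[ConfusionCounts, Metrics]:
    """Fit once on the full training set (restricted to the subset) and
    score the held-out test set."""
    clf = config.make_classifier(len(feature_subset))
    clf.fit(_subset(X_train, feature_subset), np.asarray(y_train).astype(int))
    pred = clf.predict(_subset(X_test, feature_subset))
    cc = ConfusionCounts.from_predictions(np.asarray(y_test).astype(int), pred)
    return cc, compute_metrics(cc)


def categorize_features(
    indices: Sequence[int], lambda_per_property: int = 50
) -> dict[str, int]:
    """Count feature indices (0-based) per category.

    Categories: aptamer frequency (mono+di composition), target frequency
    (amino-acid composition), and the five target property blocks. Counts sum
    to the number of indices.
    """
    counts = {cat: 0 for cat in FEATURE_CATEGORIES}
    for idx in indices:
        counts[feature_category(int(idx), lambda_per_property)] += 1
    return counts


def ifs_table_to_frame(records: Sequence[IFSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [r.k for r in records],
            "Sn": [r.sn for r in records],
            "Sp": [r.sp for r in records],
            "Ac": [r.ac for r in records],
            "MCC": [r.mcc for r in records],
        }
    )


def plot_ifs_curve(records: Sequence[IFSRecord], path: str | Path) -> None:
    """Render the MCC-versus-k curve with the optimum marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = select_optimal(records)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot([r.k for r in records], [r.mcc for r in records], lw=1.2)
    ax.axvline(best.k, color="crimson", ls="--", lw=0.8)
    ax.annotate(
        f"k={best.k}, MCC={best.mcc:.4f}",
        xy=(best.k, best.mcc),
        xytext=(5, 5),
        textcoords="offset points",
        fontsize=8,
    )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated MCC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
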