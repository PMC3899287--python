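"""Feature ranking by maximum relevance (MaxRel) and
minimum-redundancy-maximum-relevance (mRMR).

Continuous composition features are discretized per feature into three states
with cut points at mean +/- alpha*SD (alpha = 1, computed on the data being
ranked); mutual information between discrete series is then estimated with
plug-in (maximum-likelihood) probabilities and the natural logarithm.

MaxRel sorts features by I(f, c), the mutual information with the class
label. mRMR selects greedily: the first feature maximizes I(f, c); each
subsequent one maximizes

    I(f, c) - (1/m) * sum_{g in selected} I(f, g)

over the not-yet-selected features, where m is the number already selected.
Ties break toward the smaller feature index, making both rankings fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class DiscretizationPolicy:
    """Per-feature discretization into ``n_states`` bins.

    Cut points are placed symmetrically at mean + alpha*SD*linspace(-1, 1,
    n_states-1); the default (3 states, alpha=1) cuts at mean - SD and
    mean + SD.
    """

    n_states: int = 3
    alpha: float = 1.0

    def __post_init__(self):
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if not self.alpha > 0:
            raise ValidationError("alpha must be > 0")

    def discretize(self, X: np.ndarray) -> np.ndarray:
        """Discretize columns of X into integer states 0..n_states-1."""
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        offsets = np.linspace(-1.0, 1.0, self.n_states - 1)
        out = np.zeros(X.shape, dtype=np.int64)
        for off in offsets:
            out += X > (mean + self.alpha * sd * off)
        return out


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information (nats) between two discrete series.

    Zero-count joint cells contribute nothing; the estimate is non-negative
    and symmetric in its arguments.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("x and y must be equal-length non-empty 1-D series")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def _mi_matrix(D: np.ndarray) -> np.ndarray:
    """Pairwise MI (nats) between all columns of an integer state matrix.

    Joint contingencies for every column pair are accumulated with one-hot
    matrix products, so the cost is a handful of (k x n)(n x k) multiplies.
    """
    n, k = D.shape
    states = int(D.max()) + 1
    onehots = [(D == s).astype(float) for s in range(states)]
    marg = np.stack([oh.mean(axis=0) for oh in onehots])  # (states, k)
    mi = np.zeros((k, k))
    for a in range(states):
        for b in range(states):
            pj = onehots[a].T @ onehots[b] / n  # (k, k) joint P(col_i=a, col_j=b)
            ind = np.outer(marg[a], marg[b])
            mask = pj > 0
            contrib = np.zeros_like(pj)
            contrib[mask] = pj[mask] * np.log(pj[mask] / ind[mask])
            mi += contrib
    return mi


def _check_inputs(X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    c = np.asarray(c)
    if X.ndim != 2 or X.shape[0] != c.shape[0]:
        raise ValidationError("X must be 2-D with one row per label")
    if np.unique(c).size < 2:
        raise ValidationError("labels contain a single class; relevance undefined")
    return X, c


def rank_maxrel(
    X: np.ndarray,
    c: Sequence[int],
    policy: DiscretizationPolicy = DiscretizationPolicy(),
) -> list[tuple[int, float]]:
    """Rank features by relevance I(f, c), descending; ties by ascending index."""
    X, c = _check_inputs(X, np.asarray(c))
    D = policy.discretize(X)
    rel = np.array([mutual_information(D[:, j], c) for j in range(D.shape[1])])
    order = np.lexsort((np.arange(rel.size), -rel))
    return [(int(j), float(rel[j])) for j in order]


def rank_mrmr(
    X: np.ndarray,
    c: Sequence[int],
    policy: DiscretizationPolicy = DiscretizationPolicy(),
) -> list[tuple[int, float]]:
    """Greedy mRMR ranking of all features.

    Returns (feature index, selection-time score) in selection order; the
    score of the first feature is its relevance, thereafter relevance minus
    mean redundancy with the already-selected set.
    """
    X, c = _check_inputs(X, np.asarray(c))
    D = policy.discretize(X)
    k = D.shape[1]
    # class labels appended as an extra column so one matrix covers both
    # feature-feature redundancy and feature-class relevance
    _, ci = np.unique(c, return_inverse=True)
    full = np.column_stack([D, ci])
    mi = _mi_matrix(full)
    rel = mi[:k, k]
    feat_mi = mi[:k, :k]

    selected: list[tuple[int, float]] = []
    remaining = np.ones(k, dtype=bool)
    red_sum = np.zeros(k)
    for step in range(k):
        if step == 0:
            scores = rel.copy()
        else:
            scores = rel - red_sum / step
        scores[~remaining] = -np.inf
        best = int(np.argmax(scores))  # argmax takes the lowest index on ties
        selected.append((best, float(scores[best])))
        remaining[best] = False
        red_sum += feat_mi[:, best]
    return selected


@dataclass(frozen=True)
class FeatureRanking:
    """MaxRel and mRMR orderings of the same feature set."""

    maxrel: list[tuple[int, float]]
    mrmr: list[tuple[int, float]]

    @classmethod
    def compute(
        cls,
        X: np.ndarray,
        c: Sequence[int],
        policy: DiscretizationPolicy = DiscretizationPolicy(),
    ) -> "FeatureRanking":
        return cls(maxrel=rank_maxrel(X, c, policy), mrmr=rank_mrmr(X, c, policy))

    def mrmr_indices(self) -> list[int]:
        return [j for j, _ in self.mrmr]

    def to_frames(
        self, feature_names: Sequence[str] | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Tabulate both rankings (rank, feature index, name, score)."""
        frames = []
        for ranking in (self.maxrel, self.mrmr):
            df = pd.DataFrame(
                {
                    "rank": np.arange(1, len(ranking) + 1),
                    "feature_index": [j for j, _ in ranking],
                    "score": [s for _, s in ranking],
                }
            )
            if feature_names is not None:
                df.insert(2, "feature_name", [feature_names[j] for j, _ in ranking])
            frames.append(df)
        return frames[0], frames[1]

    def write_tsv(
        self,
        maxrel_path: str | Path,
        mrmr_path: str | Path,
        feature_names: Sequence[str] | None = None,
        header_lines: Sequence[str] = (),
    ) -> None:
        maxrel_df, mrmr_df = self.to_frames(feature_names)
        for df, path in ((maxrel_df, maxrel_path), (mrmr_df, mrmr_path)):
            with open(path, "w", encoding="utf-8") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, sep="\t", index=False)
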