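"""Assembly of labelled pair feature matrices.

Positive pairs come from curated interactions; negatives are drawn uniformly
at random from the (aptamer x target) grid excluding the positives, at a 3:1
negative:positive ratio. The labelled set is then split 80/20 into train and
test parts, stratified by label so both parts keep the 1:3 class ratio.

The joint feature vector of a pair is the 20-component aptamer composition
block followed by the 270-component target block — 290 components in a frozen
order, so that ranked feature indices are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .aptamer_encoder import APTAMER_FEATURE_NAMES
from .errors import CapacityError, ReferentialIntegrityError, StratificationError
from .sequence_io import PairLabel
from .target_encoder import PseAACParams, target_feature_names

#: the seven feature categories, in block order
FEATURE_CATEGORIES = (
    "aptamer frequency",
    "target frequency",
    "target polarity",
    "target codon diversity",
    "target electrostatic charge",
    "target molecular volume",
    "target secondary structure",
)


def pair_feature_names(params: PseAACParams = PseAACParams()) -> list[str]:
    """The 290 column names: aptamer block then target block."""
    return list(APTAMER_FEATURE_NAMES) + target_feature_names(params)


def feature_category(index: int, lambda_per_property: int = 50) -> str:
    """Map a 0-based feature index to one of the seven categories."""
    lam = lambda_per_property
    n_total = 40 + 5 * lam
    if not 0 <= index < n_total:
        raise IndexError(f"feature index {index} outside [0, {n_total})")
    if index < 20:
        return FEATURE_CATEGORIES[0]
    if index < 40:
        return FEATURE_CATEGORIES[1]
    return FEATURE_CATEGORIES[2 + (index - 40) // lam]


@dataclass(frozen=True)
class PairFeatureVector:
    """One encoded pair: identity, 290 ordered features, binary label."""

    pair: PairLabel
    features: np.ndarray
    label: int


@dataclass(frozen=True)
class DatasetSplit:
    """A stratified train/test partition of encoded pairs."""

    train: list[PairFeatureVector]
    test: list[PairFeatureVector]
    seed: int

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (X_train, y_train, X_test, y_test) as arrays."""
        return (
            np.array([v.features for v in self.train]),
            np.array([v.label for v in self.train]),
            np.array([v.features for v in self.test]),
            np.array([v.label for v in self.test]),
        )


def sample_negatives(
    positives: Sequence[PairLabel],
    aptamer_ids: Sequence[str],
    targets_ids: Sequence[str],
    ratio: float = 3.0,
    seed: int = 0,
) -> list[PairLabel]:
    """Draw round(ratio * n_positive) negative pairs uniformly without
    replacement from the id grid, disjoint from the positives.
    """
    n_neg = int(round(ratio * len(positives)))
    if n_neg == 0:
        return []
    pos_keys = {p.key() for p in positives}
    grid = [
        (a, t)
        for a in aptamer_ids
        for t in targets_ids
        if (a, t) not in pos_keys
    ]
    if len(grid) < n_neg:
        raise CapacityError(
            f"only {len(grid)} non-positive pairs available, {n_neg} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(grid), size=n_neg, replace=False)
    return [PairLabel(grid[i][0], grid[i][1], 0) for i in sorted(chosen)]


def split_dataset(
    samples: Sequence,
    test_fraction: float = 0.2,
    seed: int = 0,
    disjoint_targets: bool = False,
) -> DatasetSplit:
    """Stratified train/test split of labelled samples (anything with .label).

    With 725 positives and 2175 negatives at fraction 0.2 this yields exactly
    580/1740 training and 145/435 testing samples.

    ``disjoint_targets`` switches to a stricter grouped split in which no
    target id occurs on both sides (samples must carry ``.pair.target_id``);
    class stratification is then only approximate and the exact-count
    guarantee no longer holds.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    samples = list(samples)
    labels = [s.label for s in samples]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts * test_fraction).min() < 1:
        raise StratificationError(
            "each class needs at least one sample on both sides of the split"
        )
    if disjoint_targets:
        groups = [s.pair.target_id for s in samples]
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        train_idx, test_idx = next(splitter.split(samples, labels, groups))
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        if len({s.label for s in train}) < 2 or len({s.label for s in test}) < 2:
            raise StratificationError(
                "target-disjoint split left a side with a single class"
            )
    else:
        train, test = train_test_split(
            samples,
            test_size=test_fraction,
            stratify=labels,
            random_state=seed,
            shuffle=True,
        )
    return DatasetSplit(train=train, test=test, seed=seed)


def build_matrix(
    pairs: Sequence[PairLabel],
    aptamer_blocks: pd.DataFrame,
    target_blocks: pd.DataFrame,
) -> list[PairFeatureVector]:
    """Join encodings into pair vectors, preserving pair order.

    ``aptamer_blocks`` / ``target_blocks`` are the batch-encoder outputs
    indexed by id. Unresolvable ids raise.
    """
    vectors = []
    for p in pairs:
        if p.aptamer_id not in aptamer_blocks.index:
            raise ReferentialIntegrityError(f"unknown aptamer id {p.aptamer_id!r}")
        if p.target_id not in target_blocks.index:
            raise ReferentialIntegrityError(f"unknown target id {p.target_id!r}")
        feats = np.concatenate(
            [
                aptamer_blocks.loc[p.aptamer_id].to_numpy(),
                target_blocks.loc[p.target_id].to_numpy(),
            ]
        )
        vectors.append(PairFeatureVector(pair=p, features=feats, label=p.label))
    return vectors


def vectors_to_frame(
    vectors: Sequence[PairFeatureVector],
    params: PseAACParams = PseAACParams(),
) -> pd.DataFrame:
    """Tabulate pair vectors: id columns, 290 named features, label column."""
    names = pair_feature_names(params)
    data = (
        np.array([v.features for v in vectors])
        if vectors
        else np.empty((0, len(names)))
    )
    df = pd.DataFrame(data, columns=names)
    df.insert(0, "aptamer_id", [v.pair.aptamer_id for v in vectors])
    df.insert(1, "target_id", [v.pair.target_id for v in vectors])
    df["label"] = [v.label for v in vectors]
    return df
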