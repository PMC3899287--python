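"""End-to-end convenience wiring: encode -> rank -> IFS -> holdout.

These helpers chain the module surfaces without adding behaviour of their
own; the CLI and scripted analyses use them so results stay identical
whichever entry point is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aptamer_encoder import encode_aptamers
from .dataset import (
    DatasetSplit,
    PairFeatureVector,
    build_matrix,
    split_dataset,
)
from .ifs import (
    ClassifierConfig,
    ConfusionCounts,
    IFSRecord,
    Metrics,
    categorize_features,
    evaluate_holdout,
    run_ifs,
    select_optimal,
)
from .mrmr import DiscretizationPolicy, FeatureRanking
from .sequence_io import AptamerRecord, PairLabel, TargetRecord
from .target_encoder import PropertyTable, PseAACParams, encode_targets


def encode_pairs(
    aptamers: Sequence[AptamerRecord],
    targets: Sequence[TargetRecord],
    pairs: Sequence[PairLabel],
    table: PropertyTable | None = None,
    params: PseAACParams = PseAACParams(),
) -> list[PairFeatureVector]:
    """Encode every pair into its 290-component vector (order preserved)."""
    apt_ids = {p.aptamer_id for p in pairs}
    tgt_ids = {p.target_id for p in pairs}
    apt_blocks = encode_aptamers([a for a in aptamers if a.id in apt_ids])
    tgt_blocks = encode_targets(
        [t for t in targets if t.id in tgt_ids], table, params
    )
    return build_matrix(pairs, apt_blocks, tgt_blocks)


@dataclass(frozen=True)
class PipelineResult:
    """Everything the ranked-selection pipeline produces on one split."""

    ranking: FeatureRanking
    ifs_table: list[IFSRecord]
    optimal: IFSRecord
    optimal_features: list[int]
    holdout_counts: ConfusionCounts
    holdout_metrics: Metrics
    category_counts: dict[str, int]


def run_pipeline(
    split: DatasetSplit,
    policy: DiscretizationPolicy = DiscretizationPolicy(),
    config: ClassifierConfig = ClassifierConfig(),
    k_values: Sequence[int] | None = None,
) -> PipelineResult:
    """mRMR-rank the training matrix, sweep IFS, pick the optimum, and score
    the held-out part with the optimal subset."""
    X_train, y_train, X_test, y_test = split.matrices()
    ranking = FeatureRanking.compute(X_train, y_train, policy)
    order = ranking.mrmr_indices()
    table = run_ifs(X_train, y_train, order, config, k_values=k_values)
    optimal = select_optimal(table)
    subset = order[: optimal.k]
    counts, metrics = evaluate_holdout(
        X_train, y_train, X_test, y_test, subset, config
    )
    return PipelineResult(
        ranking=ranking,
        ifs_table=table,
        optimal=optimal,
        optimal_features=subset,
        holdout_counts=counts,
        holdout_metrics=metrics,
        category_counts=categorize_features(subset),
    )


def split_encoded(
    vectors: Sequence[PairFeatureVector],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified split of already-encoded pair vectors."""
    return split_dataset(vectors, test_fraction=test_fraction, seed=seed)


def matrices_from_vectors(
    vectors: Sequence[PairFeatureVector],
) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([v.features for v in vectors]),
        np.array([v.label for v in vectors]),
    )
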