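"""Shared fixtures: small random records and the expensive planted-signal
recovery sweep (computed once per session, consumed by several test modules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from aptapair import (
    AptamerRecord,
    ClassifierConfig,
    FixtureSpec,
    TargetRecord,
    encode_pairs,
    generate_corpus,
    rank_mrmr,
    run_ifs,
    select_optimal,
)
from aptapair.pipeline import matrices_from_vectors

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_aptamer(rng):
    def make(length=50, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return AptamerRecord(
            f"apt-{length}", "".join(r.choice(list("ACGT"), length))
        )

    return make


@pytest.fixture
def random_target(rng):
    def make(length=80, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return TargetRecord(f"tgt-{length}", "".join(r.choice(list(AA), length)))

    return make


@dataclass(frozen=True)
class RecoveryRun:
    """One seeded planted-signal run: mRMR order, IFS optimum, planted columns."""

    mrmr_order: list[int]
    optimal_k: int
    informative: list[int]


N_RECOVERY_RUNS = 20
RECOVERY_MAX_K = 20  # planted count is 5; the IFS sweep covers 1..20


@pytest.fixture(scope="session")
def recovery_runs() -> list[RecoveryRun]:
    """Twenty seeded end-to-end runs on the default synthetic corpus.

    Each run generates a corpus with the five default planted rules, encodes
    all pairs, ranks features by mRMR, and sweeps IFS over k = 1..20 with the
    reference forest. Several modules assert recovery statistics on this
    shared sweep.
    """
    runs = []
    for seed in range(N_RECOVERY_RUNS):
        spec = FixtureSpec(seed=seed)
        aptamers, targets, pairs = generate_corpus(spec)
        vectors = encode_pairs(aptamers, targets, pairs)
        X, y = matrices_from_vectors(vectors)
        order = [j for j, _ in rank_mrmr(X, y)]
        table = run_ifs(
            X,
            y,
            order,
            ClassifierConfig(seed=seed),
            k_values=list(range(1, RECOVERY_MAX_K + 1)),
        )
        runs.append(
            RecoveryRun(
                mrmr_order=order,
                optimal_k=select_optimal(table).k,
                informative=spec.informative_indices(),
            )
        )
    return runs
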