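"""Aptamer encoding: mono- and dinucleotide composition.

Each aptamer of length L (DNA alphabet after U->T normalization) becomes a
20-component vector: the four base frequencies count(b)/L in the fixed order
(A, T/U, C, G), followed by the sixteen overlapping-dinucleotide frequencies
count(xy)/(L-1) in the fixed order AA, AC, AT, AG, CA, CC, CT, CG, TA, TC,
TT, TG, GA, GC, GT, GG. Overlapping windows make each block sum to exactly 1.
The component order is frozen because downstream feature rankings refer to
features by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequence_io import AptamerRecord

MONO_ORDER = "ATCG"
DI_ORDER = (
    "AA", "AC", "AT", "AG",
    "CA", "CC", "CT", "CG",
    "TA", "TC", "TT", "TG",
    "GA", "GC", "GT", "GG",
)
#: exported column names, T/U written jointly as in the composition listing
APTAMER_FEATURE_NAMES = (
    "A", "T/U", "C", "G",
    "AA", "AC", "AT/AU", "AG",
    "CA", "CC", "CT/CU", "CG",
    "TA/UA", "TC/UC", "TT/UU", "TG/UG",
    "GA", "GC", "GT/GU", "GG",
)

_MONO_INDEX = {b: i for i, b in enumerate(MONO_ORDER)}
_DI_INDEX = {d: i for i, d in enumerate(DI_ORDER)}


@dataclass(frozen=True)
class AptamerFeatureBlock:
    """Mono (4) and dinucleotide (16) composition of one aptamer."""

    mono: np.ndarray
    di: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.mono, self.di])


def encode_aptamer(record: AptamerRecord | str) -> AptamerFeatureBlock:
    """Encode one aptamer into its 20-component composition block."""
    seq = record.sequence if isinstance(record, AptamerRecord) else record
    L = len(seq)
    if L < 2:
        raise ValidationError(
            "aptamer shorter than 2 nt has no dinucleotide windows"
        )
    mono = np.zeros(4)
    di = np.zeros(16)
    for b in seq:
        mono[_MONO_INDEX[b]] += 1
    for i in range(L - 1):
        di[_DI_INDEX[seq[i : i + 2]]] += 1
    return AptamerFeatureBlock(mono=mono / L, di=di / (L - 1))


def encode_aptamers(records: Sequence[AptamerRecord]) -> pd.DataFrame:
    """Batch-encode aptamers into a DataFrame (rows = ids, 20 named columns)."""
    vectors = [encode_aptamer(rec).vector for rec in records]
    return pd.DataFrame(
        np.asarray(vectors) if vectors else np.empty((0, 20)),
        index=[rec.id for rec in records],
        columns=list(APTAMER_FEATURE_NAMES),
    )
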