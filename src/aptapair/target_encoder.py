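"""Protein-target encoding: amino-acid composition plus pseudo-amino-acid
composition (PseAAC).

A target of length ``L`` is represented by 270 numbers:

* 20 amino-acid occurrence frequencies ``f_u = count(u)/L`` (alphabetical
  one-letter order), and
* for each of five physicochemical property scales (polarity, codon
  diversity, electrostatic charge, molecular volume, secondary structure),
  the lambda = 50 sequence-order correlation factors

  .. math::

      \\theta_j = \\frac{1}{L-j} \\sum_{i=1}^{L-j}
                  \\bigl(H(R_{i+j}) - H(R_i)\\bigr)^2,  \\qquad j = 1..\\lambda

  where ``H`` is the property value standardized to mean 0 / SD 1 over the 20
  residues (population SD), folded into normalized pseudo-components

  .. math::

      p_{20+j} = \\frac{w\\,\\theta_j}{\\sum_{u=1}^{20} f_u
                 + w \\sum_{k=1}^{\\lambda} \\theta_k}

  with weight ``w = 0.05``.

The five scales are processed independently, so the pseudo block has
5 x 50 = 250 components. Each per-property (20 + lambda) PseAAC vector sums
to exactly 1; only its last lambda components are exported, the 20-component
head being replaced by the single raw-frequency block shared by all
properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, ValidationError
from .sequence_io import AMINO_ACIDS, TargetRecord

#: property order of the 250-component pseudo block (frozen; feature indices
#: downstream depend on it)
PROPERTY_NAMES = (
    "polarity",
    "codon_diversity",
    "electrostatic_charge",
    "molecular_volume",
    "secondary_structure",
)
#: short keys used in exported column names
PROPERTY_KEYS = ("polarity", "codondiv", "charge", "volume", "secstruct")

DEFAULT_LAMBDA = 50
DEFAULT_WEIGHT = 0.05

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def standardize_property(raw_scale: Sequence[float]) -> np.ndarray:
    """Standardize a 20-value property scale to mean 0 and SD 1.

    The 20 amino acids are the whole population of symbols, so the population
    standard deviation (divisor 20) is used. A constant scale has no spread
    and raises :class:`DegenerateScaleError`.
    """
    arr = np.asarray(raw_scale, dtype=float)
    if arr.shape != (20,):
        raise ValidationError(f"expected 20 scale values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("property scale contains non-finite values")
    sd = arr.std(ddof=0)
    if sd < 1e-12:
        raise DegenerateScaleError("constant property scale cannot be standardized")
    return (arr - arr.mean()) / sd


@dataclass(frozen=True)
class PropertyTable:
    """Five physicochemical scales over the 20 amino acids.

    ``raw`` and ``standardized`` are (5, 20) arrays, rows in
    :data:`PROPERTY_NAMES` order, columns in alphabetical amino-acid order.
    """

    names: tuple[str, ...]
    raw: np.ndarray
    standardized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (len(self.names), 20):
            raise ValidationError(
                f"property matrix shape {raw.shape} != ({len(self.names)}, 20)"
            )
        std = np.vstack([standardize_property(row) for row in raw])
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "standardized", std)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        """Load a table with columns amino_acid + one per property."""
        df = pd.read_csv(path, sep="\t", comment="#").set_index("amino_acid")
        df = df.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)]
        return cls(names=PROPERTY_NAMES, raw=df.to_numpy().T)


_DEFAULT_TABLE: PropertyTable | None = None


def load_property_table() -> PropertyTable:
    """Load the packaged Atchley-factor property table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("aptapair").joinpath("data/aa_property_scales.tsv")
        ) as path:
            _DEFAULT_TABLE = PropertyTable.from_tsv(path)
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class PseAACParams:
    """PseAAC hyper-parameters: tiers per property and sequence-order weight."""

    lambda_per_property: int = DEFAULT_LAMBDA
    weight: float = DEFAULT_WEIGHT

    def __post_init__(self):
        if self.lambda_per_property < 1:
            raise ValidationError("lambda_per_property must be >= 1")
        if not self.weight > 0:
            raise ValidationError("weight w must be > 0")


@dataclass(frozen=True)
class TargetFeatureBlock:
    """The 270-component encoding of one target.

    ``aac`` holds the 20 raw frequencies f_u/L; ``theta`` the (5, lambda)
    correlation factors; ``pse_components`` the (5, lambda) normalized
    pseudo-components. ``vector`` concatenates aac then the five per-property
    pseudo rows in :data:`PROPERTY_NAMES` order.
    """

    aac: np.ndarray
    theta: np.ndarray
    pse_components: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.aac, self.pse_components.ravel()])


def _residue_values(seq: str, scale: np.ndarray) -> np.ndarray:
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=np.intp, count=len(seq))
    return scale[idx]


def correlation_factor(seq: TargetRecord | str, h_std: np.ndarray, j: int) -> float:
    """j-th tier sequence-order correlation factor for one standardized scale.

    theta_j averages the squared difference of standardized property values
    between residues j positions apart; it is 0 on homopolymers and invariant
    under sequence reversal.
    """
    s = seq.sequence if isinstance(seq, TargetRecord) else seq
    L = len(s)
    if j < 1 or j >= L:
        raise ValidationError(f"tier j={j} must satisfy 1 <= j <= L-1 (L={L})")
    v = _residue_values(s, np.asarray(h_std, dtype=float))
    return float(np.mean((v[j:] - v[:-j]) ** 2))


def encode_target(
    seq: TargetRecord,
    table: PropertyTable | None = None,
    params: PseAACParams = PseAACParams(),
) -> TargetFeatureBlock:
    """Encode a protein target into its 20 + 5*lambda feature block."""
    table = table or load_property_table()
    lam, w = params.lambda_per_property, params.weight
    L = len(seq)
    if L <= lam:
        raise ValidationError(
            f"target {seq.id!r}: length {L} must exceed lambda={lam} "
            "to compute all correlation tiers"
        )
    counts = np.zeros(20)
    for ch in seq.sequence:
        counts[_AA_INDEX[ch]] += 1
    aac = counts / L

    n_props = len(table.names)
    theta = np.empty((n_props, lam))
    for p in range(n_props):
        v = _residue_values(seq.sequence, table.standardized[p])
        for j in range(1, lam + 1):
            theta[p, j - 1] = np.mean((v[j:] - v[:-j]) ** 2)

    # per-property normalization: sum(f_u) = 1, so denominator = 1 + w*sum(theta)
    denom = 1.0 + w * theta.sum(axis=1, keepdims=True)
    pse = w * theta / denom
    return TargetFeatureBlock(aac=aac, theta=theta, pse_components=pse)


def target_feature_names(params: PseAACParams = PseAACParams()) -> list[str]:
    """Deterministic column names for the 270-component target block."""
    names = [f"AAC_{aa}" for aa in AMINO_ACIDS]
    for key in PROPERTY_KEYS:
        names.extend(
            f"PSE_{key}_{j}" for j in range(1, params.lambda_per_property + 1)
        )
    return names


def encode_targets(
    records: Sequence[TargetRecord],
    table: PropertyTable | None = None,
    params: PseAACParams = PseAACParams(),
) -> pd.DataFrame:
    """Batch-encode targets into a DataFrame (rows = ids, 270 named columns)."""
    vectors = [encode_target(rec, table, params).vector for rec in records]
    return pd.DataFrame(
        np.asarray(vectors) if vectors else np.empty((0, 20 + 5 * params.lambda_per_property)),
        index=[rec.id for rec in records],
        columns=target_feature_names(params),
    )
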