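"""Synthetic corpora with a planted, composition-based interaction signal.

The generator emulates the statistical shape of a curated aptamer-target
interaction study: a few hundred random aptamers (40-100 nt, uniform over
ACGT), a smaller panel of random protein targets (uniform over the 20
residues, long enough for all PseAAC tiers), positive pairs, and 3:1
randomly-paired negatives.

Interaction is not random: a set of planted rules, each a threshold on a
true composition feature (e.g. "aptamer G fraction > 0.30" or "target lysine
frequency > 0.06"), defines rule-satisfying grid cells, and a pair is
"interaction-prone" when all rules hold (a conjunction, so every planted
feature is individually necessary and therefore individually informative;
``rules_required`` relaxes this to a count threshold). Thresholds in the
default rules sit about one standard deviation above the expected
composition of a uniform random sequence, which keeps the predicate sharp
rather than straddling the bulk of the composition distribution. With
signal strength s, each positive pair is drawn from the interaction-prone
cells with probability s (otherwise uniformly from the whole grid), and
symmetrically each negative from the non-prone cells. At s = 0 labels are
independent of every feature; at s = 1 the rule conjunction separates the
classes perfectly. Because the rules act on actual encoder features, feature
ranking and incremental selection have a checkable recovery target:
:meth:`FixtureSpec.informative_indices` lists the planted columns of the
290-feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .aptamer_encoder import DI_ORDER, MONO_ORDER
from .errors import CapacityError, ValidationError
from .sequence_io import (
    AMINO_ACIDS,
    AptamerRecord,
    PairLabel,
    TargetRecord,
    write_fasta,
    write_pairs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedRule:
    """A threshold predicate on one true composition feature.

    ``feature`` is "aptamer_mono:<base>", "aptamer_di:<dinucleotide>" or
    "target_aac:<residue>"; the rule holds when that composition fraction
    exceeds ``threshold``.
    """

    feature: str
    threshold: float

    def _parts(self) -> tuple[str, str]:
        kind, _, sym = self.feature.partition(":")
        if kind not in {"aptamer_mono", "aptamer_di", "target_aac"} or not sym:
            raise ValidationError(f"unknown planted-rule feature {self.feature!r}")
        return kind, sym

    @property
    def acts_on_aptamer(self) -> bool:
        return self._parts()[0].startswith("aptamer")

    def feature_index(self) -> int:
        """0-based column of this rule's feature in the 290-feature layout."""
        kind, sym = self._parts()
        if kind == "aptamer_mono":
            return MONO_ORDER.index(sym)
        if kind == "aptamer_di":
            return 4 + DI_ORDER.index(sym)
        return 20 + AMINO_ACIDS.index(sym)

    def evaluate(self, sequence: str) -> bool:
        """Apply the rule to the relevant sequence (aptamer or target)."""
        kind, sym = self._parts()
        if kind == "aptamer_mono":
            frac = sequence.count(sym) / len(sequence)
        elif kind == "aptamer_di":
            n = sum(
                1 for i in range(len(sequence) - 1) if sequence[i : i + 2] == sym
            )
            frac = n / (len(sequence) - 1)
        else:
            frac = sequence.count(sym) / len(sequence)
        return frac > self.threshold


def default_rules() -> tuple[PlantedRule, ...]:
    """One aptamer-side and one target-side rule, jointly required.

    Thresholds sit roughly one standard deviation above the composition
    expectation of a uniform random sequence (G fraction: 0.25 expected,
    ~0.05 SD at typical aptamer lengths; lysine frequency: 0.05 expected,
    ~0.02 SD), so each rule holds for a minority of sequences and the
    planted predicate is sharp.
    """
    return (
        PlantedRule("aptamer_mono:G", 0.30),
        PlantedRule("target_aac:K", 0.06),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus."""

    n_aptamers: int = 200
    n_targets: int = 50
    aptamer_length_range: tuple[int, int] = (40, 100)
    protein_length_range: tuple[int, int] = (60, 150)
    n_positive: int = 150
    negative_ratio: float = 3.0
    signal_rules: tuple[PlantedRule, ...] = field(default_factory=default_rules)
    #: how many rules a grid cell must satisfy to be interaction-prone;
    #: None means all of them (conjunction)
    rules_required: int | None = None
    signal_strength: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.protein_length_range[0] < 51:
            raise ValidationError(
                "protein lengths must exceed the PseAAC tier count (>= 51)"
            )
        if not 0 <= self.signal_strength <= 1:
            raise ValidationError("signal_strength must lie in [0, 1]")
        if self.n_positive > self.n_aptamers * self.n_targets:
            raise CapacityError("more positives requested than grid cells")

    def informative_indices(self) -> list[int]:
        """Sorted 0-based feature columns carrying the planted signal."""
        return sorted(r.feature_index() for r in self.signal_rules)


def _random_sequences(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    alphabet: str,
) -> list[str]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    letters = np.array(list(alphabet))
    return ["".join(letters[rng.integers(0, len(letters), size=int(L))]) for L in lengths]


def _mixture_sample(
    rng: np.random.Generator,
    preferred: np.ndarray,
    universe_size: int,
    n: int,
    strength: float,
    excluded: set[int],
) -> list[int]:
    """Draw n distinct cell indices: each with probability ``strength`` from
    the preferred pool, otherwise uniformly from the whole grid; ``excluded``
    cells are never drawn."""
    chosen: set[int] = set()
    pool = np.array([i for i in preferred if i not in excluded], dtype=int)
    pref_iter = iter(int(i) for i in rng.permutation(pool))
    out: list[int] = []
    for _ in range(n):
        from_pref = rng.random() < strength
        cell = None
        if from_pref:
            for cand in pref_iter:
                if cand not in chosen:
                    cell = cand
                    break
        if cell is None:
            # uniform over the full grid, rejecting collisions
            for _attempt in range(100 * universe_size):
                cand = int(rng.integers(0, universe_size))
                if cand not in chosen and cand not in excluded:
                    cell = cand
                    break
        if cell is None:
            raise CapacityError("cannot draw enough distinct pairs")
        chosen.add(cell)
        out.append(cell)
    return out


def generate_corpus(
    spec: FixtureSpec,
) -> tuple[list[AptamerRecord], list[TargetRecord], list[PairLabel]]:
    """Generate (aptamers, targets, labelled pairs) under ``spec``.

    Reproducible: the same spec (including seed) yields byte-identical
    sequences and pair lists.
    """
    rng = np.random.default_rng(spec.seed)
    apt_seqs = _random_sequences(rng, spec.n_aptamers, spec.aptamer_length_range, "ACGT")
    tgt_seqs = _random_sequences(
        rng, spec.n_targets, spec.protein_length_range, AMINO_ACIDS
    )
    aptamers = [
        AptamerRecord(f"apt{i:04d}", s, "DNA") for i, s in enumerate(apt_seqs)
    ]
    targets = [TargetRecord(f"tgt{i:04d}", s) for i, s in enumerate(tgt_seqs)]

    rules = spec.signal_rules
    apt_rules = [r for r in rules if r.acts_on_aptamer]
    tgt_rules = [r for r in rules if not r.acts_on_aptamer]
    apt_hits = np.array(
        [sum(r.evaluate(s) for r in apt_rules) for s in apt_seqs], dtype=int
    )
    tgt_hits = np.array(
        [sum(r.evaluate(s) for r in tgt_rules) for s in tgt_seqs], dtype=int
    )
    # pair rule score on the full grid; prone = required count of rules hold
    score = apt_hits[:, None] + tgt_hits[None, :]
    need = spec.rules_required if spec.rules_required is not None else len(rules)
    need = max(1, min(need, len(rules))) if rules else 1
    prone = (score >= need).ravel()
    if rules and prone.sum() < spec.signal_strength * spec.n_positive:
        # sampler falls back to uniform grid draws once the prone pool is
        # exhausted, which dilutes the planted signal below signal_strength
        logger.warning(
            "only %d interaction-prone cells for %d positives at strength "
            "%.2f; planted signal will be diluted",
            int(prone.sum()), spec.n_positive, spec.signal_strength,
        )
    n_grid = spec.n_aptamers * spec.n_targets

    n_neg = int(round(spec.negative_ratio * spec.n_positive))
    if spec.n_positive + n_neg > n_grid:
        raise CapacityError(
            f"grid of {n_grid} cells cannot host "
            f"{spec.n_positive} positives + {n_neg} negatives"
        )

    pos_cells = _mixture_sample(
        rng,
        np.flatnonzero(prone),
        n_grid,
        spec.n_positive,
        spec.signal_strength if rules else 0.0,
        excluded=set(),
    )
    neg_cells = _mixture_sample(
        rng,
        np.flatnonzero(~prone),
        n_grid,
        n_neg,
        spec.signal_strength if rules else 0.0,
        excluded=set(pos_cells),
    )

    def cell_to_pair(cell: int, label: int) -> PairLabel:
        a, t = divmod(cell, spec.n_targets)
        return PairLabel(aptamers[a].id, targets[t].id, label)

    pairs = [cell_to_pair(c, 1) for c in pos_cells] + [
        cell_to_pair(c, 0) for c in neg_cells
    ]
    return aptamers, targets, pairs


def write_corpus(
    aptamers: Sequence[AptamerRecord],
    targets: Sequence[TargetRecord],
    pairs: Sequence[PairLabel],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a corpus in the formats the readers consume; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "aptamers": outdir / "aptamers.fasta",
        "targets": outdir / "targets.fasta",
        "positives": outdir / "pairs_positive.tsv",
        "negatives": outdir / "pairs_negative.tsv",
    }
    write_fasta(aptamers, paths["aptamers"])
    write_fasta(targets, paths["targets"])
    write_pairs([p for p in pairs if p.label == 1], paths["positives"])
    write_pairs([p for p in pairs if p.label == 0], paths["negatives"])
    return paths
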