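"""Reading, validation and normalization of aptamer/protein sequences and pair lists.

Aptamers are single-stranded DNA or RNA; because uracil pairs like thymine the
two alphabets are collapsed by mapping every U to T, so downstream composition
features are computed over {A, C, G, T} regardless of the source chemistry.
Protein targets are kept over the 20 standard amino-acid letters; targets
shorter than 50 residues are dropped because composition and sequence-order
features are unreliable on very short chains.

Supported formats: multi-record FASTA (wrapped or unwrapped, via Biopython)
and a two-column tab-separated layout (id <TAB> sequence, no header). Pair
lists are tab-separated (aptamer_id, target_id) with the label assigned by
file provenance (a positives file and an optional negatives file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    FormatError,
    ReferentialIntegrityError,
    SequenceAlphabetError,
    ValidationError,
)

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGT")
#: symbols accepted on input before U->T normalization
NUCLEOTIDE_INPUT_ALPHABET = set("ACGTU")
#: the 20 standard amino acids, alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = set(AMINO_ACIDS)

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class AptamerRecord:
    """An identified aptamer sequence, normalized to the DNA alphabet."""

    id: str
    sequence: str  # over {A,C,G,T}
    source_alphabet: Literal["DNA", "RNA"] = "DNA"

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValidationError(
                f"aptamer {self.id!r}: length {len(self.sequence)} < 2 "
                "(dinucleotide composition needs at least one window)"
            )
        for pos, sym in enumerate(self.sequence):
            if sym not in NUCLEOTIDE_ALPHABET:
                raise SequenceAlphabetError(self.id, pos, sym, "ACGT")


@dataclass(frozen=True)
class TargetRecord:
    """An identified protein target sequence over the 20 standard residues."""

    id: str
    sequence: str

    def __post_init__(self):
        for pos, sym in enumerate(self.sequence):
            if sym not in AMINO_ACID_SET:
                raise SequenceAlphabetError(self.id, pos, sym, AMINO_ACIDS)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairLabel:
    """One labelled (aptamer, target) pair; label 1 = interacting."""

    aptamer_id: str
    target_id: str
    label: int

    def key(self) -> tuple[str, str]:
        return (self.aptamer_id, self.target_id)


def normalize_nucleotides(raw: str) -> tuple[str, str]:
    """Upper-case a raw nucleic-acid string and map U->T.

    Returns (normalized sequence, source alphabet). The map is idempotent:
    a DNA string passes through unchanged. Validation happens in
    :class:`AptamerRecord`.
    """
    upper = raw.upper()
    alphabet = "RNA" if "U" in upper else "DNA"
    return upper.replace("U", "T"), alphabet


def _iter_raw_records(path: Path, fmt: str) -> Iterable[tuple[str, str]]:
    if fmt == "fasta":
        try:
            parsed = list(SeqIO.parse(str(path), "fasta"))
        except Exception as exc:  # Biopython raises assorted ValueErrors
            raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
        if not parsed and path.stat().st_size > 0:
            raise FormatError(f"{path}: no FASTA records found")
        for rec in parsed:
            yield rec.id, str(rec.seq)
    elif fmt == "tsv":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                yield parts[0], parts[1]
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'tsv')")


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in {".fasta", ".fa", ".fna", ".faa"}:
        return "fasta"
    if path.suffix.lower() in {".tsv", ".txt"}:
        return "tsv"
    # peek: FASTA records start with '>'
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "fasta" if first.startswith(">") else "tsv"


def read_aptamers(
    path: str | Path,
    format: str | None = None,
    skip_invalid: bool = False,
) -> list[AptamerRecord]:
    """Read aptamer sequences, normalizing RNA to the DNA alphabet.

    Every U becomes T; case is folded to upper. Symbols outside {A,C,G,T,U}
    raise :class:`SequenceAlphabetError` naming the record and position,
    unless ``skip_invalid`` is set, in which case the whole record is dropped
    with a warning. File order and ids are preserved.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    records: list[AptamerRecord] = []
    for rec_id, raw in _iter_raw_records(path, fmt):
        seq, alphabet = normalize_nucleotides(raw)
        try:
            records.append(AptamerRecord(rec_id, seq, alphabet))
        except ValidationError:
            if skip_invalid:
                logger.warning("skipping invalid aptamer record %r", rec_id)
                continue
            raise
    return records


def read_targets(
    path: str | Path,
    format: str | None = None,
    min_length: int = 50,
    skip_invalid: bool = False,
) -> list[TargetRecord]:
    """Read protein targets, excluding chains shorter than ``min_length``.

    Exclusions are logged one line each. Non-standard letters (B, J, O, U,
    X, Z, ...) raise unless ``skip_invalid`` drops the record.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    records: list[TargetRecord] = []
    for rec_id, raw in _iter_raw_records(path, fmt):
        try:
            rec = TargetRecord(rec_id, raw.upper())
        except ValidationError:
            if skip_invalid:
                logger.warning("skipping invalid target record %r", rec_id)
                continue
            raise
        if len(rec) < min_length:
            logger.info(
                "excluding target %r: length %d < %d", rec_id, len(rec), min_length
            )
            continue
        records.append(rec)
    return records


def _read_pair_rows(path: Path) -> list[tuple[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            rows.append((parts[0], parts[1]))
    return rows


def read_pairs(
    positives: str | Path,
    negatives: str | Path | None = None,
    aptamer_ids: Sequence[str] | None = None,
    target_ids: Sequence[str] | None = None,
) -> list[PairLabel]:
    """Read labelled pairs from a positives file and an optional negatives file.

    Labels are assigned by provenance. Duplicate (aptamer_id, target_id) keys
    anywhere in the union are rejected; if id collections are supplied, every
    referenced id must resolve.
    """
    pairs: list[PairLabel] = []
    seen: set[tuple[str, str]] = set()
    sources = [(Path(positives), POSITIVE)]
    if negatives is not None:
        sources.append((Path(negatives), NEGATIVE))
    for path, label in sources:
        for apt_id, tgt_id in _read_pair_rows(path):
            key = (apt_id, tgt_id)
            if key in seen:
                raise ValidationError(f"{path}: duplicated pair {key}")
            seen.add(key)
            pairs.append(PairLabel(apt_id, tgt_id, label))
    if aptamer_ids is not None or target_ids is not None:
        apt_set = set(aptamer_ids) if aptamer_ids is not None else None
        tgt_set = set(target_ids) if target_ids is not None else None
        for p in pairs:
            if apt_set is not None and p.aptamer_id not in apt_set:
                raise ReferentialIntegrityError(
                    f"pair ({p.aptamer_id}, {p.target_id}): unknown aptamer id"
                )
            if tgt_set is not None and p.target_id not in tgt_set:
                raise ReferentialIntegrityError(
                    f"pair ({p.aptamer_id}, {p.target_id}): unknown target id"
                )
    return pairs


def write_fasta(records: Iterable[AptamerRecord | TargetRecord], path: str | Path) -> None:
    """Write records as unwrapped multi-FASTA."""
    seqs = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def write_pairs(pairs: Iterable[PairLabel], path: str | Path) -> None:
    """Write pairs as 3-column TSV (aptamer_id, target_id, label)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.aptamer_id}\t{p.target_id}\t{p.label}\n")
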