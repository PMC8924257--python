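"""Sequence and edit-table I/O, and the coordinate conventions used everywhere.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  User-facing edit tables
  (TSV) and VCF are 1-based; BED output is 0-based half-open.
* Sequences are stored uppercase over the alphabet ``{A, C, G, T, N}``;
  any other character is a load error.  ``N`` is preserved at load time
  and downstream modules decide how to treat it.
* On a circular contig an interval may be stored as ``(start, end)`` with
  ``end > len(contig)``; indexing wraps around the origin.  Default
  topology is linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_EDIT_TABLE_COLUMNS = ("contig", "pos", "ref", "alt", "label")


class GenomeIOError(ValueError):
    """Base class for load/validation failures in this module."""


class AlphabetError(GenomeIOError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class EditValidationError(GenomeIOError):
    """An edit specification is malformed or disagrees with the genome."""


def _check_alphabet(seq: str, context: str) -> None:
    if not set(seq) <= VALID_BASES:  # fast path; locate the offender only on failure
        for i, ch in enumerate(seq):
            if ch not in VALID_BASES:
                raise AlphabetError(
                    f"illegal character {ch!r} in {context} at position {i} "
                    f"(allowed: A, C, G, T, N)"
                )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Raises :class:`AlphabetError` for characters outside {A, C, G, T, N}.
    """
    seq = seq.upper()
    _check_alphabet(seq, "sequence")
    return seq.translate(_COMPLEMENT)[::-1]


class Interval(NamedTuple):
    """0-based half-open genomic interval.

    ``end`` may exceed the contig length on a circular contig, in which
    case the interval wraps around the origin.
    """

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int, contig_length: int | None = None) -> bool:
        """Membership test, wrap-aware when ``contig_length`` is given."""
        if self.start <= pos < self.end:
            return True
        if contig_length is not None and self.end > contig_length:
            return 0 <= pos < self.end - contig_length
        return False


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA contig with a topology flag.

    The search space for PAM scanning and off-target counting.
    """

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise GenomeIOError(f"contig {self.name!r} is empty")
        _check_alphabet(self.seq, f"record {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for a 0-based half-open interval, wrapping if circular.

        On a linear contig, coordinates outside ``[0, len)`` raise
        :class:`GenomeIOError`.
        """
        n = end - start
        L = len(self.seq)
        if n < 0 or n > L:
            raise GenomeIOError(
                f"interval [{start}, {end}) has invalid length for contig "
                f"{self.name!r} (length {L})"
            )
        if not self.circular:
            if start < 0 or end > L:
                raise GenomeIOError(
                    f"interval [{start}, {end}) outside linear contig "
                    f"{self.name!r} (length {L})"
                )
            return self.seq[start:end]
        s = start % L
        if s + n <= L:
            return self.seq[s : s + n]
        return self.seq[s:] + self.seq[: s + n - L]


@dataclass(frozen=True)
class EditSpec:
    """One desired point (multi-)nucleotide substitution.

    ``pos`` is the 0-based index of the first edited base; user-facing
    files carry it 1-based.  Substitutions only: ``len(ref) == len(alt)``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if len(self.ref) != len(self.alt) or len(self.ref) < 1:
            raise EditValidationError(
                f"edit {self.label!r}: substitutions only (ref {self.ref!r} "
                f"and alt {self.alt!r} must have equal length >= 1)"
            )
        if self.ref == self.alt:
            raise EditValidationError(f"edit {self.label!r}: ref == alt")
        _check_alphabet(self.ref, f"edit {self.label!r} ref")
        _check_alphabet(self.alt, f"edit {self.label!r} alt")
        if self.pos < 0:
            raise EditValidationError(f"edit {self.label!r}: negative position")

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    def validate_against(self, genome: GenomeSequence) -> None:
        """Check the reference allele against the loaded genome."""
        observed = genome.fetch(self.pos, self.end)
        if observed != self.ref:
            raise EditValidationError(
                f"edit {self.label!r}: reference allele {self.ref!r} does not "
                f"match genome {genome.name!r} at 0-based position {self.pos} "
                f"(found {observed!r})"
            )


def genomes_by_name(genomes: Sequence[GenomeSequence]) -> dict[str, GenomeSequence]:
    index = {g.name: g for g in genomes}
    if len(index) != len(genomes):
        raise GenomeIOError("duplicate contig names in genome")
    return index


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    The record name is the first whitespace-delimited token of the header;
    sequences are uppercased and alphabet-checked.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(name=rec.id, seq=str(rec.seq), circular=circular))
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(header, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _looks_like_vcf(path: Path) -> bool:
    if path.suffix.lower() == ".vcf":
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def _read_edits_tsv(path: Path) -> list[EditSpec]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _EDIT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise EditValidationError(
            f"edit table {path} is missing required column(s): {', '.join(missing)}"
        )
    edits = []
    for row in table.itertuples(index=False):
        edits.append(
            EditSpec(
                contig=str(row.contig),
                pos=int(row.pos) - 1,  # 1-based in the file
                ref=str(row.ref),
                alt=str(row.alt),
                label=str(row.label),
            )
        )
    return edits


def _read_edits_vcf(path: Path) -> list[EditSpec]:
    import pysam

    edits = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            label = rec.id or f"{rec.chrom}:{rec.pos}"
            for alt in rec.alts or ():
                if len(rec.ref) != len(alt):
                    raise EditValidationError(
                        f"VCF record {label}: indels unsupported, "
                        f"substitutions only (REF {rec.ref!r}, ALT {alt!r})"
                    )
                edits.append(
                    EditSpec(
                        contig=rec.chrom,
                        pos=rec.start,  # pysam start is already 0-based
                        ref=rec.ref,
                        alt=alt,
                        label=label,
                    )
                )
    return edits


def read_edits(path: str | Path, genomes: Sequence[GenomeSequence]) -> list[EditSpec]:
    """Read desired edits from a 1-based TSV (contig, pos, ref, alt, label) or VCF.

    Every reference allele is verified against the loaded genome; a mismatch
    is an error naming the edit and both sequences.
    """
    path = Path(path)
    index = genomes_by_name(genomes)
    edits = _read_edits_vcf(path) if _looks_like_vcf(path) else _read_edits_tsv(path)
    for edit in edits:
        if edit.contig not in index:
            raise EditValidationError(
                f"edit {edit.label!r}: unknown contig {edit.contig!r}"
            )
        edit.validate_against(index[edit.contig])
    return edits


@dataclass(frozen=True)
class CdsFeature:
    """A coding-sequence interval used for the synonymous PAM-escape choice."""

    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str  # "+" or "-"
    phase: int = 0

    def covers(self, pos: int) -> bool:
        return self.contig_pos_in_frame(pos) is not None

    def contig_pos_in_frame(self, pos: int) -> int | None:
        """Offset of ``pos`` within the reading frame, or None if outside."""
        if not (self.start <= pos < self.end):
            return None
        if self.strand == "+":
            off = pos - (self.start + self.phase)
        else:
            off = (self.end - 1 - self.phase) - pos
        return off if off >= 0 else None


def read_cds_gff(path: str | Path) -> list[CdsFeature]:
    """Read CDS features from a GFF3 file (optional input)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        phase = int(feat.frame) if feat.frame not in (None, ".") else 0
        features.append(
            CdsFeature(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                phase=phase,
            )
        )
    return features
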