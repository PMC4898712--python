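"""Sequence, quality and taxonomy I/O.

Reads and writes the plain-text formats the pipeline touches: FASTA and
FASTQ (Phred+33 by default, Phred+64 selectable for legacy instruments),
SILVA/RDP-style taxonomy tables (TSV of reference id and a
semicolon-delimited lineage string), and tab-separated report tables.

Sequences are uppercased on input and RNA ``U`` is normalised to ``T`` so
that rRNA-derived references and DNA reads share one alphabet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "Lineage",
    "ReferenceRecord",
    "ParseError",
    "RANKS",
    "read_sequences",
    "write_sequences",
    "parse_lineage",
    "read_taxonomy_table",
    "write_tsv_report",
]

#: Fixed rank ladder, domain -> genus.  Genus is the deepest rank carried
#: because short rRNA fragments rarely resolve further.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

_IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


class ParseError(ValueError):
    """Malformed input file or lineage string."""


def _normalise_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _validate_alphabet(seq: str, context: str) -> None:
    bad = set(seq) - _IUPAC_DNA
    if bad:
        raise ParseError(f"{context}: non-IUPAC characters {sorted(bad)!r}")


@dataclass
class Read:
    """A sequence read with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = _normalise_sequence(self.sequence)
        _validate_alphabet(self.sequence, f"read {self.id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"read {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Lineage:
    """An ordered rank path (domain -> genus); trailing ranks may be absent.

    ``ranks`` holds (rank name, taxon name) pairs in the fixed order of
    :data:`RANKS` with no internal gaps.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.ranks) > len(RANKS):
            raise ParseError(f"lineage deeper than {len(RANKS)} ranks: {self.ranks!r}")
        for (name, taxon), expected in zip(self.ranks, RANKS):
            if name != expected:
                raise ParseError(f"rank order violated: got {name!r}, expected {expected!r}")
            if not taxon:
                raise ParseError("empty taxon name inside lineage")

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(taxon for _, taxon in self.ranks)

    def taxon_at(self, rank: str) -> Optional[str]:
        for name, taxon in self.ranks:
            if name == rank:
                return taxon
        return None

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth])

    def path(self, rank: Optional[str] = None, delimiter: str = ";") -> str:
        depth = RANKS.index(rank) + 1 if rank is not None else self.depth
        return delimiter.join(taxon for _, taxon in self.ranks[:depth])

    def as_string(self, delimiter: str = ";") -> str:
        return delimiter.join(self.taxa)


@dataclass
class ReferenceRecord:
    """An SSU rRNA reference sequence joined to its taxonomic lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        self.sequence = _normalise_sequence(self.sequence)
        _validate_alphabet(self.sequence, f"reference {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_sequences(
    path: Union[str, Path],
    format: str = "fasta",
    phred64: bool = False,
) -> Iterator[Read]:
    """Stream reads from a FASTA or FASTQ file.

    FASTQ qualities are decoded as Phred+33 unless ``phred64`` is set.
    Malformed records raise :class:`ParseError` naming the approximate
    line of the offending record.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    bio_format = format
    lines_per_record = 4 if format == "fastq" else 2
    if format == "fastq" and phred64:
        bio_format = "fastq-illumina"
    index = 0
    parser = SeqIO.parse(str(path), bio_format)
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed {format} record {index + 1} "
                f"(near line {index * lines_per_record + 1}): {exc}"
            ) from exc
        quals = record.letter_annotations.get("phred_quality")
        yield Read(
            id=record.id,
            sequence=str(record.seq),
            qualities=list(quals) if quals is not None else None,
        )
        index += 1


def write_sequences(reads: Iterable[Read], path: Union[str, Path], format: str = "fasta") -> None:
    """Write reads as FASTA or FASTQ (Phred+33). FASTQ requires qualities."""
    path = Path(path)
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        if format == "fastq":
            if read.qualities is None:
                raise ValueError(f"read {read.id!r} has no qualities; cannot write FASTQ")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), format)


def parse_lineage(lineage_string: str, delimiter: str = ";") -> Lineage:
    """Parse a delimited lineage string into a :class:`Lineage`.

    Fewer tokens than six ranks yield a truncated lineage (e.g. a
    phylum-deep path); more than six, or an empty leading token, is an
    error.
    """
    if not lineage_string:
        raise ParseError("empty lineage string")
    tokens = [tok.strip() for tok in lineage_string.split(delimiter)]
    while tokens and tokens[-1] == "":
        tokens.pop()
    if not tokens or tokens[0] == "":
        raise ParseError(f"lineage string {lineage_string!r} has an empty leading token")
    if any(tok == "" for tok in tokens):
        raise ParseError(f"lineage string {lineage_string!r} has an internal gap")
    if len(tokens) > len(RANKS):
        raise ParseError(f"lineage string {lineage_string!r} deeper than {len(RANKS)} ranks")
    return Lineage(tuple(zip(RANKS, tokens)))


def read_taxonomy_table(
    path: Union[str, Path], delimiter: str = ";"
) -> dict[str, Lineage]:
    """Read a 2-column TSV (ref_id, lineage string) into a lineage map.

    A header line whose first cell is ``ref_id`` and lines starting with
    ``#`` are skipped.
    """
    taxonomy: dict[str, Lineage] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "ref_id":
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            taxonomy[row[0]] = parse_lineage(row[1], delimiter)
    return taxonomy


def write_tsv_report(
    rows: Sequence[Mapping[str, object]],
    path: Union[str, Path],
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write dict rows as a TSV with a header line.

    Floats are printed with two decimals (the convention used for read
    densities); other values use ``str``.
    """
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from zero rows; pass `columns`")
        columns = list(rows[0].keys())
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(
                [
                    f"{value:.2f}" if isinstance(value, float) else value
                    for value in (row[col] for col in columns)
                ]
            )
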