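"""Quality-aware read cleaning and dereplication.

Random-primed cDNA reads often carry locally poor base calls.  Instead of
discarding whole reads, :func:`extract_quality_regions` salvages every
maximal run of bases at or above a Phred threshold, so one read may
contribute several informative sub-reads.  Downstream stages then length-
filter, drop ambiguity-riddled fragments and collapse exact duplicates
into weighted unique reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, TypeVar, Union

import numpy as np

from .seq_io import Read

__all__ = [
    "SubRead",
    "UniqueRead",
    "extract_quality_regions",
    "filter_length",
    "filter_ambiguous",
    "dereplicate",
]


@dataclass
class SubRead:
    """A contiguous slice of a parent read, with 0-based half-open coords.

    ``qualities is None`` marks a read that had no quality string and was
    passed through whole (flagged rather than trimmed).
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sub-read interval ({self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sub-read sequence length does not match its interval")

    @property
    def id(self) -> str:
        return f"{self.parent_id}/{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UniqueRead:
    """A dereplicated sequence with its multiplicity and member ids."""

    sequence: str
    count: int
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.member_ids and len(self.member_ids) != self.count:
            raise ValueError("count must equal the number of member ids")

    @property
    def id(self) -> str:
        return self.member_ids[0] if self.member_ids else self.sequence[:16]

    def __len__(self) -> int:
        return len(self.sequence)


def extract_quality_regions(
    read: Read, min_quality: int = 20, min_length: int = 50
) -> list[SubRead]:
    """Extract maximal runs of bases with quality >= ``min_quality``.

    Runs shorter than ``min_length`` are dropped.  Reads without qualities
    pass through whole as a single flagged sub-read (``qualities=None``).
    Returned sub-reads are in left-to-right parent order and every base
    below the threshold is excluded.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if read.qualities is None:
        return [SubRead(read.id, 0, len(read), read.sequence, None)]
    quals = np.asarray(read.qualities)
    mask = quals >= min_quality
    # run boundaries: positions where the good/bad state flips
    padded = np.concatenate(([False], mask, [False]))
    flips = np.flatnonzero(padded[1:] != padded[:-1])
    regions = []
    for start, end in zip(flips[::2], flips[1::2]):
        if end - start >= min_length:
            regions.append(
                SubRead(
                    read.id,
                    int(start),
                    int(end),
                    read.sequence[start:end],
                    read.qualities[start:end],
                )
            )
    return regions


_SeqItem = TypeVar("_SeqItem", Read, SubRead, UniqueRead)


def filter_length(
    items: Sequence[_SeqItem], min_len: int = 50, max_len: Optional[int] = None
) -> list[_SeqItem]:
    """Keep items with min_len <= length (<= max_len if set); order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is not None and min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [
        item
        for item in items
        if len(item) >= min_len and (max_len is None or len(item) <= max_len)
    ]


def filter_ambiguous(items: Sequence[_SeqItem], max_n_fraction: float = 0.10) -> list[_SeqItem]:
    """Drop items whose fraction of ``N`` bases exceeds ``max_n_fraction``.

    Ambiguous bases are retained through quality trimming (they reflect
    base-calling ambiguity, not low quality) but fragments dominated by
    them carry no usable words.
    """
    if not 0 <= max_n_fraction <= 1:
        raise ValueError("max_n_fraction must be in [0, 1]")
    return [
        item
        for item in items
        if item.sequence.count("N") <= max_n_fraction * len(item)
    ]


def dereplicate(items: Sequence[Union[Read, SubRead]]) -> list[UniqueRead]:
    """Collapse exact duplicate sequences into weighted unique reads.

    Forward-strand exact match only; strand canonicalisation happens later
    in similarity search, which keeps this stage order-independent.  Output
    is sorted by descending count, ties broken lexicographically by
    sequence.  The counts always sum to the number of inputs.
    """
    groups: dict[str, list[str]] = {}
    for item in items:
        groups.setdefault(item.sequence, []).append(item.id)
    uniques = [
        UniqueRead(sequence=seq, count=len(ids), member_ids=ids)
        for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.count, u.sequence))
    return uniques
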