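"""Synthetic reference sets and randomly fragmented rRNA-like reads.

Random-primed reverse transcription of SSU rRNA yields fragments with
random start points, a broad length distribution and both strands
represented.  This module emulates that process with a fully known truth:
references are generated by mutating a common root to a target
divergence, fragments are drawn by reference proportion / uniform start /
configurable length, optionally reverse-complemented, and sequencing
errors and Phred qualities are layered on afterwards.  Every emitted read
has a truth record (source reference, coordinates, strand), so each
pipeline stage can be scored exactly.

What this does *not* emulate: platform-specific artefacts (homopolymer
miscalls), priming-site sequence bias, or chimera formation — chimeric
reads are constructed explicitly where they are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seq_io import Lineage, RANKS, Read, ReferenceRecord, parse_lineage

__all__ = [
    "generate_reference_set",
    "fragment_reads",
    "apply_errors",
    "table1_like_preset",
]

_BASES = np.array(list("ACGT"))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` (always to a
    different base)."""
    arr = np.array(list(sequence))
    hit = rng.random(len(arr)) < rate
    for pos in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


def generate_reference_set(
    n_taxa: int,
    length: int = 1500,
    divergence: float = 0.10,
    seed: Optional[int] = None,
    split_rank: str = "genus",
    lineage_prefix: str = "Bacteria",
) -> list[ReferenceRecord]:
    """Generate ``n_taxa`` references by mutating a common root sequence.

    Each taxon's sequence differs from the root at ~``divergence`` of
    positions.  Lineages share all ranks above ``split_rank`` and are
    distinct from ``split_rank`` downward, so e.g. the default produces
    sister genera of one synthetic family.  Deterministic given the seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    if split_rank not in RANKS:
        raise ValueError(f"unknown rank {split_rank!r}")
    rng = np.random.default_rng(seed)
    root = _random_sequence(length, rng)
    split_depth = RANKS.index(split_rank)
    prefix_tokens = lineage_prefix.split(";")
    shared = []
    for level in range(split_depth):
        if level < len(prefix_tokens):
            shared.append(prefix_tokens[level])
        else:
            shared.append(f"{RANKS[level].capitalize()}Sim")
    records = []
    for idx in range(n_taxa):
        # a single taxon is the root itself; with several, each diverges
        seq = root if n_taxa == 1 else _mutate(root, divergence, rng)
        tokens = list(shared)
        for level in range(split_depth, len(RANKS)):
            tokens.append(f"{RANKS[level].capitalize()}{idx + 1:02d}")
        lineage = Lineage(tuple(zip(RANKS, tokens)))
        records.append(ReferenceRecord(id=f"ref{idx + 1:02d}", sequence=seq, lineage=lineage))
    return records


def fragment_reads(
    references: Sequence[ReferenceRecord],
    proportions: Sequence[float],
    n_reads: int,
    length_dist: tuple = ("uniform", 60, 400),
    strand_mix: float = 0.5,
    seed: Optional[int] = None,
    min_length: int = 8,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw random fragments from references in the given proportions.

    ``length_dist`` is ``("uniform", lo, hi)`` or ``("normal", mean, sd)``
    (truncated below at ``min_length``).  Fragment starts are uniform over
    the positions where the fragment fits, so realised lengths follow the
    configured distribution exactly (up to reference length).  Each
    fragment is reverse-complemented with probability ``strand_mix``.
    Returns the reads plus a truth table (read_id, ref_id, start, end,
    strand).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(references):
        raise ValueError("one proportion per reference required")
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("proportions must be non-negative and sum to 1")
    kind = length_dist[0]
    if kind == "uniform" and length_dist[1] < min_length:
        raise ValueError(f"minimum fragment length {length_dist[1]} below {min_length}")
    rng = np.random.default_rng(seed)
    ref_choice = rng.choice(len(references), size=n_reads, p=props)
    reads, truth = [], []
    for i in range(n_reads):
        ref = references[ref_choice[i]]
        if kind == "uniform":
            frag_len = int(rng.integers(length_dist[1], length_dist[2] + 1))
        elif kind == "normal":
            frag_len = max(min_length, int(round(rng.normal(length_dist[1], length_dist[2]))))
        else:
            raise ValueError(f"unknown length distribution {kind!r}")
        frag_len = min(frag_len, len(ref.sequence))
        start = int(rng.integers(0, len(ref.sequence) - frag_len + 1))
        end = start + frag_len
        fragment = ref.sequence[start:end]
        strand = "+"
        if rng.random() < strand_mix:
            fragment = fragment[::-1].translate(str.maketrans("ACGT", "TGCA"))
            strand = "-"
        read_id = f"frag{i + 1:06d}"
        reads.append(Read(id=read_id, sequence=fragment))
        truth.append((read_id, ref.id, start, end, strand))
    table = pd.DataFrame(truth, columns=["read_id", "ref_id", "start", "end", "strand"])
    return reads, table


def apply_errors(
    reads: Sequence[Read],
    substitution_rate: float = 0.0,
    indel_rate: float = 0.0,
    quality_profile: tuple[int, float] = (30, 0.0),
    seed: Optional[int] = None,
) -> list[Read]:
    """Layer sequencing errors and Phred qualities onto error-free reads.

    Per base: substitute with probability ``substitution_rate``; insert or
    delete (even odds) with probability ``indel_rate``.  Qualities are
    drawn around the profile's mean Phred; with dropout probability a read
    gains one low-quality stretch (Q ~5, ~20 nt), emulating locally poor
    base calls.  Zero rates leave sequences unchanged.
    """
    for name, rate in (("substitution_rate", substitution_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    mean_q, dropout = quality_profile
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        bases = []
        for base in read.sequence:
            if indel_rate and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                bases.append(str(rng.choice(_BASES)))  # insertion before base
            if substitution_rate and rng.random() < substitution_rate and base in "ACGT":
                choices = [b for b in "ACGT" if b != base]
                bases.append(choices[rng.integers(3)])
            else:
                bases.append(base)
        seq = "".join(bases)
        if not seq:
            seq = read.sequence[:1]  # degenerate: keep one base
        quals = np.clip(rng.normal(mean_q, 2, size=len(seq)).round(), 2, 41).astype(int)
        if dropout and rng.random() < dropout:
            start = int(rng.integers(0, max(1, len(seq) - 20)))
            quals[start : start + 20] = 5
        out.append(Read(id=read.id, sequence=seq, qualities=quals.tolist()))
    return out


#: Phylum-level read densities (percent, within Bacteria) used by the
#: demo preset: five dominant phyla plus eight minor groups.
_PRESET_DENSITIES = {
    "Actinobacteria": 3.6,
    "BD1-5": 0.1,
    "Bacteroidetes": 26.2,
    "Candidate division SR1": 1.5,
    "Candidate division TM7": 0.4,
    "Chlorobi": 3.0,
    "Chloroflexi": 0.3,
    "Firmicutes": 10.8,
    "Fusobacteria": 0.5,
    "Proteobacteria": 41.6,
    "Spirochaetes": 10.3,
    "Synergistetes": 0.9,
    "Tenericutes": 0.5,
}


def table1_like_preset(
    length: int = 1500,
    divergence: float = 0.12,
    seed: Optional[int] = None,
) -> tuple[list[ReferenceRecord], list[float]]:
    """A 13-phylum bacterial community preset for end-to-end demos.

    One reference per phylum; proportions echo a realistic oral-microbiome
    phylum profile (five dominant phyla carrying ~92.5% of the bacterial
    signal), normalised to sum to 1.
    """
    rng = np.random.default_rng(seed)
    root = _random_sequence(length, rng)
    records, props = [], []
    for idx, (phylum, density) in enumerate(sorted(_PRESET_DENSITIES.items())):
        seq = _mutate(root, divergence, rng)
        lineage = parse_lineage(
            f"Bacteria;{phylum};Class{idx + 1:02d};Order{idx + 1:02d};"
            f"Family{idx + 1:02d};Genus{idx + 1:02d}"
        )
        records.append(ReferenceRecord(id=f"preset{idx + 1:02d}", sequence=seq, lineage=lineage))
        props.append(density)
    total = sum(props)
    return records, [p / total for p in props]
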