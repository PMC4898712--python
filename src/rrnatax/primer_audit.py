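"""Universal-primer binding-site auditing.

'Universal' SSU rRNA PCR primers (e.g. 63f GCCTAACACATGCAAGTC and 518r
ATTACCGCGGCTGCTGG for the V1-V3 region) miss templates whose binding
sites have diverged.  Because randomly fragmented reverse-transcribed
rRNA reads are obtained without PCR, they reveal such mismatches: each
read is aligned to its best-matching reference, the primer windows are
located on that reference, and substitutions/insertions/deletions inside
the windows are read off the alignment columns.  Per-taxon roll-ups then
relate reads covering a site to the mismatch events observed in it.

Two ratio orientations are in circulation for the per-taxon summary —
reads-per-event and events-per-affected-read — so both are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .classify import Assignment
from .seq_io import Lineage, RANKS, ReferenceRecord
from .similarity import PairwiseAlignment

__all__ = [
    "PrimerSpec",
    "PrimerSiteReport",
    "TaxonMismatchSummary",
    "reverse_complement",
    "iupac_match",
    "locate_primer_window",
    "audit_read",
    "taxon_mismatch_ratio",
]

_IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer, written 5'->3'."""

    name: str
    sequence: str
    orientation: str  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq or not set(seq) <= set(_IUPAC_SETS):
            raise ValueError(f"primer {self.name!r}: invalid IUPAC sequence {self.sequence!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: orientation must be forward or reverse")


@dataclass
class PrimerSiteReport:
    read_id: str
    primer_name: str
    site_covered: bool
    mismatches: int = 0
    insertions: int = 0
    deletions: int = 0

    def __post_init__(self) -> None:
        if not self.site_covered and (self.mismatches or self.insertions or self.deletions):
            raise ValueError("event counts must be zero when the site is not covered")

    @property
    def total_events(self) -> int:
        return self.mismatches + self.insertions + self.deletions


@dataclass
class TaxonMismatchSummary:
    taxon: str
    reads_with_site: int
    total_events: int
    reads_with_any_event: int
    ratio: Optional[float]  # reads_with_site / total_events
    events_per_affected_read: Optional[float]  # total_events / reads_with_any_event


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement; rejects non-IUPAC characters."""
    seq = sequence.upper().replace("U", "T")
    if not set(seq) <= set(_IUPAC_SETS):
        bad = sorted(set(seq) - set(_IUPAC_SETS))
        raise ValueError(f"invalid IUPAC characters {bad!r}")
    return str(Seq(seq).reverse_complement())


def iupac_match(primer_base: str, template_base: str) -> bool:
    """A primer ambiguity code matching the template base counts as a match."""
    return bool(_IUPAC_SETS[primer_base] & _IUPAC_SETS[template_base])


def locate_primer_window(
    reference: ReferenceRecord,
    primer: PrimerSpec,
    max_mismatches: int = 5,
) -> Optional[tuple[int, int]]:
    """Best-matching window for a primer on a reference, or ``None``.

    Reverse primers are matched as their reverse complement (the strand
    written in the reference).  The window with the fewest IUPAC-aware
    Hamming mismatches wins, ties going leftmost; windows needing more
    than ``max_mismatches`` are rejected.  The cap defaults high because
    heavily mismatched sites are exactly the interesting ones.
    """
    target = primer.sequence if primer.orientation == "forward" else reverse_complement(primer.sequence)
    L = len(target)
    seq = reference.sequence
    if len(seq) <= L:
        raise ValueError(f"reference {reference.id!r} is not longer than primer {primer.name!r}")
    best: Optional[tuple[int, int]] = None  # (mismatches, offset)
    for offset in range(len(seq) - L + 1):
        mism = 0
        window = seq[offset : offset + L]
        for p, t in zip(target, window):
            if not iupac_match(p, t):
                mism += 1
                if best is not None and mism >= best[0]:
                    break
        else:
            if best is None or mism < best[0]:
                best = (mism, offset)
                if mism == 0:
                    break
    if best is None or best[0] > max_mismatches:
        return None
    return (best[1], best[1] + L)


def audit_read(
    alignment: PairwiseAlignment,
    primer_windows: Sequence[tuple[str, tuple[int, int]]],
) -> list[PrimerSiteReport]:
    """Count mismatch/indel events inside primer windows from an alignment.

    A window counts as covered only when the alignment's reference span
    contains it entirely.  Events are taken from alignment columns whose
    reference position lies in the window; an insertion (query base vs
    reference gap) sits between two reference positions and is assigned
    to the window only when both flanks are inside it.
    """
    reports = []
    for name, (w_start, w_end) in primer_windows:
        if w_start < 0 or w_start >= w_end:
            raise ValueError(f"primer window ({w_start}, {w_end}) is out of bounds")
        covered = alignment.ref_start <= w_start and alignment.ref_end >= w_end
        if not covered:
            reports.append(PrimerSiteReport(alignment.query_id, name, False))
            continue
        mismatches = insertions = deletions = 0
        ref_pos = alignment.ref_start
        for op in alignment.ops:
            if op in ("M", "X", "D"):
                in_window = w_start <= ref_pos < w_end
                if op == "X" and in_window:
                    mismatches += 1
                elif op == "D" and in_window:
                    deletions += 1
                ref_pos += 1
            else:  # insertion between ref_pos-1 and ref_pos
                if w_start < ref_pos < w_end:
                    insertions += 1
        reports.append(
            PrimerSiteReport(alignment.query_id, name, True, mismatches, insertions, deletions)
        )
    return reports


def taxon_mismatch_ratio(
    reports: Sequence[PrimerSiteReport],
    assignments: Mapping[str, Assignment],
    rank: str = "phylum",
) -> list[TaxonMismatchSummary]:
    """Roll primer-site reports up to per-taxon mismatch ratios.

    A read contributes to a taxon's ``reads_with_site`` when any of its
    reports covers a primer site; its events are summed over all covered
    sites.  ``ratio`` is reads-with-site / total events (undefined when no
    events were seen); ``events_per_affected_read`` is the opposite
    orientation, total events / reads-with-any-event.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    per_read: dict[str, tuple[bool, int]] = {}
    for rep in reports:
        if rep.read_id not in assignments:
            raise KeyError(f"read {rep.read_id!r} has no assignment")
        covered, events = per_read.get(rep.read_id, (False, 0))
        per_read[rep.read_id] = (covered or rep.site_covered, events + rep.total_events)

    stats: dict[str, list[int]] = {}
    for read_id, (covered, events) in per_read.items():
        if not covered:
            continue
        assignment = assignments[read_id]
        if assignment.status != "classified" or assignment.lineage is None:
            taxon = "unclassified"
        elif assignment.lineage.taxon_at(rank) is not None:
            taxon = assignment.lineage.path(rank)
        else:
            taxon = f"{assignment.lineage.as_string()};unclassified"
        row = stats.setdefault(taxon, [0, 0, 0])
        row[0] += 1
        row[1] += events
        row[2] += 1 if events > 0 else 0

    summaries = []
    for taxon in sorted(stats):
        n_site, n_events, n_affected = stats[taxon]
        summaries.append(
            TaxonMismatchSummary(
                taxon=taxon,
                reads_with_site=n_site,
                total_events=n_events,
                reads_with_any_event=n_affected,
                ratio=(n_site / n_events) if n_events else None,
                events_per_affected_read=(n_events / n_affected) if n_affected else None,
            )
        )
    return summaries
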