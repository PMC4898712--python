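"""Taxonomy projection, variable-region screening and abundance tables.

A fragment's ranked similarity hits are projected onto the reference
taxonomy: every hit within a small similarity window of the best hit
votes, and the read is assigned the lowest common ancestor (LCA) of the
voters' lineages.  Reads whose best hit falls below the classification
threshold are reported as unclassified rather than dropped — with
randomly fragmented rRNA reads the unclassified fraction is itself a
result.

Abundance is expressed as *read density*: the percentage of (weighted)
reads assigned to a taxon, normalised either over all classified reads or
within each domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .seq_io import Lineage, RANKS
from .similarity import MatchHit, PairwiseAlignment

__all__ = [
    "Assignment",
    "AbundanceTable",
    "TaxonomyError",
    "lineage_lca",
    "project_to_taxonomy",
    "screen_variable_region",
    "aggregate",
]


class TaxonomyError(KeyError):
    """A hit's reference id is missing from the taxonomy map."""


@dataclass
class Assignment:
    """Per-read classification outcome.

    ``weight`` is the dereplication count, so abundance reflects original
    read density.  ``lineage`` is truncated to the deepest consensus rank
    of the voting hits; ``None`` for unclassified reads.
    """

    read_id: str
    weight: float = 1.0
    status: str = "unclassified"  # classified|unclassified|chimeric|filtered
    lineage: Optional[Lineage] = None
    score: Optional[float] = None
    informative: Optional[bool] = None  # variable-region screen flag
    region_overlap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.status == "classified" and (self.lineage is None or self.lineage.depth < 1):
            raise ValueError("classified assignment requires a lineage with >= 1 rank")


def lineage_lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor: the deepest shared rank prefix."""
    if not lineages:
        raise ValueError("need at least one lineage")
    common: list[tuple[str, str]] = []
    for level in range(min(lin.depth for lin in lineages)):
        names = {lin.ranks[level] for lin in lineages}
        if len(names) != 1:
            break
        common.append(next(iter(names)))
    return Lineage(tuple(common))


def project_to_taxonomy(
    read_id: str,
    hits: Sequence[MatchHit],
    taxonomy: Mapping[str, Lineage],
    top_window: float = 0.02,
    min_similarity: float = 0.40,
    weight: float = 1.0,
) -> Assignment:
    """Assign a read the LCA lineage of its near-best hits.

    ``hits`` must be sorted by descending similarity.  If no hit reaches
    ``min_similarity`` the read is unclassified.  Otherwise every hit with
    similarity >= (best - top_window) votes and the LCA of the voters'
    lineages is assigned; the score is the best similarity.
    """
    if not hits or hits[0].similarity < min_similarity:
        return Assignment(
            read_id,
            weight=weight,
            status="unclassified",
            score=hits[0].similarity if hits else None,
        )
    top = hits[0].similarity
    voters = [h for h in hits if h.similarity >= top - top_window]
    lineages = []
    for hit in voters:
        if hit.ref_id not in taxonomy:
            raise TaxonomyError(f"reference {hit.ref_id!r} missing from taxonomy")
        lineages.append(taxonomy[hit.ref_id])
    lca = lineage_lca(lineages)
    if lca.depth == 0:
        # voters disagree even at domain level
        return Assignment(read_id, weight=weight, status="unclassified", score=top)
    return Assignment(read_id, weight=weight, status="classified", lineage=lca, score=top)


def screen_variable_region(
    alignment: PairwiseAlignment,
    region_map: Sequence[tuple[int, int]],
    min_overlap: float = 0.25,
) -> tuple[bool, float]:
    """Fraction of the aligned reference span inside variable regions.

    ``region_map`` holds 0-based half-open intervals on the reference
    coordinate system (the V1-V9 hypervariable segments, typically).
    Returns ``(informative, overlap_fraction)`` where a read is
    informative iff the fraction reaches ``min_overlap``.  Conserved-
    region-only reads are flagged, not discarded: that decision belongs to
    the caller.
    """
    prev_end = None
    for start, end in region_map:
        if start >= end:
            raise ValueError(f"invalid interval ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValueError("region map intervals must be sorted and non-overlapping")
        prev_end = end
    span = alignment.ref_end - alignment.ref_start
    if span <= 0:
        return (False, 0.0)
    covered = 0
    for start, end in region_map:
        covered += max(0, min(end, alignment.ref_end) - max(start, alignment.ref_start))
    fraction = covered / span
    return (fraction >= min_overlap, fraction)


@dataclass
class AbundanceTable:
    """Rank-level read densities.

    ``rows`` are (taxon path, weight, density %) triples.  With
    ``group="all"`` densities are percentages of the total classified
    weight; with ``group="within-domain"`` they are percentages of each
    domain's classified weight (the two-level presentation used for
    domain/phylum overviews).
    """

    rank: str
    group: str
    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["taxon", "weight", "density"])

    def density_of(self, taxon_path: str) -> float:
        for taxon, _, density in self.rows:
            if taxon == taxon_path:
                return density
        raise KeyError(taxon_path)

    def check_normalisation(self, tol: float = 0.01) -> None:
        groups: dict[str, float] = {}
        for taxon, _, density in self.rows:
            key = taxon.split(";", 1)[0] if self.group == "within-domain" else "all"
            groups[key] = groups.get(key, 0.0) + density
        for key, total in groups.items():
            if abs(total - 100.0) > tol:
                raise AssertionError(f"densities in group {key!r} sum to {total}, not 100")


def aggregate(
    assignments: Sequence[Assignment],
    rank: str = "phylum",
    group: str = "within-domain",
) -> AbundanceTable:
    """Aggregate classified assignments into a rank-level abundance table.

    Weights are summed per taxon at the requested rank; assignments
    classified above that rank pool under ``unclassified <deepest taxon>``.
    Density is 100 x taxon weight / group total, where the group is either
    everything (``group="all"``) or each domain separately
    (``group="within-domain"``).  A group with zero classified weight
    simply contributes no rows.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if group not in ("all", "within-domain"):
        raise ValueError(f"unknown grouping {group!r}")
    depth = RANKS.index(rank) + 1
    weights: dict[str, float] = {}
    for a in assignments:
        if a.status != "classified" or a.lineage is None:
            continue
        if a.lineage.depth >= depth:
            path = a.lineage.path(rank)
        else:
            parent = a.lineage.taxa[-1]
            prefix = a.lineage.as_string()
            path = f"{prefix};unclassified {parent}" if depth > 1 else f"unclassified {parent}"
        weights[path] = weights.get(path, 0.0) + a.weight

    totals: dict[str, float] = {}
    for path, w in weights.items():
        key = path.split(";", 1)[0] if group == "within-domain" else "all"
        totals[key] = totals.get(key, 0.0) + w

    rows = []
    for path in sorted(weights):
        key = path.split(";", 1)[0] if group == "within-domain" else "all"
        rows.append((path, weights[path], 100.0 * weights[path] / totals[key]))
    rows.sort(key=lambda r: (r[0].split(";", 1)[0], -r[1], r[0]))
    return AbundanceTable(rank=rank, group=group, rows=rows)
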