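"""End-to-end pipeline orchestration.

Two modes reflect the two kinds of input data:

* **RT-fragment mode** (:func:`run_rtrna_pipeline`) for randomly
  fragmented reverse-transcribed rRNA reads: clean -> dereplicate ->
  similarity search -> taxonomy projection -> optional variable-region
  screen -> abundance tables -> optional primer-site audit.  No chimera
  stage — these reads never went through PCR.
* **Amplicon mode** (:func:`run_amplicon_pipeline`) adds reference-based
  chimera detection between dereplication and search; chimeric weight is
  excluded from abundance tables but fully accounted in the run report.

The classification path is deterministic: identical inputs and
configuration give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from .chimera import ChimeraVerdict, detect_chimera
from .classify import (
    AbundanceTable,
    Assignment,
    aggregate,
    project_to_taxonomy,
    screen_variable_region,
)
from .cleaning import (
    UniqueRead,
    dereplicate,
    extract_quality_regions,
    filter_ambiguous,
    filter_length,
)
from .primer_audit import (
    PrimerSiteReport,
    PrimerSpec,
    TaxonMismatchSummary,
    audit_read,
    locate_primer_window,
    taxon_mismatch_ratio,
)
from .seq_io import Lineage, Read, ReferenceRecord, write_tsv_report
from .similarity import align_pair, build_word_index, search

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineResult",
    "run_rtrna_pipeline",
    "run_amplicon_pipeline",
    "write_outputs",
]


@dataclass
class PipelineConfig:
    """Tunable parameters for both pipeline modes."""

    min_quality: int = 20
    min_length: int = 50
    max_length: Optional[int] = None
    max_n_fraction: float = 0.10
    derep: bool = True
    word_length: int = 8
    min_similarity: float = 0.40
    top_window: float = 0.02
    max_hits: int = 20
    ranks: tuple[str, ...] = ("domain", "phylum")
    variable_regions: Optional[list[tuple[int, int]]] = None
    min_region_overlap: float = 0.25
    region_hard_filter: bool = False
    primers: list[PrimerSpec] = field(default_factory=list)
    primer_max_mismatches: int = 8
    band: int = 32
    chimera_min_segment: int = 60
    chimera_min_improvement: float = 0.10
    seed: Optional[int] = None

    def parameter_echo(self) -> dict:
        echo = asdict(self)
        echo["primers"] = [f"{p.name}:{p.sequence}:{p.orientation}" for p in self.primers]
        return echo


@dataclass
class RunReport:
    """Per-stage counts; the status weights must conserve the dereplicated
    input weight."""

    input_reads: int = 0
    subreads: int = 0
    after_filters: int = 0
    unique_reads: int = 0
    classified_weight: float = 0.0
    unclassified_weight: float = 0.0
    chimeric_weight: float = 0.0
    filtered_weight: float = 0.0
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def check_conservation(self) -> None:
        total = (
            self.classified_weight
            + self.unclassified_weight
            + self.chimeric_weight
            + self.filtered_weight
        )
        if abs(total - self.after_filters) > 1e-6:
            raise AssertionError(
                f"status weights sum to {total}, expected {self.after_filters}"
            )

    def rows(self) -> list[dict]:
        return [
            {"metric": "input_reads", "value": self.input_reads},
            {"metric": "subreads_after_cleaning", "value": self.subreads},
            {"metric": "after_filters", "value": self.after_filters},
            {"metric": "unique_reads", "value": self.unique_reads},
            {"metric": "classified_weight", "value": self.classified_weight},
            {"metric": "unclassified_weight", "value": self.unclassified_weight},
            {"metric": "chimeric_weight", "value": self.chimeric_weight},
            {"metric": "filtered_weight", "value": self.filtered_weight},
            {"metric": "seed", "value": self.seed if self.seed is not None else ""},
        ]


@dataclass
class PipelineResult:
    tables: dict[str, AbundanceTable]
    assignments: list[Assignment]
    report: RunReport
    chimera_verdicts: list[ChimeraVerdict] = field(default_factory=list)
    primer_reports: list[PrimerSiteReport] = field(default_factory=list)
    primer_summaries: list[TaxonMismatchSummary] = field(default_factory=list)


def _clean_and_dereplicate(
    reads: Sequence[Read], config: PipelineConfig
) -> tuple[list[UniqueRead], RunReport]:
    report = RunReport(parameters=config.parameter_echo(), seed=config.seed)
    report.input_reads = len(reads)
    subreads = []
    for read in reads:
        subreads.extend(
            extract_quality_regions(read, config.min_quality, config.min_length)
        )
    report.subreads = len(subreads)
    kept = filter_length(subreads, config.min_length, config.max_length)
    kept = filter_ambiguous(kept, config.max_n_fraction)
    # fragments shorter than a word can never be searched
    kept = [s for s in kept if len(s) >= config.word_length]
    report.after_filters = len(kept)
    if config.derep:
        uniques = dereplicate(kept)
    else:
        uniques = [UniqueRead(s.sequence, 1, [s.id]) for s in kept]
    report.unique_reads = len(uniques)
    return uniques, report


def _classify_uniques(
    uniques: Sequence[UniqueRead],
    index,
    taxonomy: dict[str, Lineage],
    config: PipelineConfig,
) -> list[Assignment]:
    assignments = []
    for unique in uniques:
        hits = search(unique.sequence, index, 0.0, config.max_hits)
        assignments.append(
            project_to_taxonomy(
                unique.id,
                hits,
                taxonomy,
                config.top_window,
                config.min_similarity,
                weight=unique.count,
            )
        )
    return assignments


def _screen_regions(
    uniques: Sequence[UniqueRead],
    assignments: list[Assignment],
    index,
    config: PipelineConfig,
) -> None:
    """Annotate assignments with variable-region overlap (flag, not filter,
    unless ``region_hard_filter`` is set — then uninformative reads get
    status ``filtered``)."""
    by_id = {u.id: u for u in uniques}
    for a in assignments:
        if a.status != "classified":
            continue
        unique = by_id[a.read_id]
        hits = search(unique.sequence, index, 0.0, 1)
        if not hits:
            continue
        ref = index.references[hits[0].ref_id]
        query = unique.sequence
        if hits[0].strand == "reverse":
            from .similarity import reverse_complement_simple

            query = reverse_complement_simple(query)
        alignment = align_pair(query, ref.sequence, config.band, unique.id, ref.id)
        informative, fraction = screen_variable_region(
            alignment, config.variable_regions, config.min_region_overlap
        )
        a.informative = informative
        a.region_overlap = fraction
        if config.region_hard_filter and not informative:
            a.status = "filtered"


def _audit_primers(
    uniques: Sequence[UniqueRead],
    assignments: Sequence[Assignment],
    index,
    config: PipelineConfig,
) -> tuple[list[PrimerSiteReport], list[TaxonMismatchSummary]]:
    from .similarity import reverse_complement_simple

    window_cache: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    by_id = {u.id: u for u in uniques}
    reports: list[PrimerSiteReport] = []
    for a in assignments:
        if a.status != "classified":
            continue
        unique = by_id[a.read_id]
        hits = search(unique.sequence, index, 0.0, 1)
        if not hits:
            continue
        ref = index.references[hits[0].ref_id]
        if ref.id not in window_cache:
            windows = []
            for primer in config.primers:
                interval = locate_primer_window(ref, primer, config.primer_max_mismatches)
                if interval is not None:
                    windows.append((primer.name, interval))
            window_cache[ref.id] = windows
        if not window_cache[ref.id]:
            continue
        query = unique.sequence
        if hits[0].strand == "reverse":
            query = reverse_complement_simple(query)
        alignment = align_pair(query, ref.sequence, config.band, unique.id, ref.id)
        reports.extend(audit_read(alignment, window_cache[ref.id]))
    assignment_map = {a.read_id: a for a in assignments}
    summaries = taxon_mismatch_ratio(reports, assignment_map, rank="phylum")
    return reports, summaries


def _finish(
    uniques: Sequence[UniqueRead],
    assignments: list[Assignment],
    report: RunReport,
    config: PipelineConfig,
    chimera_verdicts: Optional[list[ChimeraVerdict]] = None,
    index=None,
) -> PipelineResult:
    for a in assignments:
        if a.status == "classified":
            report.classified_weight += a.weight
        elif a.status == "chimeric":
            report.chimeric_weight += a.weight
        elif a.status == "filtered":
            report.filtered_weight += a.weight
        else:
            report.unclassified_weight += a.weight
    report.check_conservation()

    tables = {}
    for rank in config.ranks:
        group = "all" if rank == "domain" else "within-domain"
        tables[rank] = aggregate(assignments, rank=rank, group=group)

    primer_reports: list[PrimerSiteReport] = []
    primer_summaries: list[TaxonMismatchSummary] = []
    if config.primers and index is not None:
        primer_reports, primer_summaries = _audit_primers(
            uniques, assignments, index, config
        )
    return PipelineResult(
        tables=tables,
        assignments=assignments,
        report=report,
        chimera_verdicts=chimera_verdicts or [],
        primer_reports=primer_reports,
        primer_summaries=primer_summaries,
    )


def run_rtrna_pipeline(
    reads: Sequence[Read],
    references: Sequence[ReferenceRecord],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """RT-fragment mode: clean, dereplicate, classify, aggregate, audit.

    The chimera stage is deliberately skipped — fragments of directly
    sequenced rRNA molecules cannot be PCR chimeras.
    """
    config = config or PipelineConfig()
    if not references:
        raise ValueError("reference set is empty")
    taxonomy = {ref.id: ref.lineage for ref in references}
    index = build_word_index(references, config.word_length)
    uniques, report = _clean_and_dereplicate(reads, config)
    assignments = _classify_uniques(uniques, index, taxonomy, config)
    if config.variable_regions:
        _screen_regions(uniques, assignments, index, config)
    return _finish(uniques, assignments, report, config, index=index)


def run_amplicon_pipeline(
    reads: Sequence[Read],
    references: Sequence[ReferenceRecord],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Amplicon mode: as RT mode plus chimera detection after dereplication.

    Chimeric reads get status ``chimeric``: excluded from abundance tables
    but counted in the run report.
    """
    config = config or PipelineConfig()
    if not references:
        raise ValueError("reference set is empty")
    taxonomy = {ref.id: ref.lineage for ref in references}
    index = build_word_index(references, config.word_length)
    uniques, report = _clean_and_dereplicate(reads, config)

    verdicts = []
    clean_uniques = []
    assignments: list[Assignment] = []
    for unique in uniques:
        verdict = detect_chimera(
            unique, index, config.chimera_min_segment, config.chimera_min_improvement
        )
        verdicts.append(verdict)
        if verdict.is_chimera:
            assignments.append(
                Assignment(unique.id, weight=unique.count, status="chimeric")
            )
        else:
            clean_uniques.append(unique)
    assignments.extend(_classify_uniques(clean_uniques, index, taxonomy, config))
    if config.variable_regions:
        _screen_regions(clean_uniques, assignments, index, config)
    return _finish(uniques, assignments, report, config, verdicts, index=index)


def write_outputs(result: PipelineResult, out_dir: Union[str, Path]) -> list[Path]:
    """Write abundance tables, assignments, audits and the run report as
    TSVs; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    for rank, table in result.tables.items():
        path = out_dir / f"abundance_{rank}.tsv"
        rows = [
            {"taxon": taxon, "weight": float(weight), "density": float(density)}
            for taxon, weight, density in table.rows
        ]
        write_tsv_report(rows, path, columns=["taxon", "weight", "density"])
        written.append(path)

    path = out_dir / "assignments.tsv"
    rows = [
        {
            "read_id": a.read_id,
            "weight": float(a.weight),
            "status": a.status,
            "lineage": a.lineage.as_string() if a.lineage else "",
            "score": float(a.score) if a.score is not None else "",
        }
        for a in result.assignments
    ]
    write_tsv_report(rows, path, columns=["read_id", "weight", "status", "lineage", "score"])
    written.append(path)

    if result.chimera_verdicts:
        path = out_dir / "chimera.tsv"
        rows = [
            {
                "read_id": v.read_id,
                "is_chimera": int(v.is_chimera),
                "parent_a": v.parent_a or "",
                "parent_b": v.parent_b or "",
                "breakpoint": v.breakpoint if v.breakpoint is not None else "",
                "score": float(v.score),
                "status": v.status,
            }
            for v in result.chimera_verdicts
        ]
        write_tsv_report(
            rows,
            path,
            columns=["read_id", "is_chimera", "parent_a", "parent_b", "breakpoint", "score", "status"],
        )
        written.append(path)

    if result.primer_reports:
        path = out_dir / "primer_sites.tsv"
        rows = [
            {
                "read_id": r.read_id,
                "primer": r.primer_name,
                "site_covered": int(r.site_covered),
                "mismatches": r.mismatches,
                "insertions": r.insertions,
                "deletions": r.deletions,
            }
            for r in result.primer_reports
        ]
        write_tsv_report(
            rows,
            path,
            columns=["read_id", "primer", "site_covered", "mismatches", "insertions", "deletions"],
        )
        written.append(path)

    if result.primer_summaries:
        path = out_dir / "primer_taxon_summary.tsv"
        rows = [
            {
                "taxon": s.taxon,
                "reads_with_site": s.reads_with_site,
                "total_events": s.total_events,
                "reads_with_any_event": s.reads_with_any_event,
                "ratio_reads_per_event": float(s.ratio) if s.ratio is not None else "NA",
                "events_per_affected_read": (
                    float(s.events_per_affected_read)
                    if s.events_per_affected_read is not None
                    else "NA"
                ),
            }
            for s in result.primer_summaries
        ]
        write_tsv_report(
            rows,
            path,
            columns=[
                "taxon",
                "reads_with_site",
                "total_events",
                "reads_with_any_event",
                "ratio_reads_per_event",
                "events_per_affected_read",
            ],
        )
        written.append(path)

    path = out_dir / "report.tsv"
    write_tsv_report(result.report.rows(), path, columns=["metric", "value"])
    written.append(path)
    return written
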