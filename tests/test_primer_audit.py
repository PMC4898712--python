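"""Primer binding-site location, per-read event counting and taxon roll-ups."""

import pytest
from hypothesis import given, strategies as st

from oracles import full_dp_align, oracle_window_events
from rrnatax import (
    Assignment,
    PrimerSpec,
    ReferenceRecord,
    align_pair,
    audit_read,
    locate_primer_window,
    parse_lineage,
    reverse_complement,
    taxon_mismatch_ratio,
)
from rrnatax.primer_audit import iupac_match

P63F = PrimerSpec("63f", "GCCTAACACATGCAAGTC", "forward")
P518R = PrimerSpec("518r", "ATTACCGCGGCTGCTGG", "reverse")
LIN = parse_lineage("Bacteria;Spirochaetes")


def _ref(seq, rid="ref1"):
    return ReferenceRecord(rid, seq, LIN)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACGT", "ACGT"),
            ("ATTACCGCGGCTGCTGG", "CCAGCAGCCGCGGTAAT"),
            ("A", "T"),
            ("RYSWKM", "KMWSRY"),
        ],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGZ")

    @given(seq=st.text(alphabet="ACGTNRYSWKMBDHV", min_size=1, max_size=60))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestIupacMatch:
    def test_ambiguity_code_matches_compatible_base(self):
        assert iupac_match("R", "A") and iupac_match("R", "G")
        assert not iupac_match("R", "C")
        assert iupac_match("N", "T")


class TestLocatePrimerWindow:
    def test_exact_forward_site(self, rng):
        flank = "".join(rng.choice(list("ACGT"), size=20))
        tail = "".join(rng.choice(list("ACGT"), size=60))
        ref = _ref(flank + P63F.sequence + tail)
        assert locate_primer_window(ref, P63F, 0) == (20, 38)

    def test_site_at_origin(self, rng):
        tail = "".join(rng.choice(list("ACGT"), size=60))
        ref = _ref(P63F.sequence + tail)
        assert locate_primer_window(ref, P63F, 0) == (0, len(P63F.sequence))

    def test_reverse_primer_matched_as_reverse_complement(self, rng):
        flank = "".join(rng.choice(list("ACGT"), size=30))
        ref = _ref(flank + reverse_complement(P518R.sequence) + flank)
        assert locate_primer_window(ref, P518R, 0) == (30, 47)

    def test_absent_site_returns_none(self):
        ref = _ref("AT" * 40)
        assert locate_primer_window(ref, P63F, max_mismatches=3) is None


def _mutated_window_pair(rng, events):
    """A 240-nt reference and a query copying positions 20..220 with the
    requested isolated events inside the window (80, 120)."""
    ref = "".join(rng.choice(list("ACGT"), size=240))
    query = list(ref[20:220])
    window = (80, 120)
    offset = 20
    positions = [90, 100, 110, 95, 105]
    for kind, pos in zip(events, positions):
        qpos = pos - offset
        if kind == "X":
            query[qpos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[qpos]]
        elif kind == "D":
            query[qpos] = None
    query = "".join(b for b in query if b is not None)
    return query, ref, window


class TestAuditRead:
    def test_identical_window_has_no_events(self, rng):
        query, ref, window = _mutated_window_pair(rng, "")
        aln = align_pair(query, ref)
        (report,) = audit_read(aln, [("63f", window)])
        assert report.site_covered
        assert (report.mismatches, report.insertions, report.deletions) == (0, 0, 0)

    def test_three_substitutions_counted(self, rng):
        query, ref, window = _mutated_window_pair(rng, "XXX")
        aln = align_pair(query, ref)
        (report,) = audit_read(aln, [("63f", window)])
        assert (report.mismatches, report.insertions, report.deletions) == (3, 0, 0)

    def test_single_deletion_counted(self, rng):
        query, ref, window = _mutated_window_pair(rng, "D")
        aln = align_pair(query, ref)
        (report,) = audit_read(aln, [("63f", window)])
        assert (report.mismatches, report.insertions, report.deletions) == (0, 0, 1)

    def test_uncovered_window_reports_site_not_covered(self, rng):
        query, ref, window = _mutated_window_pair(rng, "")
        aln = align_pair(query, ref)
        (report,) = audit_read(aln, [("63f", (210, 235))])  # beyond the query span
        assert not report.site_covered
        assert report.total_events == 0

    def test_counts_agree_with_unbanded_oracle(self, rng):
        """Event counts must match those read off an exhaustive full-matrix
        alignment for constructed substitution/indel mixes."""
        for events in ("X", "XX", "XD", "XXD", "DX", "XXXX"):
            query, ref, window = _mutated_window_pair(rng, events)
            aln = align_pair(query, ref)
            (report,) = audit_read(aln, [("p", window)])
            _, ops, ref_start, _ = full_dp_align(query, ref)
            assert (
                report.mismatches,
                report.insertions,
                report.deletions,
            ) == oracle_window_events(ops, ref_start, window)


class TestTaxonMismatchRatio:
    def _reports(self, n_with_site, events_per_read):
        from rrnatax.primer_audit import PrimerSiteReport

        reports, assignments = [], {}
        for i in range(n_with_site):
            rid = f"r{i}"
            mism = events_per_read[i] if i < len(events_per_read) else 0
            reports.append(PrimerSiteReport(rid, "63f", True, mismatches=mism))
            assignments[rid] = Assignment(
                rid, status="classified", lineage=parse_lineage("Bacteria;Spirochaetes")
            )
        return reports, assignments

    def test_fig_style_ratio(self):
        reports, assignments = self._reports(10, [1] * 5)  # 10 reads, 5 events
        (summary,) = taxon_mismatch_ratio(reports, assignments, "phylum")
        assert summary.reads_with_site == 10
        assert summary.total_events == 5
        assert summary.ratio == pytest.approx(2.0)

    def test_more_events_than_reads(self):
        reports, assignments = self._reports(4, [2, 2, 2, 2])
        (summary,) = taxon_mismatch_ratio(reports, assignments, "phylum")
        assert summary.ratio == pytest.approx(0.5)
        assert summary.events_per_affected_read == pytest.approx(2.0)

    def test_zero_events_is_not_applicable(self):
        reports, assignments = self._reports(7, [])
        (summary,) = taxon_mismatch_ratio(reports, assignments, "phylum")
        assert summary.ratio is None
        assert summary.reads_with_any_event == 0

    def test_unassigned_read_raises(self):
        from rrnatax.primer_audit import PrimerSiteReport

        with pytest.raises(KeyError):
            taxon_mismatch_ratio([PrimerSiteReport("ghost", "63f", True)], {}, "phylum")
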