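"""Taxonomy projection (LCA), variable-region screening and abundance tables."""

import pytest
from hypothesis import given, strategies as st

from rrnatax import (
    Assignment,
    aggregate,
    lineage_lca,
    parse_lineage,
    project_to_taxonomy,
    screen_variable_region,
)
from rrnatax.classify import TaxonomyError
from rrnatax.similarity import MatchHit, PairwiseAlignment


def _hit(ref_id, sim):
    return MatchHit(ref_id, sim, int(sim * 100), "forward")


def _alignment(ref_start, ref_end, ops=None):
    n = ref_end - ref_start
    ops = ops or "M" * n
    return PairwiseAlignment(
        "q", "r", "A" * len(ops), "A" * len(ops), 0, len(ops), ref_start, ref_end, ops, float(n)
    )


class TestProjectToTaxonomy:
    def test_single_strong_hit_assigns_genus(self, small_taxonomy):
        a = project_to_taxonomy("q1", [_hit("refA", 0.95)], small_taxonomy)
        assert a.status == "classified"
        assert a.lineage.taxon_at("genus") == "Treponema"
        assert a.score == 0.95

    def test_two_in_window_genera_fall_back_to_family(self, small_taxonomy):
        hits = [_hit("refA", 0.95), _hit("refB", 0.94)]
        a = project_to_taxonomy("q1", hits, small_taxonomy, top_window=0.02)
        assert a.lineage.depth == 5
        assert a.lineage.taxon_at("family") == "Spirochaetaceae"
        assert a.lineage.taxon_at("genus") is None

    def test_out_of_window_hit_does_not_vote(self, small_taxonomy):
        hits = [_hit("refA", 0.95), _hit("refB", 0.80)]
        a = project_to_taxonomy("q1", hits, small_taxonomy, top_window=0.02)
        assert a.lineage.taxon_at("genus") == "Treponema"

    def test_weak_best_hit_is_unclassified(self, small_taxonomy):
        a = project_to_taxonomy("q1", [_hit("refA", 0.30)], small_taxonomy, min_similarity=0.50)
        assert a.status == "unclassified"
        assert a.lineage is None

    def test_no_hits_is_unclassified(self, small_taxonomy):
        assert project_to_taxonomy("q1", [], small_taxonomy).status == "unclassified"

    def test_missing_reference_raises(self, small_taxonomy):
        with pytest.raises(TaxonomyError, match="refZ"):
            project_to_taxonomy("q1", [_hit("refZ", 0.9)], small_taxonomy)

    def test_lca_monotone_under_added_hits(self, small_taxonomy):
        """Adding an in-window hit can only keep or shallow the rank."""
        base = [_hit("refA", 0.95)]
        depth1 = project_to_taxonomy("q", base, small_taxonomy).lineage.depth
        for extra in ("refB", "refC"):
            deeper = base + [_hit(extra, 0.95)]
            a = project_to_taxonomy("q", deeper, small_taxonomy)
            depth2 = a.lineage.depth if a.lineage else 0
            assert depth2 <= depth1


class TestLineageLca:
    @pytest.mark.parametrize(
        "strings, expected",
        [
            (["Bacteria;Spirochaetes", "Bacteria;Spirochaetes"], "Bacteria;Spirochaetes"),
            (["Bacteria;Spirochaetes", "Bacteria;Firmicutes"], "Bacteria"),
            (["Bacteria", "Archaea"], ""),
        ],
    )
    def test_lca_depth(self, strings, expected):
        lca = lineage_lca([parse_lineage(s) for s in strings])
        assert lca.as_string() == expected


class TestScreenVariableRegion:
    def test_alignment_inside_variable_interval(self):
        informative, frac = screen_variable_region(_alignment(100, 150), [(80, 200)])
        assert (informative, frac) == (True, 1.0)

    def test_alignment_outside_all_intervals(self):
        informative, frac = screen_variable_region(_alignment(300, 400), [(80, 200)])
        assert (informative, frac) == (False, 0.0)

    def test_partial_overlap_fraction(self):
        # 100-position span, 25 positions inside the interval
        informative, frac = screen_variable_region(
            _alignment(0, 100), [(75, 150)], min_overlap=0.25
        )
        assert frac == pytest.approx(0.25)
        assert informative

    def test_unsorted_intervals_rejected(self):
        with pytest.raises(ValueError):
            screen_variable_region(_alignment(0, 10), [(50, 80), (20, 60)])


def _assign(rid, lineage, weight):
    return Assignment(rid, weight=weight, status="classified", lineage=parse_lineage(lineage))


class TestAggregate:
    def test_domain_densities_from_constructed_counts(self):
        assignments = [
            _assign("a", "Bacteria", 9953),
            _assign("b", "Archaea", 1),
            _assign("c", "Eukarya", 46),
        ]
        table = aggregate(assignments, rank="domain", group="all")
        assert table.density_of("Bacteria") == pytest.approx(99.53)
        assert table.density_of("Archaea") == pytest.approx(0.01)
        assert table.density_of("Eukarya") == pytest.approx(0.46)

    def test_single_taxon_is_everything(self):
        table = aggregate([_assign("a", "Bacteria", 7)], rank="domain", group="all")
        assert table.rows == [("Bacteria", 7.0, 100.0)]

    def test_dominant_phyla_sum(self):
        weights = {
            "Actinobacteria": 36,
            "Bacteroidetes": 262,
            "Firmicutes": 108,
            "Proteobacteria": 416,
            "Spirochaetes": 103,
            "Othera": 40,
            "Otherb": 35,
        }
        assignments = [
            _assign(p, f"Bacteria;{p}", w) for p, w in weights.items()
        ]
        table = aggregate(assignments, rank="phylum", group="within-domain")
        dominant = sum(
            table.density_of(f"Bacteria;{p}")
            for p in ("Actinobacteria", "Bacteroidetes", "Firmicutes", "Proteobacteria", "Spirochaetes")
        )
        assert dominant == pytest.approx(92.5)

    def test_shallow_assignments_pool_as_unclassified(self):
        assignments = [
            _assign("a", "Bacteria;Firmicutes;Bacilli", 5),
            _assign("b", "Bacteria", 5),
        ]
        table = aggregate(assignments, rank="class", group="within-domain")
        taxa = {row[0] for row in table.rows}
        assert "Bacteria;Firmicutes;Bacilli" in taxa
        assert "Bacteria;unclassified Bacteria" in taxa

    def test_non_classified_statuses_are_excluded(self):
        assignments = [
            _assign("a", "Bacteria", 5),
            Assignment("b", weight=3, status="unclassified"),
            Assignment("c", weight=2, status="chimeric"),
        ]
        table = aggregate(assignments, rank="domain", group="all")
        assert table.rows == [("Bacteria", 5.0, 100.0)]

    def test_empty_input_gives_empty_table(self):
        assert aggregate([], rank="phylum").rows == []

    @given(
        weights=st.lists(
            st.tuples(st.sampled_from(["Bacteria", "Archaea", "Eukarya"]),
                      st.sampled_from("PQRS"),
                      st.integers(1, 500)),
            min_size=1,
            max_size=30,
        )
    )
    def test_densities_normalise_within_each_group(self, weights):
        assignments = [
            _assign(f"r{i}", f"{dom};Phylum{p}", w) for i, (dom, p, w) in enumerate(weights)
        ]
        table = aggregate(assignments, rank="phylum", group="within-domain")
        table.check_normalisation(tol=0.01)
        aggregate(assignments, rank="phylum", group="all").check_normalisation(tol=0.01)
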