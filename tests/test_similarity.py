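"""Word-similarity scoring, index search and the banded aligner."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_word_similarity, full_dp_align
from rrnatax import (
    ReferenceRecord,
    align_pair,
    build_word_index,
    parse_lineage,
    search,
    word_similarity,
)
from rrnatax.similarity import reverse_complement_simple

LIN = parse_lineage("Bacteria;Firmicutes")


def _ref(rid, seq):
    return ReferenceRecord(rid, seq, LIN)


class TestWordSimilarity:
    def test_identity_scores_one(self):
        assert word_similarity("ACGTACGTAC", "ACGTACGTAC", 8) == 1.0

    def test_disjoint_scores_zero(self):
        assert word_similarity("ACGTACGTAC", "TTTTTTTTTT", 8) == 0.0

    def test_partial_overlap(self):
        # query has 3 distinct 8-mers, only ACGTACGT occurs in the reference
        assert word_similarity("ACGTACGTAC", "ACGTACGTTTTT", 8) == pytest.approx(1 / 3)

    def test_query_shorter_than_word_rejected(self):
        with pytest.raises(ValueError):
            word_similarity("ACG", "ACGTACGT", 8)

    def test_ambiguous_words_are_skipped(self):
        # every query word contains the N, so no valid words remain
        assert word_similarity("ACGTNACGT", "ACGTACGTA", 6) == 0.0

    @given(st.data())
    def test_matches_brute_force_enumeration(self, data):
        k = data.draw(st.sampled_from([6, 8, 10]))
        query = data.draw(st.text(alphabet="ACGT", min_size=k, max_size=60))
        ref = data.draw(st.text(alphabet="ACGT", min_size=k, max_size=60))
        # splice a query chunk into the reference so overlap is common
        ref = ref + query[: len(query) // 2]
        assert word_similarity(query, ref, k) == pytest.approx(
            brute_force_word_similarity(query, ref, k)
        )


class TestWordIndex:
    def test_single_word_reference(self):
        index = build_word_index([_ref("r1", "ACGTACGT")], 8)
        assert index.postings == {"ACGTACGT": {"r1"}}

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="r1"):
            build_word_index([_ref("r1", "ACGT")], 8)

    def test_shared_word_posts_both_ids(self):
        index = build_word_index([_ref("r1", "AACCGGTTAC"), _ref("r2", "AACCGGTTGG")], 8)
        assert index.postings["AACCGGTT"] == {"r1", "r2"}


class TestSearch:
    def test_self_retrieval_at_full_similarity(self, tiny_references):
        index = build_word_index(tiny_references, 8)
        for ref in tiny_references:
            hits = search(ref.sequence, index)
            assert hits[0].ref_id == ref.id
            assert hits[0].similarity == 1.0
            assert hits[0].strand == "forward"

    def test_reverse_complement_query_found_on_reverse_strand(self, tiny_references):
        index = build_word_index(tiny_references, 8)
        query = reverse_complement_simple(tiny_references[0].sequence[100:250])
        hits = search(query, index)
        assert hits[0].ref_id == tiny_references[0].id
        assert hits[0].similarity == 1.0
        assert hits[0].strand == "reverse"

    def test_unrelated_query_returns_nothing(self, tiny_references):
        index = build_word_index(tiny_references, 8)
        assert search("ATATATATATATATATAT", index, min_similarity=0.01) == []

    def test_min_similarity_and_max_hits_respected(self, tiny_references):
        index = build_word_index(tiny_references, 8)
        query = tiny_references[0].sequence[:120]
        hits = search(query, index, min_similarity=0.0, max_hits=2)
        assert len(hits) <= 2
        assert hits == sorted(hits, key=lambda h: (-h.similarity, h.ref_id))


class TestAlignPair:
    def test_exact_substring_aligns_gap_free(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        query = ref[50:130]
        aln = align_pair(query, ref)
        assert aln.ops == "M" * 80
        assert (aln.ref_start, aln.ref_end) == (50, 130)
        assert aln.score == 80

    def test_single_substitution_gives_one_mismatch_column(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        query = list(ref[50:130])
        query[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[40]]
        aln = align_pair("".join(query), ref)
        assert aln.ops.count("X") == 1
        assert aln.ops.count("I") == aln.ops.count("D") == 0

    def test_single_deleted_base_gives_one_deletion_column(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        query = ref[50:90] + ref[91:130]  # base 90 missing from the query
        aln = align_pair(query, ref)
        assert aln.ops.count("D") == 1
        assert aln.ops.count("I") == 0

    def test_gapless_projection_invariant(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        query = ref[40:200]
        aln = align_pair(query, ref)
        assert aln.aligned_query.replace("-", "") == query
        assert aln.aligned_ref.replace("-", "") == ref[aln.ref_start : aln.ref_end]

    def test_band_parameter_validated(self):
        with pytest.raises(ValueError):
            align_pair("ACGT", "ACGT", band=0)

    def test_banded_score_equals_full_dp_on_related_pairs(self, rng):
        """On pairs whose optimal path hugs the seeded diagonal, banding
        must not change the optimal score."""
        for _ in range(25):
            ref = "".join(rng.choice(list("ACGT"), size=int(rng.integers(100, 300))))
            start = int(rng.integers(0, len(ref) - 60))
            length = int(rng.integers(40, min(120, len(ref) - start)))
            query = list(ref[start : start + length])
            for _ in range(int(rng.integers(0, 6))):  # a few substitutions
                pos = int(rng.integers(0, len(query)))
                query[pos] = rng.choice([b for b in "ACGT" if b != query[pos]])
            if rng.random() < 0.5 and len(query) > 20:  # occasionally one indel
                pos = int(rng.integers(5, len(query) - 5))
                del query[pos]
            query = "".join(query)
            expected, _, _, _ = full_dp_align(query, ref)
            assert align_pair(query, ref, band=32).score == expected
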