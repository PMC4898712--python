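"""Word (k-mer) similarity search and banded pairwise alignment.

The classification engine scores a fragment against full-length SSU rRNA
references by the fraction of the fragment's distinct k-mers that occur in
the reference.  The score is deliberately query-normalised (not Jaccard):
fragments are far shorter than the ~1.5 kb references, and an exact
substring should score 1.0.  Both strands are always evaluated because
random-primed reverse transcription with second-strand synthesis yields
reads from either strand.

:func:`align_pair` provides the semi-global (query-global, reference-
local) banded alignment used by the primer-site auditor: a fragment must
be aligned end-to-end while it may land anywhere inside the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seq_io import ReferenceRecord

__all__ = [
    "WordIndex",
    "MatchHit",
    "PairwiseAlignment",
    "build_word_index",
    "word_similarity",
    "search",
    "align_pair",
    "reverse_complement_simple",
    "kmer_set",
]

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# Alignment scoring: match +1, mismatch -1; a gap of length L costs
# open + (L-1) * extend with open=2, extend=1.
MATCH = 1
MISMATCH = -1
GAP_OPEN = 2
GAP_EXTEND = 1


def reverse_complement_simple(sequence: str) -> str:
    """Reverse complement (IUPAC-aware) without validation; fast path."""
    return sequence.translate(_COMPLEMENT)[::-1]


def kmer_set(sequence: str, k: int) -> frozenset[str]:
    """Distinct k-mers of a sequence; words containing non-ACGT are skipped."""
    words = set()
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        if _ACGT.issuperset(word):
            words.add(word)
    return frozenset(words)


@dataclass
class WordIndex:
    """Inverted k-mer index over forward-strand reference sequences."""

    word_length: int
    postings: dict[str, set[str]]
    ref_words: dict[str, frozenset[str]]
    references: dict[str, ReferenceRecord] = field(default_factory=dict)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.ref_words


@dataclass(frozen=True)
class MatchHit:
    ref_id: str
    similarity: float
    shared_words: int
    strand: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment with per-column operation labels.

    ``ops`` is one character per column: ``M`` match, ``X`` mismatch,
    ``I`` insertion-in-query (query base vs gap), ``D`` deletion-from-
    query (gap vs reference base).  Coordinates are 0-based half-open on
    the original ungapped sequences.
    """

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ops: str
    score: float

    def __post_init__(self) -> None:
        if not (len(self.aligned_query) == len(self.aligned_ref) == len(self.ops)):
            raise ValueError("alignment fields must have equal column counts")

    @property
    def n_columns(self) -> int:
        return len(self.ops)


def build_word_index(
    references: Sequence[ReferenceRecord], word_length: int = 8
) -> WordIndex:
    """Index forward-strand k-mers of every reference.

    Raises if any reference is shorter than the word length, naming the
    offending record.
    """
    if word_length < 1:
        raise ValueError("word_length must be >= 1")
    postings: dict[str, set[str]] = {}
    ref_words: dict[str, frozenset[str]] = {}
    refs: dict[str, ReferenceRecord] = {}
    for ref in references:
        if len(ref.sequence) < word_length:
            raise ValueError(
                f"reference {ref.id!r} ({len(ref.sequence)} nt) is shorter than "
                f"word length {word_length}"
            )
        words = kmer_set(ref.sequence, word_length)
        ref_words[ref.id] = words
        refs[ref.id] = ref
        for word in words:
            postings.setdefault(word, set()).add(ref.id)
    return WordIndex(word_length, postings, ref_words, refs)


def word_similarity(query: str, reference: str, k: int = 8) -> float:
    """Fraction of the query's distinct k-mers present in the reference.

    Asymmetric by design (query-normalised).  A query identical to a
    substring of the reference scores 1.0.
    """
    if len(query) < k:
        raise ValueError(f"query ({len(query)} nt) shorter than word length {k}")
    qwords = kmer_set(query, k)
    if not qwords:
        return 0.0
    rwords = kmer_set(reference, k)
    return len(qwords & rwords) / len(qwords)


def _strand_hits(qwords: frozenset[str], index: WordIndex, strand: str) -> dict[str, MatchHit]:
    counts: dict[str, int] = {}
    for word in qwords:
        for ref_id in index.postings.get(word, ()):
            counts[ref_id] = counts.get(ref_id, 0) + 1
    n_query = len(qwords)
    return {
        ref_id: MatchHit(ref_id, shared / n_query, shared, strand)
        for ref_id, shared in counts.items()
    }


def search(
    query: str,
    index: WordIndex,
    min_similarity: float = 0.0,
    max_hits: int = 20,
) -> list[MatchHit]:
    """Rank references by word similarity, evaluating both strands.

    For each reference the better strand is kept.  Hits are sorted by
    descending similarity (ties by reference id), thresholded at
    ``min_similarity`` and truncated to ``max_hits``.
    """
    k = index.word_length
    if len(query) < k:
        raise ValueError(f"query ({len(query)} nt) shorter than word length {k}")
    fwd = _strand_hits(kmer_set(query, k), index, "forward")
    rev = _strand_hits(kmer_set(reverse_complement_simple(query), k), index, "reverse")
    best: dict[str, MatchHit] = fwd
    for ref_id, hit in rev.items():
        if ref_id not in best or hit.similarity > best[ref_id].similarity:
            best[ref_id] = hit
    hits = sorted(best.values(), key=lambda h: (-h.similarity, h.ref_id))
    return [h for h in hits if h.similarity >= min_similarity][:max_hits]


def _seed_diagonal(query: str, reference: str, k: int = 8) -> Optional[int]:
    """Most frequent (ref position - query position) offset of shared words."""
    ref_positions: dict[str, list[int]] = {}
    for j in range(len(reference) - k + 1):
        word = reference[j : j + k]
        if _ACGT.issuperset(word):
            ref_positions.setdefault(word, []).append(j)
    offsets: dict[int, int] = {}
    for i in range(len(query) - k + 1):
        word = query[i : i + k]
        for j in ref_positions.get(word, ()):
            offsets[j - i] = offsets.get(j - i, 0) + 1
    if not offsets:
        return None
    # ties -> smallest offset, for determinism
    return min(offsets, key=lambda d: (-offsets[d], d))


def align_pair(
    query: str,
    reference: str,
    band: int = 32,
    query_id: str = "query",
    ref_id: str = "ref",
) -> PairwiseAlignment:
    """Banded semi-global alignment (query global, reference local).

    The full query is aligned; reference overhangs on either side are
    free.  Scoring is match +1, mismatch -1, gap open -2, gap extend -1
    (the opening base costs the open penalty).  The band of half-width
    ``band`` is centred on the diagonal with the most shared 8-mers; when
    the pair shares no words the alignment falls back to an unbanded
    sweep.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    m, n = len(query), len(reference)
    diag = _seed_diagonal(query, reference)
    if diag is None:
        diag, band = 0, max(band, m + n)  # no seed: effectively unbanded

    neg = float("-inf")
    width = n + 1
    # Gotoh three-state DP: H best overall, I ends with query-insertion,
    # D ends with deletion.  Rolling rows for scores; full pointer rows
    # kept for an exact three-state traceback.
    h_prev = [neg] * width
    i_prev = [neg] * width
    ptr_h = [bytearray(width) for _ in range(m + 1)]  # 1 diag, 2 I, 3 D
    ptr_i = [bytearray(width) for _ in range(m + 1)]  # 1 opened, 0 extended
    ptr_d = [bytearray(width) for _ in range(m + 1)]

    def col_lo(i: int) -> int:
        return max(0, i + diag - band)

    def col_hi(i: int) -> int:
        return min(n, i + diag + band)

    for j in range(col_lo(0), col_hi(0) + 1):
        h_prev[j] = 0.0  # free reference-local start
    for i in range(1, m + 1):
        qc = query[i - 1]
        h_cur = [neg] * width
        i_cur = [neg] * width
        d_left = neg
        row_h, row_i, row_d = ptr_h[i], ptr_i[i], ptr_d[i]
        lo, hi = col_lo(i), col_hi(i)
        for j in range(lo, hi + 1):
            open_i = h_prev[j] - GAP_OPEN
            ext_i = i_prev[j] - GAP_EXTEND
            if open_i >= ext_i:
                i_val, row_i[j] = open_i, 1
            else:
                i_val = ext_i
            i_cur[j] = i_val
            if j > 0:
                open_d = h_cur[j - 1] - GAP_OPEN
                ext_d = d_left - GAP_EXTEND
                if open_d >= ext_d:
                    d_val, row_d[j] = open_d, 1
                else:
                    d_val = ext_d
                sub = MATCH if qc == reference[j - 1] else MISMATCH
                diag_score = h_prev[j - 1] + sub
            else:
                d_val = diag_score = neg
            d_left = d_val
            if diag_score >= i_val and diag_score >= d_val:
                h_cur[j], row_h[j] = diag_score, 1
            elif i_val >= d_val:
                h_cur[j], row_h[j] = i_val, 2
            else:
                h_cur[j], row_h[j] = d_val, 3
        h_prev, i_prev = h_cur, i_cur

    j_end = max(range(col_lo(m), col_hi(m) + 1), key=lambda j: (h_prev[j], -j))
    score = h_prev[j_end]
    if score == neg:
        raise RuntimeError("band produced no feasible alignment")

    # three-state traceback so gap runs are reconstructed exactly
    cols_q, cols_r, ops = [], [], []
    i, j, state = m, j_end, "H"
    while i > 0:
        if state == "H":
            move = ptr_h[i][j]
            if move == 1:
                qc, rc = query[i - 1], reference[j - 1]
                cols_q.append(qc)
                cols_r.append(rc)
                ops.append("M" if qc == rc else "X")
                i, j = i - 1, j - 1
            elif move == 2:
                state = "I"
            else:
                state = "D"
        elif state == "I":
            cols_q.append(query[i - 1])
            cols_r.append("-")
            ops.append("I")
            opened = ptr_i[i][j]
            i -= 1
            if opened:
                state = "H"
        else:  # D
            cols_q.append("-")
            cols_r.append(reference[j - 1])
            ops.append("D")
            opened = ptr_d[i][j]
            j -= 1
            if opened:
                state = "H"
    return PairwiseAlignment(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query="".join(reversed(cols_q)),
        aligned_ref="".join(reversed(cols_r)),
        query_start=0,
        query_end=m,
        ref_start=j,
        ref_end=j_end,
        ops="".join(reversed(ops)),
        score=float(score),
    )
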