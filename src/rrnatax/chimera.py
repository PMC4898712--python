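"""Reference-based chimera detection for PCR amplicon reads.

A chimera stitched together from two parent templates matches each parent
well on one side of the breakpoint but no single reference well overall.
The detector therefore scans candidate breakpoints and asks whether a
two-parent explanation (best prefix parent + best suffix parent) improves
on the best single-reference word similarity by at least
``min_improvement``.  Reads that are exact substrings of one indexed
reference can never be flagged: their single-reference similarity is
already 1.0.

This check is meaningful only for amplicon data; randomly fragmented
reverse-transcribed rRNA reads never see a PCR step, so the RT pipeline
skips it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .cleaning import UniqueRead
from .similarity import WordIndex, reverse_complement_simple

__all__ = ["ChimeraVerdict", "detect_chimera"]

_ACGT = frozenset("ACGT")


@dataclass
class ChimeraVerdict:
    read_id: str
    is_chimera: bool
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    breakpoint: Optional[int] = None
    score: float = 0.0
    status: str = "ok"  # ok | too_short

    def __post_init__(self) -> None:
        if self.is_chimera and (
            self.parent_a is None or self.parent_a == self.parent_b or self.breakpoint is None
        ):
            raise ValueError("a chimera verdict needs two distinct parents and a breakpoint")


def _word_starts(sequence: str, k: int) -> list[tuple[int, str]]:
    return [
        (i, sequence[i : i + k])
        for i in range(len(sequence) - k + 1)
        if _ACGT.issuperset(sequence[i : i + k])
    ]


def _best(counts: dict[str, int], n_words: int) -> tuple[Optional[str], float]:
    """Best (ref, query-normalised similarity); ties break by ref id."""
    if not counts or n_words == 0:
        return (None, 0.0)
    ref = min(counts, key=lambda r: (-counts[r], r))
    return (ref, counts[ref] / n_words)


def _scan_orientation(
    sequence: str, index: WordIndex, min_segment: int, step: int
) -> tuple[float, Optional[str], Optional[str], Optional[int], float]:
    """Best two-parent improvement for one read orientation.

    Returns (chimera score, parent_a, parent_b, breakpoint, full similarity).
    Prefix/suffix word sets are maintained incrementally over breakpoints
    scanned at ``step``-sized strides.
    """
    k = index.word_length
    words = _word_starts(sequence, k)
    n_total = len({w for _, w in words})
    full_counts: dict[str, int] = {}
    seen: set[str] = set()
    for _, w in words:
        if w in seen:
            continue
        seen.add(w)
        for r in index.postings.get(w, ()):
            full_counts[r] = full_counts.get(r, 0) + 1
    _, s_full = _best(full_counts, n_total)

    breakpoints = list(range(min_segment, len(sequence) - min_segment + 1, step))
    if not breakpoints:
        return (float("-inf"), None, None, None, s_full)

    # suffix states precomputed right-to-left; prefix state advances with
    # the breakpoint in the main left-to-right pass
    suffix_best: dict[int, tuple[Optional[str], float]] = {}
    counts: dict[str, int] = {}
    present: set[str] = set()
    word_at = dict(words)
    next_start = len(sequence) - k  # next word start to absorb (moving left)
    for b in reversed(breakpoints):
        while next_start >= b:
            w = word_at.get(next_start)
            next_start -= 1
            if w is None or w in present:
                continue
            present.add(w)
            for r in index.postings.get(w, ()):
                counts[r] = counts.get(r, 0) + 1
        suffix_best[b] = _best(counts, len(present))

    best_score = float("-inf")
    plateau: list[tuple] = []  # (b, ref_a, ref_b) at the current best score
    pre_counts: dict[str, int] = {}
    pre_present: set[str] = set()
    pos = 0
    for b in breakpoints:
        # prefix words are those fully inside [0, b)
        while pos <= b - k:
            w = word_at.get(pos)
            pos += 1
            if w is None or w in pre_present:
                continue
            pre_present.add(w)
            for r in index.postings.get(w, ()):
                pre_counts[r] = pre_counts.get(r, 0) + 1
        ref_a, s_pre = _best(pre_counts, len(pre_present))
        ref_b, s_suf = suffix_best[b]
        score = min(s_pre, s_suf) - s_full
        if score > best_score:
            best_score = score
            plateau = [(b, ref_a, ref_b)]
        elif score == best_score:
            plateau.append((b, ref_a, ref_b))
    # shared words between similar parents flatten the score around the
    # true junction; the middle of the tied plateau is the best estimate
    b, ref_a, ref_b = plateau[len(plateau) // 2]
    return (best_score, ref_a, ref_b, b, s_full)


def detect_chimera(
    read: Union[UniqueRead, "object"],
    index: WordIndex,
    min_segment: int = 60,
    min_improvement: float = 0.10,
) -> ChimeraVerdict:
    """Flag a read as chimeric if a two-parent split beats its best single
    reference by ``min_improvement`` in word similarity.

    Candidate breakpoints are scanned at word-length steps between
    ``min_segment`` and ``len(read) - min_segment``.  Both the read and
    its reverse complement are evaluated so the verdict is strand-
    invariant; the reported breakpoint is in original read coordinates.
    Reads shorter than ``2 * min_segment`` get status ``too_short`` and
    are never flagged.
    """
    if min_segment < index.word_length:
        raise ValueError("min_segment must be at least the index word length")
    sequence = read.sequence
    read_id = getattr(read, "id", sequence[:16])
    if len(sequence) < 2 * min_segment:
        return ChimeraVerdict(read_id, False, status="too_short")

    best = None
    for oriented, is_rc in ((sequence, False), (reverse_complement_simple(sequence), True)):
        score, ref_a, ref_b, bp, s_full = _scan_orientation(
            oriented, index, min_segment, index.word_length
        )
        if bp is not None and is_rc:
            bp = len(sequence) - bp
            ref_a, ref_b = ref_b, ref_a
        cand = (score, ref_a, ref_b, bp, s_full)
        if best is None or cand[0] > best[0]:
            best = cand
    score, ref_a, ref_b, bp, s_full = best
    is_chimera = (
        score >= min_improvement
        and ref_a is not None
        and ref_b is not None
        and ref_a != ref_b
    )
    if is_chimera:
        return ChimeraVerdict(read_id, True, ref_a, ref_b, bp, score)
    return ChimeraVerdict(read_id, False, score=score if score > float("-inf") else 0.0)
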