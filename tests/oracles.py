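"""Independent reference implementations used as test oracles.

These deliberately re-derive the quantities the package computes using
the most transparent method available — explicit set enumeration for word
similarity and a full-matrix (unbanded) affine-gap dynamic program for
semi-global alignment — and stay independent of the package's code paths.
Scoring objective: match +1, mismatch -1, a gap of length L costs
2 + (L - 1).
"""

from __future__ import annotations

NEG = float("-inf")


def brute_force_word_similarity(query: str, reference: str, k: int) -> float:
    """Query-normalised shared-distinct-k-mer fraction by direct enumeration."""
    q_words = set()
    for i in range(len(query) - k + 1):
        w = query[i : i + k]
        if all(c in "ACGT" for c in w):
            q_words.add(w)
    if not q_words:
        return 0.0
    r_words = set()
    for i in range(len(reference) - k + 1):
        w = reference[i : i + k]
        if all(c in "ACGT" for c in w):
            r_words.add(w)
    return len(q_words & r_words) / len(q_words)


def full_dp_align(query: str, reference: str):
    """Unbanded semi-global Gotoh alignment (query global, reference local).

    Returns ``(score, ops)`` where ops is a string over M/X/I/D per
    alignment column.  Full (m+1) x (n+1) matrices, no banding, no
    seeding — the exhaustive counterpart to the package's banded aligner.
    """
    m, n = len(query), len(reference)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # query-insertion state
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # deletion state
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            E[i][j] = max(H[i - 1][j] - 2, E[i - 1][j] - 1)
            if j > 0:
                F[i][j] = max(H[i][j - 1] - 2, F[i][j - 1] - 1)
                sub = 1 if query[i - 1] == reference[j - 1] else -1
                diag = H[i - 1][j - 1] + sub
            else:
                diag = NEG
            H[i][j] = max(diag, E[i][j], F[i][j])
    j_end = max(range(n + 1), key=lambda j: (H[m][j], -j))
    score = H[m][j_end]

    ops = []
    i, j = m, j_end
    state = "H"
    while i > 0:
        if state == "H":
            sub = (
                H[i - 1][j - 1] + (1 if query[i - 1] == reference[j - 1] else -1)
                if j > 0
                else NEG
            )
            if j > 0 and H[i][j] == sub:
                ops.append("M" if query[i - 1] == reference[j - 1] else "X")
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("I")
            opened = E[i][j] == H[i - 1][j] - 2
            i -= 1
            if opened:
                state = "H"
        else:
            ops.append("D")
            opened = F[i][j] == H[i][j - 1] - 2
            j -= 1
            if opened:
                state = "H"
    ref_start = j
    ops.reverse()
    return score, "".join(ops), ref_start, j_end


def oracle_window_events(ops: str, ref_start: int, window: tuple[int, int]):
    """(mismatches, insertions, deletions) inside a reference window, read
    off oracle alignment columns."""
    w_start, w_end = window
    mismatches = insertions = deletions = 0
    ref_pos = ref_start
    for op in ops:
        if op == "I":
            if w_start < ref_pos < w_end:
                insertions += 1
            continue
        if w_start <= ref_pos < w_end:
            if op == "X":
                mismatches += 1
            elif op == "D":
                deletions += 1
        ref_pos += 1
    return mismatches, insertions, deletions
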