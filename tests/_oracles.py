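"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths they check: the G4Hunter oracle
expands runs outward from each position instead of scanning runs, and the
alignment oracle enumerates every global alignment and scores the
alignment strings directly.
"""

from __future__ import annotations

from g4probe.align import nuc44


def g4hunter_mean_bruteforce(seq: str) -> float:
    """Mean G4Hunter score via per-position run expansion."""
    seq = seq.upper()
    total = 0
    for i, b in enumerate(seq):
        if b not in "GC":
            continue
        left = i
        while left > 0 and seq[left - 1] == b:
            left -= 1
        right = i
        while right < len(seq) - 1 and seq[right + 1] == b:
            right += 1
        run = right - left + 1
        total += min(run, 4) if b == "G" else -min(run, 4)
    return total / len(seq)


def score_alignment(
    row_a: str, row_b: str, gap_open: float, gap_extend: float
) -> float:
    """Score a gapped alignment pair directly from its strings."""
    matrix = nuc44()
    score = 0.0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            score += float(matrix[ca, cb])
    for row in (row_a, row_b):
        i = 0
        while i < len(row):
            if row[i] == "-":
                j = i
                while j < len(row) and row[j] == "-":
                    j += 1
                score -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (no all-gap columns) of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def best_alignment_score_bruteforce(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    return max(
        score_alignment(ra, rb, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )
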